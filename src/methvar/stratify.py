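"""Epigenetic subtyping: PCA-guided sequence selection, Ward clustering, and
clinical/survival association of the resulting subgroups.

Sequence selection follows the correlation rule: PCA over tumor samples
(sequences centered), then every sequence whose methylation vector has
|Pearson r| above the threshold with a retained principal-component score
vector is kept.  Clustering is agglomerative with Euclidean distance and the
Ward criterion on sequence-wise centered-and-scaled values.  Survival is
compared with Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .differential import fisher_exact_two_sided
from .preprocess import TUMOR, MethylationMatrix

logger = logging.getLogger(__name__)


class StratifyError(ValueError):
    pass


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    correlations: pd.DataFrame  # sequences x components
    selected_per_component: dict[int, list[str]]
    selected: list[str]  # union, in matrix order


def pca_select_sequences(
    matrix: MethylationMatrix,
    corr_threshold: float = 0.85,
    n_components: int = 2,
    tumors_only: bool = True,
) -> PCAResult:
    """PCA over tumor samples; select sequences tracking the main components.

    Sequences are centered before the decomposition.  For each retained
    component, sequences with |Pearson correlation| between their methylation
    vector (across the PCA samples) and the component score vector strictly
    above ``corr_threshold`` are selected; the union is reported in matrix
    order.
    """
    samples = matrix.group_samples(TUMOR) if tumors_only else list(matrix.values.columns)
    if len(samples) < 3:
        raise StratifyError("PCA needs >= 3 samples")
    X = matrix.values[samples].to_numpy(dtype=float).T  # samples x sequences
    X = X - X.mean(axis=0, keepdims=True)  # center per sequence
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise StratifyError(
            f"n_components={n_components} exceeds matrix rank bound {max_rank}"
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(X)  # samples x components

    # Pearson r between each (centered) sequence vector and each score vector
    s = scores - scores.mean(axis=0, keepdims=True)
    s_norm = np.linalg.norm(s, axis=0)
    x_norm = np.linalg.norm(X, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (X.T @ s) / np.outer(x_norm, s_norm)
    corr = np.nan_to_num(corr, nan=0.0)

    seq_index = matrix.values.index
    selected_per: dict[int, list[str]] = {}
    union = np.zeros(len(seq_index), dtype=bool)
    for j in range(n_components):
        mask = np.abs(corr[:, j]) > corr_threshold
        selected_per[j + 1] = list(seq_index[mask])
        union |= mask
    result = PCAResult(
        scores=pd.DataFrame(
            scores,
            index=pd.Index(samples, name="sample_id"),
            columns=[f"PC{j + 1}" for j in range(n_components)],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        correlations=pd.DataFrame(
            corr, index=seq_index, columns=[f"PC{j + 1}" for j in range(n_components)]
        ),
        selected_per_component=selected_per,
        selected=list(seq_index[union]),
    )
    logger.info(
        "PCA selection: %s sequences above |r| > %.2f; explained variance %s",
        len(result.selected),
        corr_threshold,
        np.round(result.explained_variance_ratio, 3),
    )
    return result


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> cluster id (1-based)
    k: int
    method: str
    metric: str
    selected_ids: list[str] = field(default_factory=list)
    linkage_matrix: np.ndarray | None = None

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def ward_cluster(
    matrix: MethylationMatrix,
    k: int,
    selected_ids: list[str] | None = None,
    tumors_only: bool = True,
    scale_sequences: bool = True,
) -> ClusterAssignment:
    """Ward / Euclidean hierarchical clustering of samples.

    Values are centered and (by default) scaled per sequence before
    clustering.  The Ward.D2-style criterion of
    :func:`scipy.cluster.hierarchy.linkage` is used; the result is
    deterministic given the input (distance ties are broken by scipy's
    fixed merge order).
    """
    samples = matrix.group_samples(TUMOR) if tumors_only else list(matrix.values.columns)
    if k < 1:
        raise StratifyError("k must be >= 1")
    if k > len(samples):
        raise StratifyError(f"k={k} exceeds {len(samples)} samples")
    values = matrix.values
    if selected_ids is not None:
        if not selected_ids:
            raise StratifyError("selected_ids is empty")
        values = values.loc[selected_ids]
    X = values[samples].to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if scale_sequences:
        sd = X.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd[:, None]
    Z = linkage(X.T, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=pd.Index(samples, name="sample_id"), name="cluster"),
        k=k,
        method="ward",
        metric="euclidean",
        selected_ids=list(values.index),
        linkage_matrix=Z,
    )


def choose_k_silhouette(
    matrix: MethylationMatrix,
    selected_ids: list[str] | None = None,
    k_range: range = range(2, 7),
    tumors_only: bool = True,
) -> int:
    """Pick k maximizing the mean silhouette over Ward partitions."""
    from sklearn.metrics import silhouette_score

    samples = matrix.group_samples(TUMOR) if tumors_only else list(matrix.values.columns)
    values = matrix.values if selected_ids is None else matrix.values.loc[selected_ids]
    X = values[samples].to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    X = (X / sd[:, None]).T
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(samples):
            break
        labels = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise StratifyError("no viable k in range")
    return best_k


# ---------------------------------------------------------------------------
# clinical association
# ---------------------------------------------------------------------------

def cluster_clinical_association(
    assignment: ClusterAssignment,
    clinical: pd.DataFrame,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of cluster membership with clinical features.

    2x2 tables use the exact Fisher test, larger contingency tables a
    chi-square test, continuous features a Kruskal-Wallis test; p-values are
    Bonferroni-corrected across the tested factors.
    """
    if assignment.k < 2:
        raise StratifyError("association needs >= 2 clusters")
    samples = [s for s in assignment.labels.index if s in clinical.index]
    labels = assignment.labels.loc[samples]
    clin = clinical.loc[samples]
    if categorical is None:
        categorical = [
            c
            for c in clin.columns
            if not pd.api.types.is_numeric_dtype(clin[c]) and not c.endswith("_event")
        ]
    if continuous is None:
        continuous = [
            c
            for c in clin.columns
            if pd.api.types.is_numeric_dtype(clin[c])
            and not c.endswith(("_days", "_event"))
        ]
    rows = []
    for factor in categorical:
        table = pd.crosstab(clin[factor], labels)
        if table.shape[0] < 2:
            logger.warning("factor %s has a single level, skipped", factor)
            continue
        if table.shape == (2, 2):
            p = fisher_exact_two_sided(table.to_numpy().tolist())
            test = "fisher"
        else:
            p = float(stats.chi2_contingency(table.to_numpy())[1])
            test = "chi2"
        rows.append((factor, test, p))
    for factor in continuous:
        groups = [clin.loc[labels == c, factor].to_numpy() for c in sorted(labels.unique())]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            continue
        try:
            p = float(stats.kruskal(*groups).pvalue)
        except ValueError:  # all values identical
            p = 1.0
        rows.append((factor, "kruskal", p))
    out = pd.DataFrame(rows, columns=["factor", "test", "p"]).set_index("factor")
    out["p_bonf"] = np.minimum(1.0, out["p"] * len(out))
    out["significant"] = out["p_bonf"] < alpha
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMComparison:
    curves: dict[int, pd.DataFrame]  # cluster -> KM table (time, survival)
    medians: dict[int, float]  # np.inf when the curve never crosses 0.5
    statistic: float
    p: float
    p_method: str
    groups: tuple[int, int]


def _logrank_statistic(times, events, labels) -> float:
    """Plain two-group log-rank chi-square statistic (used by the
    permutation option; lifelines supplies the default path)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = events & (times == t)
        n = at_risk.sum()
        d_tot = d.sum()
        n1 = (at_risk & (labels == uniq[0])).sum()
        d1 = (d & (labels == uniq[0])).sum()
        obs_minus_exp += d1 - d_tot * n1 / n
        if n > 1:
            var += d_tot * (n1 / n) * (1 - n1 / n) * (n - d_tot) / (n - 1)
    if var == 0:
        return 0.0
    return float(obs_minus_exp**2 / var)


def plot_km(km: "KMComparison", path) -> None:
    """Step plot of the Kaplan-Meier curves (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in km.curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=f"cluster {g}")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"log-rank {km.groups}: p = {km.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(
    matrix: MethylationMatrix, assignment: ClusterAssignment, path
) -> None:
    """Sequence x sample heatmap of centered-and-scaled levels, samples
    ordered by cluster (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(assignment.labels.sort_values(kind="stable").index)
    values = matrix.values.loc[assignment.selected_ids or matrix.values.index, order]
    X = values.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    X = X / sd[:, None]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(X, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_ylabel(f"{X.shape[0]} sequences")
    fig.colorbar(im, ax=ax, label="z-scored methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_logrank(
    assignment: ClusterAssignment,
    clinical: pd.DataFrame,
    endpoint: str = "LSS",
    groups: tuple[int, int] | None = None,
    p_method: str = "chi2",
    max_exact_n: int = 20,
) -> KMComparison:
    """Kaplan-Meier curves per cluster and a two-group log-rank test.

    ``p_method='chi2'`` uses the asymptotic log-rank test (lifelines);
    ``'permutation'`` recomputes the statistic over all label assignments
    (exhaustive when the comparison has <= ``max_exact_n`` samples, else
    10,000 random permutations) and reports the proportion at least as
    extreme.  Median survival is ``inf`` when a curve never crosses 0.5.
    """
    time_col, event_col = f"{endpoint}_days", f"{endpoint}_event"
    for col in (time_col, event_col):
        if col not in clinical.columns:
            raise StratifyError(f"clinical table lacks endpoint column {col!r}")
    samples = [s for s in assignment.labels.index if s in clinical.index]
    labels = assignment.labels.loc[samples]
    clin = clinical.loc[samples]
    clusters = sorted(labels.unique())
    if groups is None:
        if len(clusters) != 2:
            raise StratifyError("specify groups=(a, b) when there are != 2 clusters")
        groups = (clusters[0], clusters[1])
    for g in groups:
        mask = labels == g
        if int(clin.loc[mask, event_col].sum()) < 2:
            raise StratifyError(f"cluster {g} has < 2 events for {endpoint}")

    curves: dict[int, pd.DataFrame] = {}
    medians: dict[int, float] = {}
    for g in clusters:
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(clin.loc[mask, time_col], clin.loc[mask, event_col], label=str(g))
        surv = kmf.survival_function_
        curves[g] = surv.rename(columns={surv.columns[0]: "survival"}).reset_index(
            names="time"
        )
        medians[g] = float(kmf.median_survival_time_)

    mask = labels.isin(groups)
    t = clin.loc[mask, time_col].to_numpy(dtype=float)
    e = clin.loc[mask, event_col].to_numpy(dtype=bool)
    lab = labels[mask].to_numpy()
    res = logrank_test(t[lab == groups[0]], t[lab == groups[1]],
                       e[lab == groups[0]], e[lab == groups[1]])
    statistic = float(res.test_statistic)
    if p_method == "chi2":
        p = float(res.p_value)
    elif p_method == "permutation":
        n = len(t)
        n1 = int((lab == groups[0]).sum())
        obs = _logrank_statistic(t, e, lab == groups[0])
        idx = np.arange(n)
        if n <= max_exact_n:
            count = 0
            total_n = 0
            for chosen in itertools.combinations(idx, n1):
                member = np.zeros(n, dtype=bool)
                member[list(chosen)] = True
                if _logrank_statistic(t, e, member) >= obs - 1e-12:
                    count += 1
                total_n += 1
            p = count / total_n
        else:
            rng = np.random.default_rng(0)
            count = 0
            n_perm = 10000
            for _ in range(n_perm):
                member = np.zeros(n, dtype=bool)
                member[rng.choice(n, size=n1, replace=False)] = True
                if _logrank_statistic(t, e, member) >= obs - 1e-12:
                    count += 1
            p = (count + 1) / (n_perm + 1)
        statistic = obs
    else:
        raise StratifyError(f"unknown p_method {p_method!r}")
    return KMComparison(
        curves=curves, medians=medians, statistic=statistic, p=p,
        p_method=p_method, groups=groups,
    )
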