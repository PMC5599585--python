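"""Methylation-disruption analysis.

Each tumor's per-sequence methylation change relative to the median of the
control lymph nodes is summarized as a methylation variability profile
(MVP): a Gaussian kernel density of the change distribution evaluated on a
grid shared by all samples.  Distances between samples are the L1 distance
between their MVP curves (the area bounded by the two densities, bounded by
2 = twice the total-variation distance); the Methylation Variability Score
(MVS) of a tumor is its L1 distance to the renormalized pointwise-median
control profile — the larger the MVS, the greater the disruption.  Consensus
hierarchical clustering over subsets of sequences ranked by decreasing
median absolute deviation (MAD) of the changes identifies robust
high-disruption subgroups, and a Fisher test links the most disrupted
cluster to short lymphoma-specific survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .differential import fisher_exact_two_sided
from .preprocess import CONTROL, MethylationMatrix

logger = logging.getLogger(__name__)

GRID_SIZE = 512
GRID_PERCENTILES = (0.1, 99.9)
MIN_BANDWIDTH = 1e-3


class DisruptError(ValueError):
    pass


@dataclass
class MVProfile:
    """Density of one sample's differential-methylation values on a shared grid."""

    sample_id: str
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.density.shape:
            raise DisruptError("grid and density must have equal length")
        area = np.trapezoid(self.density, self.grid)
        if not np.isclose(area, 1.0, atol=1e-6):
            raise DisruptError(f"density must integrate to 1, got {area:.6g}")


# ---------------------------------------------------------------------------
# methylation changes
# ---------------------------------------------------------------------------

def differential_matrix(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-sequence change of every sample from the control median.

    The reference for each sequence is the median across control samples;
    controls get change values against that same reference, so that control
    MVPs can serve as the reference profile set.
    """
    controls = matrix.group_samples(CONTROL)
    if not controls:
        raise DisruptError("no control samples")
    reference = matrix.values[controls].median(axis=1)
    return matrix.values.sub(reference, axis=0)


# ---------------------------------------------------------------------------
# MVP construction
# ---------------------------------------------------------------------------

def shared_grid(
    changes: pd.DataFrame,
    percentiles: tuple[float, float] = GRID_PERCENTILES,
    size: int = GRID_SIZE,
) -> np.ndarray:
    """Evaluation grid spanning the pooled percentile range of all changes."""
    pooled = changes.to_numpy(dtype=float).ravel()
    lo, hi = np.percentile(pooled, percentiles)
    if lo == hi:
        lo, hi = lo - 1.0, hi + 1.0
    return np.linspace(lo, hi, size)


def mvp(
    values: np.ndarray | pd.Series,
    grid: np.ndarray,
    sample_id: str = "",
    bandwidth: str | float = "silverman",
) -> MVProfile:
    """Gaussian KDE of one sample's change values on the shared grid.

    The density is renormalized to integrate to exactly 1 over the grid.
    Degenerate inputs (all values identical) fall back to a minimum
    bandwidth floor with a warning.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise DisruptError("mvp needs >= 2 finite values")
    if np.ptp(x) == 0 or x.std() == 0:
        logger.warning("sample %s: degenerate change distribution, bandwidth floor used", sample_id)
        density = np.exp(-0.5 * ((grid - x[0]) / MIN_BANDWIDTH) ** 2)
    else:
        sd = x.std(ddof=1)
        if bandwidth == "silverman":
            # Silverman's rule of thumb with the robust spread estimate,
            # 0.9 * min(sd, IQR/1.34) * n^(-1/5): keeps a heavy differential-
            # methylation tail from over-smoothing the central bulk
            q75, q25 = np.percentile(x, [75, 25])
            spread = min(sd, (q75 - q25) / 1.34) or sd
            bw = max(0.9 * spread * x.size ** (-0.2), MIN_BANDWIDTH)
        elif isinstance(bandwidth, (int, float)):
            bw = max(float(bandwidth), MIN_BANDWIDTH)
        else:
            raise DisruptError(f"unknown bandwidth rule {bandwidth!r}")
        kde = gaussian_kde(x, bw_method=bw / sd)
        density = kde(grid)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise DisruptError(f"sample {sample_id}: density mass fell outside the grid")
    return MVProfile(sample_id=sample_id, grid=grid, density=density / area)


def mvp_profiles(
    changes: pd.DataFrame,
    grid: np.ndarray | None = None,
    bandwidth: str | float = "silverman",
) -> dict[str, MVProfile]:
    """One MVP per sample (column of the change matrix) on a common grid."""
    if grid is None:
        grid = shared_grid(changes)
    return {
        s: mvp(changes[s].to_numpy(), grid, sample_id=s, bandwidth=bandwidth)
        for s in changes.columns
    }


# ---------------------------------------------------------------------------
# distances and the MVS
# ---------------------------------------------------------------------------

def mvp_distance(a: MVProfile, b: MVProfile) -> float:
    """Area bounded by two MVP curves: trapezoidal integral of |f - g|.

    A metric on profiles sharing a grid; bounded above by 2 (attained by
    densities with disjoint support).
    """
    if a.grid.shape != b.grid.shape or not np.array_equal(a.grid, b.grid):
        raise DisruptError("profiles must share the evaluation grid")
    return float(np.trapezoid(np.abs(a.density - b.density), a.grid))


def median_control_profile(control_profiles: list[MVProfile]) -> MVProfile:
    """Pointwise median of control densities, renormalized to integrate to 1."""
    if not control_profiles:
        raise DisruptError("empty control profile set")
    grid = control_profiles[0].grid
    stack = np.vstack([p.density for p in control_profiles])
    med = np.median(stack, axis=0)
    area = np.trapezoid(med, grid)
    if area <= 0:
        raise DisruptError("degenerate control median profile")
    return MVProfile(sample_id="control_median", grid=grid, density=med / area)


def mvs(sample: MVProfile, control_profiles: list[MVProfile]) -> float:
    """Methylation Variability Score: L1 distance to the control reference."""
    return mvp_distance(sample, median_control_profile(control_profiles))


def shared_bandwidth(changes: pd.DataFrame) -> float:
    """Common KDE bandwidth for cross-sample profile comparison.

    The robust SD (IQR/1.34) of the pooled change distribution.  Profiles
    that are compared or clustered must be smoothed identically, and at the
    scale of the overall change distribution rather than the per-sample
    optimum, so that curve differences reflect which sequences deviate and
    by how much — not sample-specific fine structure of the normalized bulk.
    """
    pooled = changes.to_numpy(dtype=float).ravel()
    q75, q25 = np.percentile(pooled, [75, 25])
    return max((q75 - q25) / 1.34, MIN_BANDWIDTH)


def mvs_scores(
    values_or_changes,
    tumor_samples: list[str],
    control_samples: list[str],
    grid: np.ndarray | None = None,
    matrix: MethylationMatrix | None = None,
) -> pd.Series:
    """MVS for every tumor, against the median control MVP.

    The control reference profiles are built from leave-one-out changes
    (each control against the median of the remaining controls) when the
    full ``matrix`` is supplied: with the plain control-vs-control-median
    changes every control carries an atom of exactly-zero changes (it is
    itself the per-sequence median for a share of sequences), which makes
    the reference artificially spiky.  All profiles use the shared
    pooled-scale bandwidth.
    """
    if not control_samples:
        raise DisruptError("no control samples")
    changes = values_or_changes
    if grid is None:
        grid = shared_grid(changes)
    bw = shared_bandwidth(changes)
    profiles = {
        s: mvp(changes[s].to_numpy(), grid, s, bandwidth=bw) for s in tumor_samples
    }
    if matrix is not None:
        control_profiles = []
        for c in control_samples:
            others = [x for x in control_samples if x != c]
            if not others:
                raise DisruptError("leave-one-out reference needs >= 2 controls")
            loo = matrix.values[c] - matrix.values[others].median(axis=1)
            control_profiles.append(mvp(loo.to_numpy(), grid, c, bandwidth=bw))
    else:
        control_profiles = [
            mvp(changes[c].to_numpy(), grid, c, bandwidth=bw) for c in control_samples
        ]
    reference = median_control_profile(control_profiles)
    return pd.Series(
        {s: mvp_distance(profiles[s], reference) for s in tumor_samples}, name="MVS"
    )


# ---------------------------------------------------------------------------
# MAD ranking
# ---------------------------------------------------------------------------

def mad_rank_sequences(
    changes: pd.DataFrame, tumor_samples: list[str] | None = None, scale: float = 1.0
) -> pd.Series:
    """Sequences sorted by decreasing MAD of tumor changes.

    MAD is unscaled by default (``scale=1``; pass 1.4826 for the
    normal-consistent variant).  Ties are broken by sequence id so the
    ranking is deterministic.
    """
    cols = tumor_samples if tumor_samples is not None else list(changes.columns)
    if len(cols) < 2:
        raise DisruptError("MAD ranking needs >= 2 tumors")
    x = changes[cols].to_numpy(dtype=float)
    med = np.median(x, axis=1, keepdims=True)
    mad = scale * np.median(np.abs(x - med), axis=1)
    out = pd.Series(mad, index=changes.index, name="mad")
    # decreasing MAD, ties broken by sequence id
    order = np.lexsort((changes.index.to_numpy(), -mad))
    return out.iloc[order]


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # samples x samples in [0, 1], diagonal 1
    assignment: pd.Series  # sample -> cluster id from the consensus distance
    subset_size: int
    n_resamples: int
    k: int


def _profile_distance_matrix(profiles: dict[str, MVProfile], samples: list[str]) -> np.ndarray:
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mvp_distance(profiles[samples[i]], profiles[samples[j]])
    return d


def consensus_cluster(
    changes: pd.DataFrame,
    mad_ranking: pd.Series,
    subset_size: int,
    samples: list[str] | None = None,
    k: int = 3,
    n_resamples: int = 1000,
    sample_fraction: float = 0.8,
    linkage_method: str = "average",
    seed: int = 0,
) -> ConsensusResult:
    """Consensus hierarchical clustering of MVPs on top-MAD sequences.

    Restricts the change matrix to the ``subset_size`` highest-MAD sequences,
    builds one MVP per sample on that restriction (profiles are per-sample,
    so they are computed once), and repeatedly clusters random sample subsets
    with the MVP L1 distance and the given linkage.  The consensus entry for
    a pair is (#times co-clustered) / (#times co-drawn); the final assignment
    comes from clustering the distance 1 - consensus.
    """
    if samples is None:
        samples = list(changes.columns)
    if subset_size > len(mad_ranking):
        raise DisruptError(
            f"subset_size {subset_size} exceeds {len(mad_ranking)} ranked sequences"
        )
    n = len(samples)
    n_draw = int(round(sample_fraction * n))
    if n_draw < k:
        raise DisruptError("sample_fraction yields fewer samples than clusters")
    top = mad_ranking.index[:subset_size]
    restricted = changes.loc[top, samples]
    grid = shared_grid(restricted)
    profiles = mvp_profiles(restricted, grid, bandwidth=shared_bandwidth(restricted))
    dist = _profile_distance_matrix(profiles, samples)

    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    drawn = np.zeros((n, n))
    full = n_draw == n
    for _ in range(n_resamples):
        idx = np.arange(n) if full else np.sort(rng.choice(n, size=n_draw, replace=False))
        sub = dist[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method=linkage_method)
        labels = fcluster(Z, t=k, criterion="maxclust")
        same = labels[:, None] == labels[None, :]
        drawn[np.ix_(idx, idx)] += 1
        together[np.ix_(idx, idx)] += same
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(drawn > 0, together / drawn, 0.0)
    np.fill_diagonal(consensus, 1.0)

    final_Z = linkage(squareform(1.0 - consensus, checks=False), method=linkage_method)
    final = fcluster(final_Z, t=k, criterion="maxclust")
    index = pd.Index(samples, name="sample_id")
    return ConsensusResult(
        consensus=pd.DataFrame(consensus, index=index, columns=index),
        assignment=pd.Series(final, index=index, name="cluster"),
        subset_size=subset_size,
        n_resamples=n_resamples,
        k=k,
    )


def consensus_over_subsets(
    changes: pd.DataFrame,
    mad_ranking: pd.Series,
    subset_sizes: list[int],
    **kwargs,
) -> dict[int, ConsensusResult]:
    return {
        size: consensus_cluster(changes, mad_ranking, size, **kwargs)
        for size in subset_sizes
    }


# ---------------------------------------------------------------------------
# disrupted-group survival read-out
# ---------------------------------------------------------------------------

@dataclass
class DisruptedGroupReport:
    cluster: int
    members: list[str]
    median_mvs: float
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    excluded_censored: list[str]


def flag_disrupted_group(
    result: ConsensusResult,
    mvs: pd.Series,
    clinical: pd.DataFrame,
    lss_cutoff: float = 180.0,
) -> DisruptedGroupReport:
    """Test whether the most-disrupted cluster is enriched for short survival.

    The cluster with the highest median MVS is flagged; Fisher's exact test
    compares (in-cluster vs out) x (LSS below vs at/above the cutoff).
    Samples censored before the cutoff are uninformative about short
    survival and are excluded; samples surviving past the cutoff count as
    long regardless of the event flag.
    """
    labels = result.assignment
    if labels.nunique() < 2:
        raise DisruptError("all samples in one cluster; nothing to compare")
    samples = [s for s in labels.index if s in clinical.index and s in mvs.index]
    labels = labels.loc[samples]
    if int(clinical.loc[samples, "LSS_event"].sum()) == 0:
        raise DisruptError("no deaths; short-survival test undefined")
    medians = mvs.loc[samples].groupby(labels).median()
    target = int(medians.idxmax())
    members = [s for s in samples if labels[s] == target]

    time = clinical.loc[samples, "LSS_days"].astype(float)
    event = clinical.loc[samples, "LSS_event"].astype(bool)
    short = (time < lss_cutoff) & event
    informative = (time >= lss_cutoff) | event
    excluded = [s for s in samples if not informative[s]]
    inc = labels == target
    a = int((inc & short & informative).sum())
    b = int((inc & ~short & informative).sum())
    c = int((~inc & short & informative).sum())
    d = int((~inc & ~short & informative).sum())
    p = fisher_exact_two_sided([[a, b], [c, d]])
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return DisruptedGroupReport(
        cluster=target,
        members=members,
        median_mvs=float(medians.loc[target]),
        table=((a, b), (c, d)),
        odds_ratio=odds,
        p=p,
        excluded_censored=excluded,
    )
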