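"""Differential methylation, differential variability, and enrichment tests.

Level differences between tumors and controls are tested per sequence with a
two-sided Mann-Whitney-Wilcoxon rank-sum test (exact null when the smaller
group has <= 8 samples and the row is tie-free, normal approximation with tie
and continuity correction otherwise), Bonferroni-corrected over the number of
sequences actually tested.  Differential variability uses a two-sided
variance-ratio F test over the study's binary clinical pairings.  Fisher's
exact test (two-sided, "minlike" convention: sum of all tables whose
probability does not exceed the observed one) is computed with exact integer
hypergeometric arithmetic.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CONTROL, TUMOR, MethylationMatrix

logger = logging.getLogger(__name__)

EXACT_MAX_SMALL_GROUP = 8  # exact MWW null when min(n1, n2) <= this and no ties


class DifferentialError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def bonferroni(p: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if n_tests is None:
        n_tests = p.size
    return np.minimum(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# exact Mann-Whitney null distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _mwu_exact_counts(n1: int, n2: int) -> np.ndarray:
    """Number of label arrangements with each U value, via the classic
    Gaussian-binomial recurrence G(m, n) = G(m-1, n) + q^m G(m, n-1)."""

    @lru_cache(maxsize=None)
    def g(m: int, n: int) -> tuple[int, ...]:
        if m == 0 or n == 0:
            return (1,)
        a = g(m - 1, n)
        b = g(m, n - 1)
        out = [0] * (m * n + 1)
        for u, c in enumerate(a):
            out[u] += c
        for u, c in enumerate(b):
            out[u + m] += c
        return tuple(out)

    return np.array(g(n1, n2), dtype=float)


def mwu_exact_pvalues(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p for every U in 0..n1*n2: 2*min(P(U<=u), P(U>=u)), capped."""
    counts = _mwu_exact_counts(n1, n2)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _mwu_vectorized(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided MWW over matrices x (n_seq x n1) and y (n_seq x n2).

    Returns (U of the first group, p).  Exact tie-free null when
    min(n1, n2) <= EXACT_MAX_SMALL_GROUP; otherwise normal approximation with
    tie and continuity corrections.
    """
    n1, n2 = x.shape[1], y.shape[1]
    data = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(data, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    # tie correction term per row
    n = n1 + n2
    sorted_rows = np.sort(data, axis=1)
    tied = np.diff(sorted_rows, axis=1) == 0
    has_ties = tied.any(axis=1)

    p = np.empty(data.shape[0])
    use_exact = (min(n1, n2) <= EXACT_MAX_SMALL_GROUP) & ~has_ties
    if use_exact.any():
        table = mwu_exact_pvalues(n1, n2)
        p[use_exact] = table[np.rint(u1[use_exact]).astype(int)]
    approx = ~use_exact
    if approx.any():
        tie_term = np.zeros(data.shape[0])
        for i in np.flatnonzero(approx & has_ties):
            _, counts = np.unique(data[i], return_counts=True)
            tie_term[i] = (counts**3 - counts).sum()
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term[approx] / (n * (n - 1)))
        sigma = np.sqrt(sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.abs(u1[approx] - mu) - 0.5) / sigma  # continuity corrected
        z = np.where(sigma > 0, np.maximum(z, 0.0), np.inf)
        p[approx] = np.where(np.isfinite(z), 2.0 * stats.norm.sf(z), 1.0)
    # constant rows carry no information
    constant = (data == data[:, :1]).all(axis=1)
    p[constant] = 1.0
    return u1, np.minimum(p, 1.0)


def mww_dmr_test(matrix: MethylationMatrix, alpha: float = 0.01) -> pd.DataFrame:
    """Per-sequence tumor-vs-control rank-sum test with Bonferroni control.

    Direction is the sign of (median tumor - median control); the returned
    frame has columns statistic, p, p_bonf, effect, direction, significant,
    constant.
    """
    tumors = matrix.group_samples(TUMOR)
    controls = matrix.group_samples(CONTROL)
    if len(tumors) < 2 or len(controls) < 2:
        raise DifferentialError("both groups need >= 2 samples")
    x = matrix.values[tumors].to_numpy(dtype=float)
    y = matrix.values[controls].to_numpy(dtype=float)
    u, p = _mwu_vectorized(x, y)
    effect = np.median(x, axis=1) - np.median(y, axis=1)
    constant = (
        np.concatenate([x, y], axis=1) == np.concatenate([x, y], axis=1)[:, :1]
    ).all(axis=1)
    p_bonf = bonferroni(p, len(p))
    significant = p_bonf < alpha
    direction = np.where(effect > 0, "hyper", np.where(effect < 0, "hypo", "none"))
    out = pd.DataFrame(
        {
            "sequence_class": matrix.sequence_class.to_numpy(),
            "statistic": u,
            "p": p,
            "p_bonf": p_bonf,
            "effect": effect,
            "direction": direction,
            "significant": significant,
            "constant": constant,
        },
        index=matrix.values.index,
    )
    n_hyper = int((significant & (direction == "hyper")).sum())
    n_hypo = int((significant & (direction == "hypo")).sum())
    logger.info("MWW DMR test: %d hyper, %d hypo of %d sequences", n_hyper, n_hypo, len(p))
    return out


# ---------------------------------------------------------------------------
# differential variability F-test
# ---------------------------------------------------------------------------

#: the study's binary clinical pairings: factor -> (group A levels, group B levels)
CLINICAL_PAIRINGS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "stage": (("III", "IV"), ("V",)),
    "substage": (("a",), ("b",)),
    "extranodal": (("yes",), ("no",)),
    "treatment": (("CH",), ("CH+VAX",)),
    "steroid_pretreatment": (("yes",), ("no",)),
    "relapse_yes_no": (("before_end", "after_end"), ("none",)),
    "relapse_timing": (("before_end",), ("after_end", "none")),
}


def _binary_groups(clinical: pd.DataFrame, factor: str) -> tuple[list[str], list[str]]:
    if factor not in CLINICAL_PAIRINGS:
        raise DifferentialError(
            f"unknown clinical factor {factor!r}; known: {sorted(CLINICAL_PAIRINGS)}"
        )
    column = "relapse" if factor.startswith("relapse") else factor
    if column not in clinical.columns:
        raise DifferentialError(f"clinical table lacks column {column!r}")
    levels_a, levels_b = CLINICAL_PAIRINGS[factor]
    a = list(clinical.index[clinical[column].isin(levels_a)])
    b = list(clinical.index[clinical[column].isin(levels_b)])
    return a, b


def variability_ftest(
    matrix: MethylationMatrix,
    clinical: pd.DataFrame,
    factor: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided variance-ratio F test per sequence for one clinical pairing.

    Rows with zero variance in both groups are flagged ``degenerate`` and
    excluded from the correction (p = NaN).
    """
    group_a, group_b = _binary_groups(clinical, factor)
    group_a = [s for s in group_a if s in matrix.values.columns]
    group_b = [s for s in group_b if s in matrix.values.columns]
    if len(group_a) < 2 or len(group_b) < 2:
        raise DifferentialError(
            f"factor {factor!r}: each group needs >= 2 samples "
            f"(got {len(group_a)} vs {len(group_b)})"
        )
    xa = matrix.values[group_a].to_numpy(dtype=float)
    xb = matrix.values[group_b].to_numpy(dtype=float)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    dfa, dfb = len(group_a) - 1, len(group_b) - 1
    degenerate = (va == 0) & (vb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = va / vb
        cdf = stats.f.cdf(f, dfa, dfb)
        sf = stats.f.sf(f, dfa, dfb)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
    p[degenerate] = np.nan
    tested = int((~degenerate).sum())
    p_bonf = np.minimum(1.0, p * tested)
    more_variable = np.where(degenerate, "none", np.where(f > 1, "A", "B"))
    out = pd.DataFrame(
        {
            "factor": factor,
            "F": f,
            "p": p,
            "p_bonf": p_bonf,
            "more_variable": more_variable,
            "significant": p_bonf < alpha,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    return out


def variability_ftest_all(
    matrix: MethylationMatrix, clinical: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Run every clinical pairing; long-format concatenation."""
    frames = []
    for factor in CLINICAL_PAIRINGS:
        try:
            frames.append(variability_ftest(matrix, clinical, factor, alpha))
        except DifferentialError as exc:
            logger.warning("skipping factor %s: %s", factor, exc)
    if not frames:
        raise DifferentialError("no clinical pairing had two viable groups")
    return pd.concat(frames)


# ---------------------------------------------------------------------------
# multivariate linear model
# ---------------------------------------------------------------------------

def _design_matrix(clinical: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=clinical.index, name="intercept")]
    for cov in covariates:
        if cov not in clinical.columns:
            raise DifferentialError(f"unknown covariate {cov!r}")
        col = clinical[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
    return pd.concat(parts, axis=1)


def multivariate_lm(
    matrix: MethylationMatrix,
    clinical: pd.DataFrame,
    covariates: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-sequence OLS of methylation on the covariate set (tumors only).

    Reports the overall-model F p-value (Bonferroni-corrected across
    sequences) plus the fitted coefficients.  Categorical covariates are
    dummy-coded against their first level.
    """
    if not covariates:
        raise DifferentialError("covariates must be non-empty")
    samples = [s for s in matrix.values.columns if s in clinical.index]
    if len(samples) < 3:
        raise DifferentialError("need >= 3 samples with clinical data")
    design = _design_matrix(clinical.loc[samples], covariates)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            design.columns[j]
            for j in range(1, k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DifferentialError(f"rank-deficient design; collinear columns: {collinear}")
    if n <= k:
        raise DifferentialError("more model terms than samples")
    Y = matrix.values[samples].to_numpy(dtype=float).T  # samples x sequences
    beta_hat, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta_hat
    resid = Y - fitted
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df_model, df_resid = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df_model) / (rss / df_resid)
    p = stats.f.sf(f, df_model, df_resid)
    p = np.where(tss == 0, 1.0, p)
    p_bonf = bonferroni(p, len(p))
    out = pd.DataFrame(
        {"F": f, "p": p, "p_bonf": p_bonf, "significant": p_bonf < alpha},
        index=matrix.values.index,
    )
    coef = pd.DataFrame(
        beta_hat.T, index=matrix.values.index, columns=[f"coef_{c}" for c in design.columns]
    )
    return pd.concat([out, coef], axis=1)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, minlike, exact integer arithmetic)
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher p for a 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the same margins
    whose probability is <= the observed table's ("minlike" convention).
    Probability comparisons use exact integer numerators, so ties are handled
    exactly.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise DifferentialError("table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    total = comb(n, c1)
    return float(sum(v for v in nums if v <= obs) / total)


def fisher_pvalues_by_margins(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p for every admissible a given fixed margins."""
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    total = comb(n, c1)
    return np.array(
        [sum(v for v in nums if v <= obs) / total for obs in nums], dtype=float
    )


def location_enrichment(
    dmr: pd.DataFrame,
    annotation: pd.DataFrame,
    direction: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Genomic-location enrichment of significant DMRs in one direction.

    Per location category: 2x2 Fisher of (overlaps category) x (significant
    in the requested direction), background = all tested sequences.  A
    multi-label sequence counts once in every category it overlaps.
    """
    if direction not in ("hyper", "hypo"):
        raise DifferentialError("direction must be 'hyper' or 'hypo'")
    missing = dmr.index.difference(annotation.index)
    if len(missing):
        raise DifferentialError(
            f"annotation does not cover tested sequences, e.g. {list(missing)[:3]}"
        )
    ann = annotation.loc[dmr.index]
    hit = (dmr["significant"] & (dmr["direction"] == direction)).to_numpy()
    loc_sets = ann["locations"].str.split(",")
    categories = sorted({loc for locs in loc_sets for loc in locs if loc})
    rows = []
    for cat in categories:
        in_cat = loc_sets.apply(lambda locs: cat in locs).to_numpy()
        a = int((in_cat & hit).sum())
        b = int((in_cat & ~hit).sum())
        c = int((~in_cat & hit).sum())
        d = int((~in_cat & ~hit).sum())
        if a + b == 0:
            logger.warning("location %s: empty category, skipped", cat)
            continue
        p = fisher_exact_two_sided([[a, b], [c, d]])
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((cat, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["location", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("location")
    out["p_bonf"] = np.minimum(1.0, out["p"] * len(out))
    out["enriched"] = (out["p_bonf"] < alpha) & (out["odds_ratio"] > 1)
    return out


def beta_category_fisher(
    beta_matrix: MethylationMatrix, alpha: float = 0.01, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-sequence Fisher test on dichotomized beta values.

    Each sample is classified methylated (beta >= 0.5) or unmethylated; the
    tumor x category 2x2 table is tested with the exact two-sided Fisher
    test.  Margin-indexed memoization keeps the genome-wide pass cheap.
    """
    if beta_matrix.scale != "beta":
        raise DifferentialError("beta_category_fisher expects a beta-scale matrix")
    tumors = beta_matrix.group_samples(TUMOR)
    controls = beta_matrix.group_samples(CONTROL)
    n1, n2 = len(tumors), len(controls)
    meth = beta_matrix.values.to_numpy() >= threshold
    t_idx = beta_matrix.values.columns.get_indexer(tumors)
    c_idx = beta_matrix.values.columns.get_indexer(controls)
    a = meth[:, t_idx].sum(axis=1)  # methylated tumors
    k_tot = a + meth[:, c_idx].sum(axis=1)

    @lru_cache(maxsize=None)
    def margin_p(c1: int) -> np.ndarray:
        return fisher_pvalues_by_margins(n1, n2, c1)

    p = np.empty(len(a))
    for i, (ai, ki) in enumerate(zip(a, k_tot)):
        lo = max(0, ki - n2)
        p[i] = margin_p(int(ki))[int(ai) - lo]
    p_bonf = bonferroni(p, len(p))
    frac_t = a / n1
    frac_c = (k_tot - a) / n2
    direction = np.where(frac_t > frac_c, "hyper", np.where(frac_t < frac_c, "hypo", "none"))
    return pd.DataFrame(
        {
            "methylated_tumors": a,
            "methylated_controls": k_tot - a,
            "p": p,
            "p_bonf": p_bonf,
            "direction": direction,
            "significant": p_bonf < alpha,
        },
        index=beta_matrix.values.index,
    )
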