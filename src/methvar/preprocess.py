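"""Probe-level preprocessing for two-color methylation-enrichment arrays.

Order of operations: intensity-dependent (dye-bias) loess correction per
array, array-level quality control, between-sample quantile normalization,
probe-to-sequence median aggregation, and the low-methylation enrichment
filter on the beta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

TUMOR = "tumor"
CONTROL = "control"

MIN_PROBES_FOR_LOESS = 50


class PreprocessError(ValueError):
    pass


@dataclass
class ProbeTable:
    """Probe-level log2 ratios (methylation-enriched channel over input).

    ``log2_ratio`` and ``intensity`` are probes x samples DataFrames sharing
    index and columns; ``probe_to_sequence`` maps every probe to exactly one
    target sequence; ``sample_groups`` labels each sample tumor or control.
    """

    log2_ratio: pd.DataFrame
    intensity: pd.DataFrame
    probe_to_sequence: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.log2_ratio.index.has_duplicates:
            dups = self.log2_ratio.index[self.log2_ratio.index.duplicated()][:3]
            raise PreprocessError(f"duplicate probe ids: {list(dups)}")
        if self.log2_ratio.columns.has_duplicates:
            raise PreprocessError("duplicate sample ids in probe table")
        if not self.log2_ratio.index.equals(self.intensity.index) or not (
            self.log2_ratio.columns.equals(self.intensity.columns)
        ):
            raise PreprocessError("log2_ratio and intensity must be aligned")
        if not self.log2_ratio.index.equals(self.probe_to_sequence.index):
            raise PreprocessError("probe_to_sequence must cover every probe")
        missing = self.log2_ratio.columns.difference(self.sample_groups.index)
        if len(missing):
            raise PreprocessError(f"samples without group label: {list(missing)[:3]}")
        self.sample_groups = self.sample_groups.loc[self.log2_ratio.columns]
        self.sample_groups.index.name = "sample_id"

    @property
    def samples(self) -> list[str]:
        return list(self.log2_ratio.columns)

    def subset_samples(self, keep: Iterable[str]) -> "ProbeTable":
        keep = [s for s in self.samples if s in set(keep)]
        return ProbeTable(
            log2_ratio=self.log2_ratio[keep],
            intensity=self.intensity[keep],
            probe_to_sequence=self.probe_to_sequence,
            sample_groups=self.sample_groups.loc[keep],
        )


@dataclass
class MethylationMatrix:
    """Sequence x sample methylation levels with group labels.

    ``scale`` is ``"log2"`` (log2 enrichment ratio) or ``"beta"`` (the
    logistic transform of it, a methylation proportion on (0, 1)).
    """

    values: pd.DataFrame
    sequence_class: pd.Series  # 'CpG' | 'CDS'
    sample_groups: pd.Series
    scale: str = "log2"
    normalized: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise PreprocessError("methylation matrix contains missing values")
        self.sequence_class = self.sequence_class.loc[self.values.index]
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        self.sample_groups.index.name = "sample_id"

    def group_samples(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def subset_samples(self, keep: Iterable[str]) -> "MethylationMatrix":
        keep = [s for s in self.values.columns if s in set(keep)]
        return replace(self, values=self.values[keep], sample_groups=self.sample_groups.loc[keep])


# ---------------------------------------------------------------------------
# dye-bias loess correction
# ---------------------------------------------------------------------------

def loess_dye_correct(probes: ProbeTable, span: float = 0.3) -> ProbeTable:
    """Remove the intensity-dependent dye bias from each array.

    Per array, a loess curve of log2 ratio versus mean log2 intensity is
    fitted and subtracted; the residuals are re-centered to the array median
    so the correction does not shift genuinely non-zero methylation ratios.
    """
    if not 0 < span <= 1:
        raise PreprocessError(f"span must be in (0, 1], got {span}")
    n = probes.log2_ratio.shape[0]
    if n < MIN_PROBES_FOR_LOESS:
        raise PreprocessError(
            f"need >= {MIN_PROBES_FOR_LOESS} probes per array for loess, got {n}"
        )
    corrected = probes.log2_ratio.copy()
    for sample in probes.samples:
        m = probes.log2_ratio[sample].to_numpy(dtype=float)
        a = probes.intensity[sample].to_numpy(dtype=float)
        delta = 0.01 * (a.max() - a.min())
        fit = lowess(m, a, frac=span, delta=delta, return_sorted=False)
        corrected[sample] = m - fit + np.median(m)
    return replace(probes, log2_ratio=corrected)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization (ties share averaged ranks).

    After normalization every column's sorted vector equals the across-sample
    mean of sorted vectors, and within-column rank order is preserved.
    """
    if values.shape[1] < 2:
        raise PreprocessError("quantile normalization requires >= 2 samples")
    x = values.to_numpy(dtype=float)
    n = x.shape[0]
    sorted_x = np.sort(x, axis=0)
    if (sorted_x == sorted_x[:, :1]).all():
        # marginals already identical (e.g. re-normalization): the mean of
        # identical columns is that column, computed exactly so the
        # transform is idempotent to the bit
        reference = sorted_x[:, 0]
    else:
        reference = sorted_x.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        idx = ranks - 1.0
        i0 = np.floor(idx).astype(int)
        frac = idx - i0
        i1 = np.minimum(i0 + 1, n - 1)
        # integer ranks index the reference exactly (keeps the map idempotent
        # to the bit); averaged tie ranks interpolate between neighbours
        interp = (1.0 - frac) * reference[i0] + frac * reference[i1]
        out[:, j] = np.where(frac == 0.0, reference[i0], interp)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize_probes(probes: ProbeTable) -> ProbeTable:
    return replace(probes, log2_ratio=quantile_normalize(probes.log2_ratio))


# ---------------------------------------------------------------------------
# array quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCCriteria:
    """Array-level outlier screens on the log2-ratio distribution.

    An array is dropped when the robust z-score (deviation from the
    across-array median in across-array MAD units) of its own median or of
    its spread (MAD) exceeds ``max_robust_z`` AND the deviation is also
    practically large: the location by more than ``min_median_shift`` log2
    units, the spread by more than a ``min_relative_spread`` fraction of the
    typical spread.  The magnitude floors keep biological group differences
    between otherwise tight arrays from tripping the screen.
    """

    max_robust_z: float = 5.0
    min_median_shift: float = 0.5
    min_relative_spread: float = 0.5
    enabled: bool = True


@dataclass
class QCReport:
    kept: list[str]
    dropped: list[str]
    metrics: pd.DataFrame


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / (1.4826 * mad)


def qc_filter_arrays(
    probes: ProbeTable, criteria: QCCriteria = QCCriteria()
) -> tuple[ProbeTable, QCReport]:
    """Drop outlier arrays; returns the filtered table plus a QC report."""
    x = probes.log2_ratio.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med[None, :]), axis=0)
    metrics = pd.DataFrame(
        {"median": med, "mad": mad}, index=pd.Index(probes.samples, name="sample_id")
    )
    metrics["z_median"] = _robust_z(med)
    metrics["z_mad"] = _robust_z(mad)
    if not criteria.enabled:
        return probes, QCReport(kept=probes.samples, dropped=[], metrics=metrics)
    typical_mad = np.median(mad)
    bad_median = (metrics["z_median"].abs() > criteria.max_robust_z) & (
        (metrics["median"] - np.median(med)).abs() > criteria.min_median_shift
    )
    bad_mad = (metrics["z_mad"].abs() > criteria.max_robust_z) & (
        (metrics["mad"] - typical_mad).abs() > criteria.min_relative_spread * typical_mad
    )
    bad = bad_median | bad_mad
    dropped = list(metrics.index[bad])
    kept = [s for s in probes.samples if s not in set(dropped)]
    if not kept:
        raise PreprocessError("all arrays failed QC")
    for s in dropped:
        logger.warning("QC: dropping array %s (robust z beyond %.1f)", s, criteria.max_robust_z)
    return probes.subset_samples(kept), QCReport(kept=kept, dropped=dropped, metrics=metrics)


# ---------------------------------------------------------------------------
# probe -> sequence aggregation
# ---------------------------------------------------------------------------

def aggregate_to_sequences(
    probes: ProbeTable, sequence_class: pd.Series | None = None
) -> MethylationMatrix:
    """Per (sequence, sample) cell: median of the sequence's probe signals."""
    grouped = probes.log2_ratio.groupby(probes.probe_to_sequence, sort=True).median()
    grouped.index.name = "sequence_id"
    if sequence_class is None:
        sequence_class = pd.Series("CpG", index=grouped.index, name="sequence_class")
    else:
        missing = grouped.index.difference(sequence_class.index)
        if len(missing):
            raise PreprocessError(f"sequences without class annotation: {list(missing)[:3]}")
        sequence_class = sequence_class.loc[grouped.index]
    return MethylationMatrix(
        values=grouped,
        sequence_class=sequence_class,
        sample_groups=probes.sample_groups,
        scale="log2",
        normalized=True,
    )


# ---------------------------------------------------------------------------
# beta transform and the low-methylation filter
# ---------------------------------------------------------------------------

def beta_transform(matrix: MethylationMatrix) -> MethylationMatrix:
    """Map log2 ratios m onto beta = 2^m / (2^m + 1), a proportion in (0, 1).

    The base-2 logistic sends m = 0 (equal channels) to beta = 0.5 and is the
    inverse of beta -> log2(beta / (1 - beta)).
    """
    if matrix.scale != "log2":
        raise PreprocessError("beta_transform expects a log2-scale matrix")
    m = matrix.values.to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-m))
    return replace(
        matrix,
        values=pd.DataFrame(beta, index=matrix.values.index, columns=matrix.values.columns),
        scale="beta",
    )


def logit2(beta_matrix: MethylationMatrix) -> MethylationMatrix:
    """Inverse of :func:`beta_transform`."""
    if beta_matrix.scale != "beta":
        raise PreprocessError("logit2 expects a beta-scale matrix")
    b = beta_matrix.values.to_numpy(dtype=float)
    m = np.log2(b) - np.log2(1.0 - b)
    return replace(
        beta_matrix,
        values=pd.DataFrame(m, index=beta_matrix.values.index, columns=beta_matrix.values.columns),
        scale="log2",
    )


@dataclass
class FilterReport:
    retained: int
    dropped: int
    retained_by_class: dict[str, int]
    dropped_by_class: dict[str, int]


def filter_low_methylation(
    matrix: MethylationMatrix,
    enrich_threshold: float = 0.5,
    min_fraction: float = 0.25,
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop sequences with enriched methylation in too few samples.

    A sample is "enriched" at a sequence when its beta value is >=
    ``enrich_threshold``; a sequence is retained iff the enriched fraction
    reaches ``min_fraction`` in the tumor group OR in the control group.
    Accepts a log2-scale matrix (transformed internally) or a beta-scale one.
    """
    beta = matrix if matrix.scale == "beta" else beta_transform(matrix)
    groups = (TUMOR, CONTROL)
    for g in groups:
        if not beta.group_samples(g):
            raise PreprocessError(f"empty {g} group")
    keep = np.zeros(beta.values.shape[0], dtype=bool)
    for g in groups:
        cols = beta.group_samples(g)
        frac = (beta.values[cols].to_numpy() >= enrich_threshold).mean(axis=1)
        keep |= frac >= min_fraction
    kept_index = matrix.values.index[keep]
    cls = matrix.sequence_class
    report = FilterReport(
        retained=int(keep.sum()),
        dropped=int((~keep).sum()),
        retained_by_class=cls.loc[kept_index].value_counts().to_dict(),
        dropped_by_class=cls.loc[matrix.values.index[~keep]].value_counts().to_dict(),
    )
    logger.info(
        "low-methylation filter: retained %d, dropped %d (%s)",
        report.retained,
        report.dropped,
        report.retained_by_class,
    )
    filtered = replace(
        matrix,
        values=matrix.values.loc[kept_index],
        sequence_class=cls.loc[kept_index],
        filtered=True,
    )
    return filtered, report


def preprocess_pipeline(
    probes: ProbeTable,
    sequence_class: pd.Series | None = None,
    span: float = 0.3,
    qc: QCCriteria = QCCriteria(),
    enrich_threshold: float = 0.5,
    min_fraction: float = 0.25,
    correct_dye_bias: bool = True,
) -> tuple[MethylationMatrix, MethylationMatrix, QCReport, FilterReport]:
    """loess -> QC -> quantile -> aggregate -> filter.

    Returns ``(filtered log2 matrix, filtered beta matrix, qc report,
    filter report)``.
    """
    if correct_dye_bias:
        probes = loess_dye_correct(probes, span=span)
    probes, qc_report = qc_filter_arrays(probes, qc)
    probes = quantile_normalize_probes(probes)
    matrix = aggregate_to_sequences(probes, sequence_class)
    filtered, filt_report = filter_low_methylation(
        matrix, enrich_threshold=enrich_threshold, min_fraction=min_fraction
    )
    beta = beta_transform(filtered)
    return filtered, beta, qc_report, filt_report
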