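"""Synthetic two-color CpG methylation-array experiments with known ground truth.

Emulates a methylation-enrichment array study of canine diffuse large B-cell
lymphoma: ~170,000 probes tiling ~36,807 CpG regions and 672 coding sequences,
37 tumor and 7 control arrays, planted hyper-/hypo-methylated sequences,
planted tumor subgroups with their own methylation signatures, a planted
gradient of genome-wide methylation disruption, and censored Weibull survival
times whose hazard depends on subgroup and disruption.

The generative model for a probe-level log2 ratio (methylation-enriched
channel over input) is additive:

    M[p, j] = b[s(p)] + DMR effect + subgroup signature + probe offset
              + dye bias(A[p, j]) + technical noise

where ``b[s]`` is a bimodal per-sequence baseline (unmethylated vs methylated
mode, mimicking CpG-island biology), the DMR effect at planted sequences is
``sign * effect_size * d[j]`` for tumors (``d[j]`` the sample's disruption
multiplier), subgroup signatures are Helmert-contrast mean shifts over the
planted subtypes, and the dye bias is a smooth low-order polynomial in the
probe's mean log2 intensity ``A[p, j]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_experiment",
    "write_fixtures",
    "small_config",
    "study_config",
]

TUMOR = "tumor"
CONTROL = "control"

#: Fraction of hypo-methylated sequences planted in coding regions rather than
#: CpG regions (the study observed 43 of 183 hypo calls in CDS).
_HYPO_CDS_FRACTION = 43.0 / 183.0

_LOCATIONS = (
    "promoter",
    "5'UTR",
    "upstream",
    "exon",
    "intron",
    "3'UTR",
    "downstream",
    "intergenic",
)


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class SurvivalParams:
    """Weibull proportional-hazards survival model for the tumor cohort.

    ``scale_days``/``shape`` parameterize the baseline survivor function
    S0(t) = exp(-(t/scale)^shape); a sample with hazard multiplier m has
    S(t) = S0(t)^m.  The multiplier is the product of the subgroup hazard
    and the disruption multiplier raised to ``disruption_hazard_exp``, so
    heavily disrupted tumors die sooner.  Censoring is independent: with
    probability ``censor_rate`` a sample is censored uniformly before its
    event time.
    """

    scale_days: float = 600.0
    shape: float = 1.3
    hazard_multipliers: tuple[float, ...] = (1.0, 1.7, 3.0)
    disruption_hazard_exp: float = 1.0
    censor_rate: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the study design: 37 tumors vs 7 control lymph nodes,
    36,807 CpG regions at ~2.8 probes each and 672 CDS at ~101 probes each
    (102,000 + 68,000 ≈ 170,000 probes), with planted differential counts at
    full scale of ≈1,011 hyper-methylated CpG regions and ≈183 hypo-methylated
    sequences.  ``small_config()`` gives a ~2,000-sequence version for fast
    tests.
    """

    n_tumors: int = 37
    n_controls: int = 7
    n_cpg_sequences: int = 36807
    n_cds_sequences: int = 672
    probes_per_cpg: float = 102000 / 36807  # Poisson mean, floored at 1
    probes_per_cds: float = 68000 / 672
    frac_hyper: float = 0.02697  # of all sequences -> ~1,011 at full scale
    frac_hypo: float = 0.004882  # -> ~183 at full scale
    effect_size: float = 1.8  # log2-ratio shift at planted DMRs
    dmr_response_jitter: float = 0.4  # lognormal sigma of per-(sequence, sample) response
    frac_unstable: float = 0.075  # epigenetically unstable sequences (disruption pool)
    unstable_scale: float = 1.2  # base sd of unstable deviations at multiplier 1
    noise_sd: float = 0.25  # per-probe technical noise
    probe_offset_sd: float = 0.15  # fixed per-probe offset within a sequence
    biological_sd: float = 0.30  # per (sequence, sample) deviation
    dye_bias_amplitude: float = 0.3
    # bimodal baseline: methylated mode vs unmethylated mode
    frac_high_baseline: float = 0.78
    high_baseline_mean: float = 1.5
    high_baseline_sd: float = 0.5
    low_baseline_mean: float = -1.2
    low_baseline_sd: float = 0.35
    n_subgroups: int = 3
    subgroup_signature_size: int = 250  # sequences per Helmert contrast
    subgroup_effect: float = 1.5
    disruption_levels: tuple[float, ...] | None = None  # per-tumor multipliers
    n_disrupted: int = 6  # high-disruption tumors when levels not given
    disrupted_multiplier: float = 3.5
    disruption_gradient: tuple[float, float] = (0.7, 1.8)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tumors": self.n_tumors,
            "n_controls": self.n_controls,
            "n_cpg_sequences": self.n_cpg_sequences,
            "n_subgroups": self.n_subgroups,
        }
        for name, value in counts.items():
            if value <= 0:
                raise SimulationError(f"{name} must be positive, got {value}")
        if self.n_cds_sequences < 0:
            raise SimulationError("n_cds_sequences must be non-negative")
        if not (0 <= self.frac_hyper and 0 <= self.frac_hypo):
            raise SimulationError("planted fractions must be non-negative")
        if self.frac_hyper + self.frac_hypo >= 1:
            raise SimulationError("frac_hyper + frac_hypo must be < 1")
        if self.disruption_levels is not None and len(self.disruption_levels) != self.n_tumors:
            raise SimulationError(
                "disruption_levels must have one multiplier per tumor "
                f"({self.n_tumors}), got {len(self.disruption_levels)}"
            )

    @property
    def n_sequences(self) -> int:
        return self.n_cpg_sequences + self.n_cds_sequences


def study_config(**overrides) -> SimulationConfig:
    """Full study-scale configuration (the dataclass defaults)."""
    return SimulationConfig(**overrides)


def null_config(n_sequences: int = 10000, **overrides) -> SimulationConfig:
    """No planted structure at all: tumors and controls share one distribution.

    Used for type-I-error calibration of the differential tests.
    """
    params = dict(
        n_cpg_sequences=n_sequences,
        n_cds_sequences=0,
        effect_size=0.0,
        frac_hyper=0.0,
        frac_hypo=0.0,
        frac_unstable=0.0,
        n_subgroups=1,
        subgroup_signature_size=0,
        disruption_levels=tuple([1.0] * overrides.get("n_tumors", 37)),
        dye_bias_amplitude=0.0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def small_config(**overrides) -> SimulationConfig:
    """~2,000 sequences / ~6,200 probes; keeps the suite fast.

    Planted fractions are raised so the small experiment still carries
    ~54 hyper and ~10 hypo sequences plus 3 subgroups of meaningful size.
    """
    params = dict(
        n_cpg_sequences=1960,
        n_cds_sequences=40,
        probes_per_cds=6.0,
        frac_hyper=0.027,
        frac_hypo=0.005,
        subgroup_signature_size=40,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """What was planted: the answer key for every downstream stage."""

    hyper_ids: set[str]
    hypo_ids: set[str]
    subgroup_labels: dict[str, int]  # tumor sample -> subtype id (0-based)
    signature_map: dict[int, set[str]]  # subtype -> informative sequence ids
    signature_ids: set[str]  # union over contrasts
    unstable_ids: set[str]  # disruption-responsive pool
    disruption_multipliers: dict[str, float]
    disruption_rank: list[str]  # tumors, most disrupted first

    def __post_init__(self) -> None:
        if self.hyper_ids & self.hypo_ids:
            raise SimulationError("hyper and hypo sets must be disjoint")


def _helmert_contrasts(k: int) -> np.ndarray:
    """(k-1) x k Helmert-style contrast rows, each with max |entry| = 1.

    Row c compares subgroup c+1 against the mean of subgroups 0..c; rows are
    mutually orthogonal, which keeps the planted subtype signatures aligned
    with distinct principal components.
    """
    rows = []
    for c in range(1, k):
        row = np.zeros(k)
        row[:c] = 1.0 / c
        row[c] = -1.0
        rows.append(row)
    return np.asarray(rows)


def _default_disruption(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Gradient of multipliers plus a high-disruption block, randomly assigned."""
    if config.disruption_levels is not None:
        return np.asarray(config.disruption_levels, dtype=float)
    n_high = min(config.n_disrupted, config.n_tumors)
    lo, hi = config.disruption_gradient
    base = np.linspace(lo, hi, config.n_tumors - n_high) if config.n_tumors > n_high else np.empty(0)
    levels = np.concatenate([base, np.full(n_high, config.disrupted_multiplier)])
    return rng.permutation(levels)


def _simulate_annotation(
    seq_ids: list[str], seq_class: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(seq_ids)
    chrom = rng.integers(1, 39, size=n)  # autosomes only; chrX excluded by design
    start = rng.integers(10_000, 60_000_000, size=n)
    length = rng.integers(150, 1500, size=n)
    is_cds = seq_class == "CDS"
    # multi-label genomic locations; CDS always overlaps an exon
    probs = np.array([0.18, 0.08, 0.14, 0.22, 0.25, 0.07, 0.10, 0.18])
    picks = rng.random((n, len(_LOCATIONS))) < probs
    picks[is_cds, _LOCATIONS.index("exon")] = True
    none = ~picks.any(axis=1)
    picks[none, _LOCATIONS.index("intergenic")] = True
    locations = [
        ",".join(loc for loc, hit in zip(_LOCATIONS, row) if hit) for row in picks
    ]
    has_gene = rng.random(n) < 0.7
    genes = np.where(has_gene, [f"GENE{i:05d}" for i in range(n)], "")
    return pd.DataFrame(
        {
            "chromosome": [f"chr{c}" for c in chrom],
            "start": start,
            "end": start + length,  # 1-based inclusive
            "sequence_class": seq_class,
            "locations": locations,
            "gene_symbol": genes,
        },
        index=pd.Index(seq_ids, name="sequence_id"),
    )


def _simulate_clinical(
    tumor_ids: list[str],
    subgroup: np.ndarray,
    disruption: np.ndarray,
    params: SurvivalParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(tumor_ids)
    stage = rng.choice(["III", "IV", "V"], size=n, p=[3 / 39, 16 / 39, 20 / 39])
    substage = rng.choice(["a", "b"], size=n, p=[27 / 39, 12 / 39])
    extranodal = rng.choice(["yes", "no"], size=n, p=[0.4, 0.6])
    treatment = rng.choice(["CH", "CH+VAX"], size=n, p=[14 / 37, 23 / 37])
    steroid = rng.choice(["yes", "no"], size=n, p=[15 / 39, 24 / 39])
    relapse = rng.choice(
        ["before_end", "after_end", "none"], size=n, p=[20 / 39, 14 / 39, 5 / 39]
    )
    age = np.clip(rng.normal(7.5, 2.4, size=n), 2.0, 14.0).round(1)
    weight = np.clip(rng.lognormal(np.log(26.0), 0.45, size=n), 5.0, 75.0).round(1)

    mult = np.asarray(params.hazard_multipliers, dtype=float)
    if len(mult) < subgroup.max() + 1:
        mult = np.resize(mult, subgroup.max() + 1)
    hazard = mult[subgroup] * disruption ** params.disruption_hazard_exp
    # Weibull PH: T = scale * (E / m)^(1/shape), E ~ Exp(1)
    exp_draw = rng.exponential(1.0, size=n)
    lss = params.scale_days * (exp_draw / hazard) ** (1.0 / params.shape)
    ttp = lss * rng.uniform(0.3, 0.9, size=n)
    censored = rng.random(n) < params.censor_rate
    cens_frac = rng.uniform(0.5, 1.0, size=n)
    lss_time = np.where(censored, lss * cens_frac, lss)
    ttp_time = np.where(censored, ttp * cens_frac, ttp)
    return pd.DataFrame(
        {
            "stage": stage,
            "substage": substage,
            "extranodal": extranodal,
            "treatment": treatment,
            "steroid_pretreatment": steroid,
            "relapse": relapse,
            "age": age,
            "weight": weight,
            "TTP_days": np.maximum(ttp_time, 1.0).round(1),
            "TTP_event": ~censored,
            "LSS_days": np.maximum(lss_time, 1.0).round(1),
            "LSS_event": ~censored,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )


def simulate_experiment(config: SimulationConfig):
    """Generate a full synthetic experiment.

    Returns ``(probes, annotation, clinical, truth)`` where ``probes`` is a
    :class:`methvar.preprocess.ProbeTable`, ``annotation`` a per-sequence
    DataFrame, ``clinical`` a per-tumor DataFrame and ``truth`` the
    :class:`GroundTruth` answer key.  The same seed yields bitwise-identical
    output.
    """
    from .preprocess import ProbeTable  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_seq = config.n_sequences
    width = max(5, len(str(n_seq)))
    seq_ids = [f"SEQ{i:0{width}d}" for i in range(n_seq)]
    seq_class = np.where(np.arange(n_seq) < config.n_cpg_sequences, "CpG", "CDS")
    is_cpg = seq_class == "CpG"

    # --- per-sequence baseline: bimodal (methylated vs unmethylated mode) ---
    high = rng.random(n_seq) < config.frac_high_baseline
    baseline = np.where(
        high,
        rng.normal(config.high_baseline_mean, config.high_baseline_sd, n_seq),
        rng.normal(config.low_baseline_mean, config.low_baseline_sd, n_seq),
    )

    # --- plant DMRs: hyper from unmethylated CpG, hypo from methylated ---
    n_hyper = int(round(config.frac_hyper * n_seq))
    n_hypo = int(round(config.frac_hypo * n_seq))
    n_hypo_cds = int(round(n_hypo * _HYPO_CDS_FRACTION)) if config.n_cds_sequences else 0
    n_hypo_cpg = n_hypo - n_hypo_cds

    low_cpg = np.flatnonzero(~high & is_cpg)
    high_cpg = np.flatnonzero(high & is_cpg)
    high_cds = np.flatnonzero(high & ~is_cpg)
    if n_hyper > low_cpg.size or n_hypo_cpg > high_cpg.size or n_hypo_cds > high_cds.size:
        raise SimulationError("not enough eligible sequences for the planted DMR counts")
    hyper_idx = rng.choice(low_cpg, size=n_hyper, replace=False)
    hypo_idx = np.concatenate(
        [
            rng.choice(high_cpg, size=n_hypo_cpg, replace=False),
            rng.choice(high_cds, size=n_hypo_cds, replace=False),
        ]
    ).astype(int)

    effect_sign = np.zeros(n_seq)
    effect_sign[hyper_idx] = 1.0
    effect_sign[hypo_idx] = -1.0

    # --- subgroups: Helmert-contrast signatures over non-DMR methylated CpG ---
    n_tum, n_ctl = config.n_tumors, config.n_controls
    k = config.n_subgroups
    subgroup = rng.permutation(np.arange(n_tum) % k)
    contrasts = _helmert_contrasts(k)  # (k-1, k)
    eligible = np.setdiff1d(high_cpg, np.concatenate([hyper_idx, hypo_idx]))
    signature_effect = np.zeros((n_seq, n_tum))
    signature_map: dict[int, set[str]] = {g: set() for g in range(k)}
    signature_ids: set[str] = set()
    if k > 1:
        need = config.subgroup_signature_size * (k - 1)
        if need > eligible.size:
            raise SimulationError("not enough sequences for the subgroup signatures")
        chosen = rng.choice(eligible, size=need, replace=False)
        for c in range(k - 1):
            rows = chosen[c * config.subgroup_signature_size : (c + 1) * config.subgroup_signature_size]
            amp = config.subgroup_effect * (1.0 - 0.2 * c)  # break PC degeneracy
            signature_effect[rows[:, None], np.arange(n_tum)] = amp * contrasts[c][subgroup]
            ids = {seq_ids[i] for i in rows}
            signature_ids |= ids
            for g in range(k):
                if contrasts[c][g] != 0:
                    signature_map[g] |= ids

    # --- disruption multipliers ---
    disruption = _default_disruption(config, rng)
    if disruption.size != n_tum or np.any(disruption <= 0):
        raise SimulationError("disruption multipliers must be positive, one per tumor")

    # --- sequence x sample mean structure ---
    tumor_ids = [f"T{i + 1:02d}" for i in range(n_tum)]
    control_ids = [f"C{i + 1:02d}" for i in range(n_ctl)]
    sample_ids = tumor_ids + control_ids
    # epigenetically unstable pool: per-(sequence, tumor) deviations whose
    # spread scales with the sample's disruption multiplier.  Counts/extents
    # of deviating loci per sample survive quantile normalization, unlike a
    # pure magnitude scaling of shared differential sites.
    planted = np.concatenate([hyper_idx, hypo_idx])
    if k > 1:
        planted = np.concatenate([planted, chosen])
    free = np.setdiff1d(np.arange(n_seq), planted)
    n_unstable = int(round(config.frac_unstable * n_seq))
    if n_unstable > free.size:
        raise SimulationError("not enough sequences for the unstable pool")
    unstable_idx = rng.choice(free, size=n_unstable, replace=False)
    unstable_effect = np.zeros((n_seq, n_tum))
    if n_unstable:
        u_s = rng.uniform(0.5, 1.5, size=n_unstable)
        z = rng.normal(0.0, 1.0, size=(n_unstable, n_tum))
        unstable_effect[unstable_idx, :] = (
            config.unstable_scale * u_s[:, None] * disruption[None, :] * z
        )

    means = np.tile(baseline[:, None], (1, n_tum + n_ctl))
    # planted DMRs shift consistently in every tumor, with lognormal (mean-1)
    # per-(sequence, sample) jitter in the response magnitude
    dmr_rows = np.flatnonzero(effect_sign != 0)
    response = np.ones((n_seq, n_tum))
    if config.dmr_response_jitter > 0 and dmr_rows.size:
        sig = config.dmr_response_jitter
        response[dmr_rows, :] = rng.lognormal(
            -0.5 * sig**2, sig, size=(dmr_rows.size, n_tum)
        )
    means[:, :n_tum] += (
        effect_sign[:, None] * config.effect_size * response
        + signature_effect
        + unstable_effect
    )
    means += rng.normal(0.0, config.biological_sd, size=means.shape)

    # --- probe layer ---
    probes_per = np.maximum(
        1,
        np.where(
            is_cpg,
            rng.poisson(config.probes_per_cpg, n_seq),
            rng.poisson(config.probes_per_cds, n_seq),
        ),
    )
    probe_seq_idx = np.repeat(np.arange(n_seq), probes_per)
    n_probes = probe_seq_idx.size
    within = np.concatenate([np.arange(c) for c in probes_per])
    probe_ids = [f"{seq_ids[s]}_P{w + 1}" for s, w in zip(probe_seq_idx, within)]

    ratio = means[probe_seq_idx, :].copy()
    ratio += rng.normal(0.0, config.probe_offset_sd, size=n_probes)[:, None]
    ratio += rng.normal(0.0, config.noise_sd, size=ratio.shape)

    # intensities and smooth intensity-dependent dye bias, per array
    probe_intensity = rng.normal(10.0, 1.2, size=n_probes)
    intensity = probe_intensity[:, None] + rng.normal(0.0, 0.3, size=ratio.shape)
    if config.dye_bias_amplitude > 0:
        z = (intensity - 10.0) / 1.2
        lin = rng.uniform(-1.0, 1.0, size=ratio.shape[1])
        quad = rng.uniform(-0.6, 0.6, size=ratio.shape[1])
        ratio += config.dye_bias_amplitude * (lin[None, :] * z + quad[None, :] * z**2)

    probe_index = pd.Index(probe_ids, name="probe_id")
    probes = ProbeTable(
        log2_ratio=pd.DataFrame(ratio, index=probe_index, columns=sample_ids),
        intensity=pd.DataFrame(intensity, index=probe_index, columns=sample_ids),
        probe_to_sequence=pd.Series(
            [seq_ids[s] for s in probe_seq_idx], index=probe_index, name="sequence_id"
        ),
        sample_groups=pd.Series(
            [TUMOR] * n_tum + [CONTROL] * n_ctl,
            index=pd.Index(sample_ids, name="sample_id"),
            name="group",
        ),
    )

    annotation = _simulate_annotation(seq_ids, seq_class, rng)
    clinical = _simulate_clinical(
        tumor_ids, subgroup, disruption, config.survival_params, rng
    )

    order = np.argsort(-disruption, kind="stable")
    truth = GroundTruth(
        hyper_ids={seq_ids[i] for i in hyper_idx},
        hypo_ids={seq_ids[i] for i in hypo_idx},
        subgroup_labels={tumor_ids[i]: int(subgroup[i]) for i in range(n_tum)},
        signature_map=signature_map,
        signature_ids=signature_ids,
        unstable_ids={seq_ids[i] for i in unstable_idx},
        disruption_multipliers={tumor_ids[i]: float(disruption[i]) for i in range(n_tum)},
        disruption_rank=[tumor_ids[i] for i in order],
    )
    return probes, annotation, clinical, truth


# ---------------------------------------------------------------------------
# fixture persistence
# ---------------------------------------------------------------------------

def write_fixtures(outputs, directory: str | Path) -> dict[str, Path]:
    """Persist a simulated experiment as TSV/JSON files.

    ``outputs`` is the 4-tuple from :func:`simulate_experiment`.  Files
    round-trip losslessly through :mod:`methvar.io`.  Returns the mapping of
    artifact name to path.
    """
    from . import io as mio

    probes, annotation, clinical, truth = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "probes": directory / "probes.tsv",
        "intensity": directory / "intensity.tsv",
        "samples": directory / "samples.tsv",
        "annotation": directory / "annotation.tsv",
        "clinical": directory / "clinical.tsv",
        "ground_truth": directory / "ground_truth.json",
    }
    mio.write_probe_table(probes, paths["probes"], paths["intensity"], paths["samples"])
    mio.write_annotation(annotation, paths["annotation"])
    mio.write_clinical(clinical, paths["clinical"])
    payload = {
        "hyper_ids": sorted(truth.hyper_ids),
        "hypo_ids": sorted(truth.hypo_ids),
        "subgroup_labels": truth.subgroup_labels,
        "signature_map": {str(g): sorted(v) for g, v in truth.signature_map.items()},
        "signature_ids": sorted(truth.signature_ids),
        "unstable_ids": sorted(truth.unstable_ids),
        "disruption_multipliers": truth.disruption_multipliers,
        "disruption_rank": truth.disruption_rank,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        hyper_ids=set(payload["hyper_ids"]),
        hypo_ids=set(payload["hypo_ids"]),
        subgroup_labels={k: int(v) for k, v in payload["subgroup_labels"].items()},
        signature_map={int(g): set(v) for g, v in payload["signature_map"].items()},
        signature_ids=set(payload["signature_ids"]),
        unstable_ids=set(payload["unstable_ids"]),
        disruption_multipliers={
            k: float(v) for k, v in payload["disruption_multipliers"].items()
        },
        disruption_rank=list(payload["disruption_rank"]),
    )
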