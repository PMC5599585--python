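"""Readers/writers for the pipeline's TSV/BED/YAML artifacts and the
end-to-end orchestration.

Conventions: annotation coordinates are 1-based inclusive everywhere inside
the package; the BED6 writer converts to 0-based half-open at the boundary.
Every output file starts with a comment line declaring the config hash and
seed.  All randomness flows from one root seed through named substreams
(:func:`substream`), so stages rerun independently reproduce the pipeline's
results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, disrupt, preprocess, stratify
from .preprocess import MethylationMatrix, ProbeTable

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named child generator of the root seed (stage-level reproducibility)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([root_seed, key]))


def substream_seed(root_seed: int, name: str) -> int:
    """Integer seed (< 2^31) for stages that take a plain seed."""
    return int(substream(root_seed, name).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={index_col: str})
    if df.empty:
        raise ParseError(f"{path}: empty data section")
    if index_col not in df.columns:
        raise ParseError(f"{path}: missing required column {index_col!r}")
    dup = df[index_col][df[index_col].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated {index_col} {dup.iloc[0]!r}")
    return df.set_index(index_col)

def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        for c in bad:
            rows = df.index[pd.to_numeric(df[c], errors="coerce").isna()][:3]
            raise ParseError(f"{path}: non-numeric cells in column {c!r}, rows {list(rows)}")
    return df


def _header_comment(seed: int | None, config_hash: str | None) -> str:
    parts = ["# methvar"]
    if config_hash:
        parts.append(f"config_hash={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_hash))
        df.to_csv(fh, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# typed readers / writers
# ---------------------------------------------------------------------------

def read_probe_table(
    probes_path: str | Path,
    intensity_path: str | Path,
    samples_path: str | Path,
) -> ProbeTable:
    probes = _read_tsv(probes_path, "probe_id")
    if "sequence_id" not in probes.columns:
        raise ParseError(f"{probes_path}: missing required column 'sequence_id'")
    seq_map = probes["sequence_id"].astype(str)
    ratios = _require_numeric(probes.drop(columns="sequence_id"), probes_path)
    intensity = _require_numeric(_read_tsv(intensity_path, "probe_id"), intensity_path)
    samples = read_sample_sheet(samples_path)
    return ProbeTable(
        log2_ratio=ratios.astype(float),
        intensity=intensity.astype(float).loc[ratios.index, ratios.columns],
        probe_to_sequence=seq_map.rename("sequence_id"),
        sample_groups=samples["group"],
    )


def write_probe_table(
    probes: ProbeTable,
    probes_path: str | Path,
    intensity_path: str | Path,
    samples_path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    out = probes.log2_ratio.copy()
    out.insert(0, "sequence_id", probes.probe_to_sequence)
    write_tsv(out, probes_path, seed, config_hash)
    write_tsv(probes.intensity, intensity_path, seed, config_hash)
    write_tsv(probes.sample_groups.to_frame("group"), samples_path, seed, config_hash)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = _read_tsv(path, "sample_id")
    if "group" not in sheet.columns:
        raise ParseError(f"{path}: missing required column 'group'")
    bad = set(sheet["group"]) - {preprocess.TUMOR, preprocess.CONTROL}
    if bad:
        raise ParseError(f"{path}: unknown group labels {sorted(bad)}")
    return sheet


def read_matrix(path: str | Path, samples_path: str | Path) -> MethylationMatrix:
    df = _read_tsv(path, "sequence_id")
    cls = None
    if "sequence_class" in df.columns:
        cls = df.pop("sequence_class").astype(str)
    values = _require_numeric(df, path).astype(float)
    samples = read_sample_sheet(samples_path)
    if cls is None:
        cls = pd.Series("CpG", index=values.index, name="sequence_class")
    scale = "beta" if float(values.to_numpy().min()) >= 0 and float(values.to_numpy().max()) <= 1 else "log2"
    return MethylationMatrix(
        values=values,
        sequence_class=cls,
        sample_groups=samples["group"],
        scale=scale,
        normalized=True,
    )


def write_matrix(
    matrix: MethylationMatrix,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    out = matrix.values.copy()
    out.insert(0, "sequence_class", matrix.sequence_class)
    write_tsv(out, path, seed, config_hash)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = _read_tsv(path, "sequence_id")
    required = {"chromosome", "start", "end", "sequence_class", "locations"}
    missing = required - set(ann.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    ann["start"] = pd.to_numeric(ann["start"], errors="raise").astype(int)
    ann["end"] = pd.to_numeric(ann["end"], errors="raise").astype(int)
    bad = ann.index[ann["start"] > ann["end"]]
    if len(bad):
        raise ParseError(f"{path}: start > end for {list(bad)[:3]}")
    empty = ann.index[ann["locations"].fillna("") == ""]
    if len(empty):
        raise ParseError(f"{path}: empty locations for {list(empty)[:3]}")
    if "gene_symbol" in ann.columns:
        ann["gene_symbol"] = ann["gene_symbol"].fillna("")
    return ann


def write_annotation(
    ann: pd.DataFrame, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    write_tsv(ann, path, seed, config_hash)


def read_clinical(path: str | Path) -> pd.DataFrame:
    clin = _read_tsv(path, "sample_id")
    for endpoint in ("TTP", "LSS"):
        tcol, ecol = f"{endpoint}_days", f"{endpoint}_event"
        if tcol in clin.columns:
            clin[tcol] = pd.to_numeric(clin[tcol], errors="raise")
            if (clin[tcol] < 0).any():
                raise ParseError(f"{path}: negative {tcol}")
            clin[ecol] = clin[ecol].astype(str).str.lower().isin(("true", "1", "yes"))
    return clin


def write_clinical(
    clin: pd.DataFrame, path: str | Path, seed: int | None = None, config_hash: str | None = None
) -> None:
    write_tsv(clin, path, seed, config_hash)


def write_bed(
    dmr: pd.DataFrame,
    annotation: pd.DataFrame,
    path: str | Path,
    max_score: float = 1000.0,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """BED6 of significant sequences; 1-based inclusive -> 0-based half-open.

    Score is -10*log10(p_bonf), capped; strand is '.' (arrays are unstranded
    at the sequence level).
    """
    sig = dmr[dmr["significant"]]
    ann = annotation.loc[sig.index]
    with np.errstate(divide="ignore"):
        score = np.minimum(max_score, -10.0 * np.log10(sig["p_bonf"].to_numpy()))
    bed = pd.DataFrame(
        {
            "chrom": ann["chromosome"].to_numpy(),
            "chromStart": ann["start"].to_numpy() - 1,
            "chromEnd": ann["end"].to_numpy(),
            "name": sig.index.to_numpy(),
            "score": np.round(score, 1),
            "strand": ".",
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_hash))
        bed.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one run needs; YAML round-trip stable."""

    probes_path: str = ""
    intensity_path: str = ""
    samples_path: str = ""
    annotation_path: str = ""
    clinical_path: str = ""
    out_dir: str = "results"
    span: float = 0.3
    qc_max_robust_z: float = 5.0
    enrich_threshold: float = 0.5
    min_fraction: float = 0.25
    alpha: float = 0.01
    corr_threshold: float = 0.85
    n_components: int = 2
    k: int = 3
    endpoint: str = "LSS"
    subset_sizes: tuple[int, ...] = (250, 500, 1000, 2000)
    n_resamples: int = 1000
    sample_fraction: float = 0.8
    consensus_k: int = 3
    lss_cutoff: float = 180.0
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ParseError("span must be in (0, 1]")
        if not 0 < self.min_fraction <= 1:
            raise ParseError("min_fraction must be in (0, 1]")
        if not 0 < self.enrich_threshold < 1:
            raise ParseError("enrich_threshold must be in (0, 1)")
        if not 0 < self.corr_threshold < 1:
            raise ParseError("corr_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ParseError("alpha must be in (0, 1)")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["subset_sizes"] = list(self.subset_sizes)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "subset_sizes" in data:
            data["subset_sizes"] = tuple(int(s) for s in data["subset_sizes"])
        return cls(**data)


@dataclass
class PipelineResult:
    matrix: MethylationMatrix
    beta: MethylationMatrix
    qc_report: preprocess.QCReport
    filter_report: preprocess.FilterReport
    dmr: pd.DataFrame
    enrichment: dict[str, pd.DataFrame]
    pca: stratify.PCAResult
    assignment: stratify.ClusterAssignment
    clinical_association: pd.DataFrame | None
    km: stratify.KMComparison | None
    changes: pd.DataFrame
    mvs: pd.Series
    mad_ranking: pd.Series
    consensus: dict[int, disrupt.ConsensusResult]
    disrupted: disrupt.DisruptedGroupReport | None
    outputs: dict[str, Path]


def run_pipeline(
    config: PipelineConfig,
    probes: ProbeTable | None = None,
    annotation: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute preprocess -> differential -> stratify -> disrupt.

    Inputs may be passed in memory; otherwise they are read from the paths in
    ``config``.  Any stage failure aborts with a stage-tagged message.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    chash = config.config_hash()
    out_dir = Path(config.out_dir)
    outputs: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage %s starting", name)

    try:
        _stage("read")
        if probes is None:
            probes = read_probe_table(
                config.probes_path, config.intensity_path, config.samples_path
            )
        if annotation is None:
            if not config.annotation_path:
                raise ParseError("annotation_path required")
            annotation = read_annotation(config.annotation_path)
        if clinical is None:
            if not config.clinical_path:
                raise ParseError("clinical_path required for survival stages")
            clinical = read_clinical(config.clinical_path)
    except Exception as exc:
        raise RuntimeError(f"[read] {exc}") from exc

    try:
        _stage("preprocess")
        matrix, beta, qc_report, filter_report = preprocess.preprocess_pipeline(
            probes,
            sequence_class=annotation["sequence_class"],
            span=config.span,
            qc=preprocess.QCCriteria(max_robust_z=config.qc_max_robust_z),
            enrich_threshold=config.enrich_threshold,
            min_fraction=config.min_fraction,
        )
        logger.info(
            "preprocess: %d probes -> %d sequences retained (%d dropped)",
            probes.log2_ratio.shape[0], filter_report.retained, filter_report.dropped,
        )
    except Exception as exc:
        raise RuntimeError(f"[preprocess] {exc}") from exc

    try:
        _stage("differential")
        dmr = differential.mww_dmr_test(matrix, alpha=config.alpha)
        enrichment = {
            d: differential.location_enrichment(dmr, annotation, d, alpha=config.alpha)
            for d in ("hyper", "hypo")
        }
    except Exception as exc:
        raise RuntimeError(f"[differential] {exc}") from exc

    try:
        _stage("stratify")
        pca = stratify.pca_select_sequences(
            matrix, corr_threshold=config.corr_threshold, n_components=config.n_components
        )
        selected = pca.selected if pca.selected else None
        assignment = stratify.ward_cluster(matrix, k=config.k, selected_ids=selected)
        association = None
        km = None
        if clinical is not None:
            association = stratify.cluster_clinical_association(assignment, clinical)
            sizes = assignment.labels.value_counts()
            big = sizes.index[:2]
            try:
                km = stratify.km_logrank(
                    assignment, clinical, endpoint=config.endpoint,
                    groups=(int(big[0]), int(big[1])),
                )
            except stratify.StratifyError as exc:
                logger.warning("log-rank skipped: %s", exc)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[stratify] {exc}") from exc

    try:
        _stage("disrupt")
        changes = disrupt.differential_matrix(matrix)
        tumors = matrix.group_samples(preprocess.TUMOR)
        controls = matrix.group_samples(preprocess.CONTROL)
        mvs = disrupt.mvs_scores(changes, tumors, controls, matrix=matrix)
        mad_ranking = disrupt.mad_rank_sequences(changes, tumors)
        sizes = [s for s in config.subset_sizes if s <= len(mad_ranking)]
        consensus = {
            size: disrupt.consensus_cluster(
                changes,
                mad_ranking,
                size,
                samples=tumors,
                k=config.consensus_k,
                n_resamples=config.n_resamples,
                sample_fraction=config.sample_fraction,
                seed=substream_seed(config.seed, f"consensus_{size}"),
            )
            for size in sizes
        }
        disrupted = None
        if clinical is not None and consensus:
            ref_size = sizes[-1]
            try:
                disrupted = disrupt.flag_disrupted_group(
                    consensus[ref_size], mvs, clinical, lss_cutoff=config.lss_cutoff
                )
            except disrupt.DisruptError as exc:
                logger.warning("disrupted-group test skipped: %s", exc)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[disrupt] {exc}") from exc

    if write_outputs:
        _stage("write")
        seed = config.seed
        outputs["matrix"] = out_dir / "matrix.tsv"
        write_matrix(matrix, outputs["matrix"], seed, chash)
        outputs["beta"] = out_dir / "matrix_beta.tsv"
        write_matrix(beta, outputs["beta"], seed, chash)
        outputs["dmr"] = out_dir / "dmr.tsv"
        write_tsv(dmr, outputs["dmr"], seed, chash)
        outputs["dmr_bed"] = out_dir / "dmr_significant.bed"
        write_bed(dmr, annotation, outputs["dmr_bed"], seed=seed, config_hash=chash)
        for d, table in enrichment.items():
            outputs[f"enrichment_{d}"] = out_dir / f"enrichment_{d}.tsv"
            write_tsv(table, outputs[f"enrichment_{d}"], seed, chash)
        outputs["pca_selection"] = out_dir / "pca_selection.tsv"
        write_tsv(
            pca.correlations.loc[pca.selected], outputs["pca_selection"], seed, chash
        )
        outputs["clusters"] = out_dir / "clusters.tsv"
        write_tsv(assignment.labels.to_frame(), outputs["clusters"], seed, chash)
        if association is not None:
            outputs["clinical_association"] = out_dir / "clinical_association.tsv"
            write_tsv(association, outputs["clinical_association"], seed, chash)
        outputs["mvs"] = out_dir / "mvs.tsv"
        write_tsv(mvs.to_frame(), outputs["mvs"], seed, chash)
        outputs["mad"] = out_dir / "mad_ranking.tsv"
        write_tsv(mad_ranking.to_frame(), outputs["mad"], seed, chash)
        for size, res in consensus.items():
            outputs[f"consensus_{size}"] = out_dir / f"consensus_{size}.tsv"
            write_tsv(res.consensus, outputs[f"consensus_{size}"], seed, chash)
            outputs[f"consensus_assignment_{size}"] = (
                out_dir / f"consensus_assignment_{size}.tsv"
            )
            write_tsv(
                res.assignment.to_frame(),
                outputs[f"consensus_assignment_{size}"],
                seed,
                chash,
            )

    return PipelineResult(
        matrix=matrix,
        beta=beta,
        qc_report=qc_report,
        filter_report=filter_report,
        dmr=dmr,
        enrichment=enrichment,
        pca=pca,
        assignment=assignment,
        clinical_association=association,
        km=km,
        changes=changes,
        mvs=mvs,
        mad_ranking=mad_ranking,
        consensus=consensus,
        disrupted=disrupted,
        outputs=outputs,
    )
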