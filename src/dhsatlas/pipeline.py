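"""End-to-end orchestration: qc -> cluster -> reptest -> normalize -> export.

Each stage writes its artifact (TSV/BED/GFF3) into the run directory plus a
``manifest.json`` recording the configuration hash, the random seed and a
checksum per artifact. A rerun with an identical configuration reuses any
stage whose artifacts are present and whose config hash matches, so the
pipeline is resumable stage by stage; rerunning from scratch with the same
seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import intensity as intensity_mod
from . import qc as qc_mod
from .clustering import (
    DHSCluster,
    MCLParams,
    cluster_all,
    cluster_spans,
    clusters_from_frame,
    clusters_to_frame,
)
from .exceptions import ConfigError
from .io import (
    SampleRecord,
    export_bed,
    export_gff3,
    export_matrix,
    read_metadata,
    read_narrowpeak,
    write_metadata,
)
from .replication import filter_replicable, replication_test

logger = logging.getLogger("dhsatlas")

STAGES = ("qc", "cluster", "reptest", "normalize", "export")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the reference analysis values."""

    metadata: Path
    out_dir: Path
    min_peaks: int = qc_mod.DEFAULT_MIN_PEAKS
    max_peaks: int = qc_mod.DEFAULT_MAX_PEAKS
    autosomes_only: bool = True
    mcl: MCLParams = field(default_factory=MCLParams)
    n_runs: int = 10
    alpha: float = 0.05
    n_subsample: int = intensity_mod.DEFAULT_N_SUBSAMPLE
    activity_threshold: float = intensity_mod.DEFAULT_ACTIVITY_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        self.metadata = Path(self.metadata)
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["metadata"] = str(self.metadata)
        payload["out_dir"] = str(self.out_dir)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: list[SampleRecord]
    clusters: list[DHSCluster]
    replication: pd.DataFrame
    normalized: pd.DataFrame
    cell_type_matrix: pd.DataFrame
    artifacts: dict[str, Path]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config_hash: str) -> None:
        self.path = out_dir / "manifest.json"
        self.config_hash = config_hash
        self.data: dict = {"config_hash": config_hash, "stages": {}}
        if self.path.exists():
            try:
                stored = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                stored = {}
            if stored.get("config_hash") == config_hash:
                self.data = stored

    def stage_done(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        for fp, digest in entry.items():
            p = Path(fp)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, files: Sequence[Path]) -> None:
        self.data["stages"][stage] = {str(fp): _sha256(fp) for fp in files}
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _load_peaks(
    samples: Sequence[SampleRecord], autosomes_only: bool
) -> dict[str, list]:
    peaks = {}
    for s in samples:
        if not s.path:
            raise ConfigError(f"sample {s.sample_id} has no peak-file path")
        peaks[s.sample_id] = read_narrowpeak(
            s.path, s.sample_id, autosomes_only=autosomes_only
        )
    return peaks


def run_all(config: PipelineConfig, resume: bool = True) -> PipelineResult:
    """Run every stage in order, reusing finished stages when ``resume``."""
    cfg = config
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = _Manifest(out, chash)
    header = f" dhsatlas config={chash} seed={cfg.seed}"
    art = {
        "qc_report": out / "qc_report.tsv",
        "samples_pass": out / "samples_pass.tsv",
        "members": out / "cluster_members.tsv",
        "clusters_bed": out / "clusters.bed",
        "replication": out / "replication.tsv",
        "normalized": out / "intensity_normalized.tsv",
        "celltype": out / "celltype_matrix.tsv",
        "matrix_export": out / "replicable_matrix.tsv",
        "replicable_bed": out / "replicable.bed",
        "gff_dir": out / "gff3",
    }

    # ----- qc --------------------------------------------------------------
    samples_all = read_metadata(cfg.metadata)
    if resume and manifest.stage_done("qc"):
        samples = read_metadata(art["samples_pass"])
        logger.info("qc: reused (%d samples pass)", len(samples))
        peaks = _load_peaks(samples, cfg.autosomes_only)
    else:
        peaks = _load_peaks(
            [s for s in samples_all if s.path], cfg.autosomes_only
        )
        counts = {sid: len(p) for sid, p in peaks.items()}
        # samples without a readable path count as zero peaks
        for s in samples_all:
            counts.setdefault(s.sample_id, 0)
        samples, report = qc_mod.run_qc(
            samples_all, counts, min_peaks=cfg.min_peaks, max_peaks=cfg.max_peaks
        )
        report.to_frame().to_csv(art["qc_report"], sep="\t", index=False)
        write_metadata(samples, art["samples_pass"])
        manifest.record("qc", [art["qc_report"], art["samples_pass"]])
        logger.info(
            "qc: %d in, %d removed (metadata), %d removed (peak count), %d pass",
            report.n_input, report.n_removed_metadata,
            report.n_removed_peakcount, report.n_passed,
        )
        peaks = {s.sample_id: peaks.get(s.sample_id, []) for s in samples}

    all_peaks = [p for s in samples for p in peaks[s.sample_id]]
    logger.info("peaks: %d across %d samples", len(all_peaks), len(samples))

    # ----- cluster ---------------------------------------------------------
    if resume and manifest.stage_done("cluster"):
        members = pd.read_csv(art["members"], sep="\t", comment="#")
        clusters = clusters_from_frame(members)
        logger.info("cluster: reused (%d clusters)", len(clusters))
    else:
        clusters = cluster_all(all_peaks, cfg.mcl)
        clusters_to_frame(clusters).to_csv(art["members"], sep="\t", index=False)
        export_bed(cluster_spans(clusters), art["clusters_bed"], header=header)
        manifest.record("cluster", [art["members"], art["clusters_bed"]])
        logger.info("cluster: %d peaks -> %d clusters", len(all_peaks), len(clusters))

    # ----- reptest ---------------------------------------------------------
    if resume and manifest.stage_done("reptest"):
        rep = pd.read_csv(art["replication"], sep="\t", comment="#",
                          index_col="cluster_id")
    else:
        rep = replication_test(
            clusters, samples, n_runs=cfg.n_runs, alpha=cfg.alpha, seed=cfg.seed
        )
        rep.to_csv(art["replication"], sep="\t")
        manifest.record("reptest", [art["replication"]])
    replicable_ids = filter_replicable(rep, alpha=cfg.alpha)
    logger.info(
        "reptest: %d/%d clusters replicable (alpha=%g, %d runs)",
        len(replicable_ids), len(clusters), cfg.alpha, cfg.n_runs,
    )

    # ----- normalize -------------------------------------------------------
    id_set = set(replicable_ids)
    replicable_clusters = [c for c in clusters if c.cluster_id in id_set]
    sample_ids = [s.sample_id for s in samples]
    raw = intensity_mod.assign_intensities(replicable_clusters, sample_ids)
    scaled = intensity_mod.scale_per_sample(raw)
    normalized = intensity_mod.quantile_normalize(
        scaled, n_subsample=cfg.n_subsample, seed=cfg.seed
    )
    ct = intensity_mod.collapse_by_celltype(normalized, samples)
    final = intensity_mod.filter_active(ct, threshold=cfg.activity_threshold)
    normalized.to_csv(art["normalized"], sep="\t")
    final.to_csv(art["celltype"], sep="\t")
    manifest.record("normalize", [art["normalized"], art["celltype"]])
    logger.info(
        "normalize: %d replicable clusters, %d pass the >%g activity filter",
        len(replicable_clusters), len(final), cfg.activity_threshold,
    )

    # ----- export ----------------------------------------------------------
    spans = cluster_spans(replicable_clusters)
    final_spans = spans.loc[final.index]
    export_matrix(final, final_spans, art["matrix_export"])
    export_bed(final_spans, art["replicable_bed"], header=header)
    gff_files = export_gff3(final, final_spans, art["gff_dir"],
                            header_extra=header)
    manifest.record(
        "export", [art["matrix_export"], art["replicable_bed"], *gff_files]
    )
    logger.info("export: %d final sites, %d GFF3 files", len(final), len(gff_files))

    return PipelineResult(
        config=cfg,
        samples=samples,
        clusters=clusters,
        replication=rep,
        normalized=normalized,
        cell_type_matrix=final,
        artifacts=art,
    )
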