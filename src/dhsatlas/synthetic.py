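"""Synthetic peak-call datasets with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
multiple cell types x replicates generated by multiple centers (batches);
true regulatory sites active in random subsets of cell types, whose peak
boundaries jitter between samples and whose intensities carry a per-batch
monotone distortion (power + scale) plus lognormal noise and per-replicate
dropout; and spurious peaks, each present in exactly one sample, at
positions overlapping nothing else. Site lengths are log-normal with a
median around 310 bp, matching typical replicable DHS lengths.

Outputs are written in the exact formats the I/O module reads (narrowPeak
per sample, metadata TSV, truth TSV) and are byte-identical for a given
seed.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import DHSCluster
from .exceptions import ConfigError
from .io import (
    GenomicInterval,
    Peak,
    SampleRecord,
    chrom_sort_key,
    write_metadata,
    write_narrowpeak,
)

_BATCH_NAMES = ("centerA", "centerB", "centerC", "centerD")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 20 cell types with 2-4 replicates each (cycled), 2 generating
    centers assigned per replicate so cell types span batches, a 4 x 30 Mb
    autosomal genome, 2,000 true sites (log-normal lengths, median 310 bp),
    30 bp boundary jitter, 10% per-replicate dropout, and 2,000 spurious
    single-sample peaks per sample. Batch 2 distorts intensities by a
    monotone power/scale transform.
    """

    n_cell_types: int = 20
    replicates_per_cell_type: tuple[int, ...] | None = None  # default: cycle 2,3,4
    n_batches: int = 2
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 30_000_000 for i in range(1, 5)}
    )
    n_true_sites: int = 2_000
    site_length_median: float = 310.0
    site_length_sigma: float = 0.35
    min_site_length: int = 50
    activity_prob: float = 0.3
    jitter_sd: float = 30.0
    dropout: float = 0.1
    base_intensity_range: tuple[float, float] = (3.0, 60.0)
    batch_scale: tuple[float, ...] = (1.0, 0.55, 0.8, 1.3)
    batch_power: tuple[float, ...] = (1.0, 1.25, 0.85, 1.1)
    intensity_noise_sd: float = 0.15
    spurious_per_sample: int = 2_000
    spurious_intensity_range: tuple[float, float] = (2.0, 12.0)
    placement_margin: int = 150
    placement_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_batches < 1:
            raise ConfigError("counts must be positive")
        if not 0 <= self.activity_prob <= 1 or not 0 <= self.dropout <= 1:
            raise ConfigError("probabilities must be in [0, 1]")
        if self.n_true_sites < 0 or self.spurious_per_sample < 0:
            raise ConfigError("site counts must be >= 0")
        if self.n_batches > len(_BATCH_NAMES):
            raise ConfigError(f"at most {len(_BATCH_NAMES)} batches supported")

    def replicate_counts(self) -> list[int]:
        if self.replicates_per_cell_type is not None:
            if len(self.replicates_per_cell_type) != self.n_cell_types:
                raise ConfigError(
                    "replicates_per_cell_type length must equal n_cell_types"
                )
            return list(self.replicates_per_cell_type)
        cycle = (2, 3, 4)
        return [cycle[i % len(cycle)] for i in range(self.n_cell_types)]


@dataclass(frozen=True)
class TruthSite:
    """Ground-truth entry: a true regulatory site or one spurious peak."""

    site_id: str
    interval: GenomicInterval
    is_true: bool
    active_cell_types: frozenset[str] = frozenset()
    source_sample: str = ""  # for spurious entries: the one carrying sample


@dataclass
class SimulatedDataset:
    """In-memory handle to a generated dataset (all files on disk too)."""

    out_dir: Path
    samples: list[SampleRecord]
    truth: list[TruthSite]
    peak_files: dict[str, Path]
    metadata_path: Path
    truth_path: Path

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (
                t.site_id,
                t.interval.chrom,
                t.interval.start,
                t.interval.end,
                int(t.is_true),
                ",".join(sorted(t.active_cell_types)),
                t.source_sample,
            )
            for t in self.truth
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "site_id",
                "chrom",
                "start",
                "end",
                "is_true",
                "active_cell_types",
                "source_sample",
            ],
        )


class _Placer:
    """Non-overlapping interval placement per chromosome via sorted lists."""

    def __init__(self, margin: int) -> None:
        self.margin = margin
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def try_place(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        lo, hi = start - self.margin, end + self.margin
        i = bisect.bisect_left(starts, hi)
        if i > 0 and ends[i - 1] > lo:
            return False
        starts.insert(i, start)
        ends.insert(i, end)
        return True


def _draw_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    length = rng.lognormal(math.log(cfg.site_length_median), cfg.site_length_sigma)
    return max(cfg.min_site_length, int(round(length)))


def _place_interval(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    placer: _Placer,
    chroms: list[str],
    weights: np.ndarray,
) -> GenomicInterval:
    for _ in range(cfg.placement_retries):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = _draw_length(cfg, rng)
        limit = cfg.chrom_lengths[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        if placer.try_place(chrom, start, start + length):
            return GenomicInterval(chrom, start, start + length)
    raise ConfigError(
        "could not place a non-overlapping interval within the retry budget; "
        "increase genome size or reduce site counts"
    )


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> SimulatedDataset:
    """Generate narrowPeak files, metadata and a ground-truth table.

    Fully seeded: the same config (including seed) produces byte-identical
    files.
    """
    cfg = config
    out_dir = Path(out_dir)
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # --- samples -----------------------------------------------------------
    samples: list[SampleRecord] = []
    for t in range(cfg.n_cell_types):
        ct = f"CT{t + 1:02d}"
        for r in range(cfg.replicate_counts()[t]):
            batch = _BATCH_NAMES[r % cfg.n_batches]
            sid = f"{ct}_r{r + 1}"
            samples.append(
                SampleRecord(sid, ct, f"{ct}_d{r + 1}", batch,
                             str(peaks_dir / f"{sid}.narrowPeak"))
            )
    cell_types = sorted({s.cell_type for s in samples})
    batch_index = {name: i for i, name in enumerate(_BATCH_NAMES[: cfg.n_batches])}

    # --- true sites --------------------------------------------------------
    chroms = sorted(cfg.chrom_lengths, key=chrom_sort_key)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placer = _Placer(cfg.placement_margin)
    truth: list[TruthSite] = []
    base_intensity: dict[str, float] = {}
    for k in range(cfg.n_true_sites):
        interval = _place_interval(cfg, rng, placer, chroms, weights)
        while True:
            active = [ct for ct in cell_types if rng.random() < cfg.activity_prob]
            if active:
                break
        site_id = f"site{k + 1:05d}"
        truth.append(
            TruthSite(site_id, interval, True, frozenset(active))
        )
        base_intensity[site_id] = float(rng.uniform(*cfg.base_intensity_range))

    # --- per-sample peaks --------------------------------------------------
    sample_peaks: dict[str, list[Peak]] = {s.sample_id: [] for s in samples}
    for s in samples:
        b = batch_index[s.project]
        scale = cfg.batch_scale[b]
        power = cfg.batch_power[b]
        for site in truth:
            if s.cell_type not in site.active_cell_types:
                continue
            if rng.random() < cfg.dropout:
                continue
            start = site.interval.start + int(round(rng.normal(0, cfg.jitter_sd)))
            end = site.interval.end + int(round(rng.normal(0, cfg.jitter_sd)))
            start = max(0, start)
            if end - start < cfg.min_site_length // 2:
                end = start + cfg.min_site_length // 2
            value = (
                scale
                * base_intensity[site.site_id] ** power
                * math.exp(rng.normal(0, cfg.intensity_noise_sd))
            )
            sample_peaks[s.sample_id].append(
                Peak(GenomicInterval(site.interval.chrom, start, end),
                     s.sample_id, round(value, 6), round(value, 6))
            )
        for i in range(cfg.spurious_per_sample):
            interval = _place_interval(cfg, rng, placer, chroms, weights)
            value = round(float(rng.uniform(*cfg.spurious_intensity_range)), 6)
            truth.append(
                TruthSite(
                    f"spur_{s.sample_id}_{i + 1:05d}", interval, False,
                    frozenset(), s.sample_id,
                )
            )
            sample_peaks[s.sample_id].append(
                Peak(interval, s.sample_id, value, value)
            )

    # --- write files -------------------------------------------------------
    peak_files = {}
    for s in samples:
        fp = peaks_dir / f"{s.sample_id}.narrowPeak"
        write_narrowpeak(sample_peaks[s.sample_id], fp)
        peak_files[s.sample_id] = fp
    metadata_path = out_dir / "metadata.tsv"
    write_metadata(samples, metadata_path)
    ds = SimulatedDataset(
        out_dir=out_dir,
        samples=samples,
        truth=truth,
        peak_files=peak_files,
        metadata_path=metadata_path,
        truth_path=out_dir / "truth.tsv",
    )
    ds.truth_frame().to_csv(ds.truth_path, sep="\t", index=False)
    return ds


# ---------------------------------------------------------------------------
# Recovery evaluation


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    spurious_pass_rate: float
    n_replicable: int
    n_true_sites: int
    n_matched_sites: int
    n_spurious_clusters: int


def _match(
    span: GenomicInterval, site: GenomicInterval, tolerance_bp: int
) -> bool:
    """Reciprocal overlap >= 50% or centers within ``tolerance_bp``."""
    if span.chrom != site.chrom:
        return False
    inter = span.intersection_length(site)
    if inter >= 0.5 * len(span) and inter >= 0.5 * len(site):
        return True
    return abs(span.center - site.center) <= tolerance_bp


def _match_clusters_to_sites(
    clusters: Sequence[DHSCluster],
    sites: Sequence[TruthSite],
    tolerance_bp: int,
) -> dict[str, set[str]]:
    """cluster_id -> matching site ids (sorted-sweep candidate generation)."""
    by_chrom: dict[str, list[TruthSite]] = {}
    for t in sites:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.interval.start)
    out: dict[str, set[str]] = {}
    for c in clusters:
        cands = by_chrom.get(c.span.chrom, [])
        starts = [t.interval.start for t in cands]
        lo = bisect.bisect_left(starts, c.span.start - tolerance_bp - 10_000)
        hi = bisect.bisect_right(starts, c.span.end + tolerance_bp)
        hits = {
            t.site_id
            for t in cands[lo:hi]
            if _match(c.span, t.interval, tolerance_bp)
        }
        if hits:
            out[c.cluster_id] = hits
    return out


def evaluate_recovery(
    clusters: Sequence[DHSCluster],
    replicable_ids: Sequence[str],
    truth: Sequence[TruthSite],
    tolerance_bp: int = 100,
) -> RecoveryMetrics:
    """Site-level precision/recall of the replicable set and the spurious
    pass rate (fraction of spurious-only clusters called replicable)."""
    if not truth:
        raise ValueError("empty truth table")
    true_sites = [t for t in truth if t.is_true]
    spurious = [t for t in truth if not t.is_true]
    replicable_set = set(replicable_ids)
    replicable = [c for c in clusters if c.cluster_id in replicable_set]

    true_hits = _match_clusters_to_sites(replicable, true_sites, tolerance_bp)
    matched_sites = set().union(*true_hits.values()) if true_hits else set()
    precision = len(true_hits) / len(replicable) if replicable else float("nan")
    recall = (
        len(matched_sites) / len(true_sites) if true_sites else float("nan")
    )

    # spurious-only clusters: match a spurious entry and no true site
    all_true_hits = _match_clusters_to_sites(clusters, true_sites, tolerance_bp)
    spur_hits = _match_clusters_to_sites(clusters, spurious, tolerance_bp)
    spur_clusters = [
        c for c in clusters
        if c.cluster_id in spur_hits and c.cluster_id not in all_true_hits
    ]
    if spur_clusters:
        rate = sum(c.cluster_id in replicable_set for c in spur_clusters) / len(
            spur_clusters
        )
    else:
        rate = float("nan")
    return RecoveryMetrics(
        precision=float(precision),
        recall=float(recall),
        spurious_pass_rate=float(rate),
        n_replicable=len(replicable),
        n_true_sites=len(true_sites),
        n_matched_sites=len(matched_sites),
        n_spurious_clusters=len(spur_clusters),
    )
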