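"""Readers and writers for the formats the pipeline touches.

All internal coordinates are BED-style: 0-based, half-open ``[start, end)``.
GFF3 export converts to 1-based inclusive coordinates. Chromosome names are
normalised to the ``chr``-prefixed dialect on read, so ``1`` and ``chr1``
refer to the same sequence.

The peak inputs are narrowPeak (10-column BED extension) files as produced
by Hotspot-style peak callers: column 7 is signalValue and column 8 the
-log10 p-value of peak accessibility. Column 8 is the intensity source; a
value of -1 (or a truncated line) falls back to signalValue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ParseError, SchemaError

#: Human autosomes; the pipeline scope excludes X and Y.
AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

METADATA_COLUMNS = ("sample_id", "cell_type", "donor_id", "project", "path")


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the ``chr``-prefixed dialect."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


def chrom_sort_key(name: str) -> tuple:
    """Sort chromosomes numerically where possible (chr2 before chr10)."""
    body = name[3:] if name.startswith("chr") else name
    return (0, int(body)) if body.isdigit() else (1, body)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """One called accessibility peak from one sample.

    ``neglog10_p`` is the -log10 p-value of peak accessibility after the
    fallback rule has been applied; it is always >= 0.
    """

    interval: GenomicInterval
    sample_id: str
    neglog10_p: float
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.neglog10_p < 0:
            raise ValueError("neglog10_p must be >= 0 after fallback")


@dataclass(frozen=True)
class SampleRecord:
    """One row of the sample metadata table.

    ``project`` is the generating center and doubles as the batch label.
    Empty ``cell_type``/``donor_id`` are preserved here and filtered by the
    sample-QC stage, not rejected at parse time.
    """

    sample_id: str
    cell_type: str
    donor_id: str
    project: str
    path: str = ""


_SKIP_PREFIXES = ("#", "track", "browser")


def read_narrowpeak(
    path: str | Path,
    sample_id: str,
    *,
    autosomes_only: bool = True,
) -> list[Peak]:
    """Read a narrowPeak (or plain BED) file into a list of :class:`Peak`.

    Lines must have >= 3 whitespace-separated columns. Column 8 (-log10
    p-value) supplies ``neglog10_p``; if it is -1 or absent, signalValue
    (column 7) is used instead; if both are absent the peak gets 0.
    Non-autosomal peaks are dropped when ``autosomes_only`` is set.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}, line {lineno}: fewer than 3 columns")
            try:
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            signal = _float_field(fields, 6, path, lineno)
            pval = _float_field(fields, 7, path, lineno)
            signal = max(signal, 0.0)
            neglog10_p = pval if pval >= 0 else signal
            if autosomes_only and chrom not in AUTOSOMES:
                continue
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), sample_id, neglog10_p, signal)
            )
    return peaks


def _float_field(fields: Sequence[str], idx: int, path: Path, lineno: int) -> float:
    """Parse an optional numeric column; absent columns read as -1."""
    if len(fields) <= idx:
        return -1.0
    try:
        return float(fields[idx])
    except ValueError as exc:
        raise ParseError(f"{path}, line {lineno}: column {idx + 1}: {exc}") from exc


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 10-column narrowPeak, sorted by chrom then start."""
    rows = sorted(
        peaks, key=lambda p: (chrom_sort_key(p.interval.chrom), p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                "\t".join(
                    (
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        ".",
                        "0",
                        ".",
                        str(float(p.signal)),
                        str(float(p.neglog10_p)),
                        "-1",
                        "-1",
                    )
                )
                + "\n"
            )


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated sample metadata table.

    Requires columns sample_id, cell_type, donor_id, project, path. Missing
    cell_type/donor_id values are kept as empty strings (the QC stage drops
    them); a missing column or a duplicate sample_id is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate sample_id(s) {sorted(set(dupes))}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            cell_type=row.cell_type.strip(),
            donor_id=row.donor_id.strip(),
            project=row.project.strip(),
            path=row.path,
        )
        for row in df.itertuples()
    ]


def write_metadata(samples: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.sample_id, s.cell_type, s.donor_id, s.project, s.path) for s in samples],
        columns=list(METADATA_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrix / cluster exports


def _sorted_cluster_ids(spans: pd.DataFrame) -> list:
    order = sorted(
        spans.index,
        key=lambda cid: (
            chrom_sort_key(spans.at[cid, "chrom"]),
            int(spans.at[cid, "start"]),
            int(spans.at[cid, "end"]),
        ),
    )
    return order


def export_matrix(
    matrix: pd.DataFrame, spans: pd.DataFrame, path: str | Path
) -> None:
    """Write the cell-type matrix as a TSV keyed by cluster span.

    Columns: chrom, start, end, cluster_id, then one column per cell type.
    Rows are sorted by chromosome then start, so the file is ready for
    bgzip/tabix indexing downstream.
    """
    order = [cid for cid in _sorted_cluster_ids(spans) if cid in matrix.index]
    out = pd.concat(
        [spans.loc[order, ["chrom", "start", "end"]], matrix.loc[order]], axis=1
    )
    out.insert(3, "cluster_id", order)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`export_matrix`: returns (matrix, spans)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("cluster_id")
    spans = df[["chrom", "start", "end"]].copy()
    matrix = df.drop(columns=["chrom", "start", "end"])
    return matrix, spans


def export_bed(spans: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write cluster spans as BED6 (name = cluster_id), sorted."""
    order = _sorted_cluster_ids(spans)
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for cid in order:
            row = spans.loc[cid]
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t{cid}\t0\t.\n"
            )


def _safe_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name) or "unnamed"


def export_gff3(
    matrix: pd.DataFrame,
    spans: pd.DataFrame,
    out_dir: str | Path,
    *,
    source: str = "dhsatlas",
    header_extra: str | None = None,
) -> list[Path]:
    """Write one GFF3 file per cell type (matrix column).

    Coordinates are converted from internal 0-based half-open to GFF3
    1-based inclusive (start+1, end). Only clusters with non-zero intensity
    in a cell type appear in that cell type's file; the intensity is stored
    in the attributes column. An empty matrix yields header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = [cid for cid in _sorted_cluster_ids(spans) if cid in matrix.index]
    written = []
    for cell_type in matrix.columns:
        fp = out_dir / f"{_safe_filename(str(cell_type))}.gff3"
        with open(fp, "w") as fh:
            fh.write("##gff-version 3\n")
            if header_extra:
                fh.write(f"#{header_extra}\n")
            for cid in order:
                value = float(matrix.at[cid, cell_type])
                if value == 0:
                    continue
                row = spans.loc[cid]
                fh.write(
                    "\t".join(
                        (
                            str(row["chrom"]),
                            source,
                            "open_chromatin_region",
                            str(int(row["start"]) + 1),
                            str(int(row["end"])),
                            f"{value:.6g}",
                            ".",
                            ".",
                            f"ID={cid};intensity={value:.6g}",
                        )
                    )
                    + "\n"
                )
        written.append(fp)
    return written
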