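"""Sample-level quality filters applied before clustering.

Two filters: (1) metadata completeness — a sample must carry both a cell
type and a donor/replicate identifier, since the replication test pairs
replicates within cell types; (2) peak count — samples with fewer than
``min_peaks`` or more than ``max_peaks`` called peaks (counted after
autosome restriction) are outliers of the peak-count distribution and are
dropped. Counts exactly equal to a threshold are retained (the cutoffs are
strict inequalities). The filters commute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigError
from .io import SampleRecord

DEFAULT_MIN_PEAKS = 40_000
DEFAULT_MAX_PEAKS = 500_000


@dataclass
class QCReport:
    """Accounting of the sample-QC funnel; counts reconcile exactly."""

    n_input: int = 0
    n_removed_metadata: int = 0
    n_removed_peakcount: int = 0
    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_passed(self) -> int:
        return self.n_input - self.n_removed_metadata - self.n_removed_peakcount

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["sample_id", "reason"])


def filter_by_metadata(
    samples: Sequence[SampleRecord],
) -> tuple[list[SampleRecord], list[tuple[str, str]]]:
    """Drop samples lacking a cell type and/or donor ID."""
    passed, removed = [], []
    for s in samples:
        if not s.cell_type or not s.donor_id:
            missing = []
            if not s.cell_type:
                missing.append("cell_type")
            if not s.donor_id:
                missing.append("donor_id")
            removed.append((s.sample_id, "missing " + "+".join(missing)))
        else:
            passed.append(s)
    return passed, removed


def filter_by_peak_count(
    samples: Sequence[SampleRecord],
    peak_counts: Mapping[str, int],
    min_peaks: int = DEFAULT_MIN_PEAKS,
    max_peaks: float = DEFAULT_MAX_PEAKS,
) -> tuple[list[SampleRecord], list[tuple[str, str]]]:
    """Drop samples with too few (< min) or too many (> max) peaks.

    Boundary counts equal to a threshold are retained.
    """
    if min_peaks < 0 or max_peaks < 0 or min_peaks > max_peaks:
        raise ConfigError(
            f"invalid peak-count thresholds min={min_peaks}, max={max_peaks}"
        )
    passed, removed = [], []
    for s in samples:
        n = peak_counts[s.sample_id]
        if n < min_peaks:
            removed.append((s.sample_id, f"too few peaks ({n} < {min_peaks})"))
        elif n > max_peaks:
            removed.append((s.sample_id, f"too many peaks ({n} > {max_peaks:g})"))
        else:
            passed.append(s)
    return passed, removed


def run_qc(
    samples: Sequence[SampleRecord],
    peak_counts: Mapping[str, int],
    min_peaks: int = DEFAULT_MIN_PEAKS,
    max_peaks: float = DEFAULT_MAX_PEAKS,
) -> tuple[list[SampleRecord], QCReport]:
    """Apply both sample filters and return the survivors with a report."""
    report = QCReport(n_input=len(samples))
    passed, removed_meta = filter_by_metadata(samples)
    passed, removed_count = filter_by_peak_count(
        passed, peak_counts, min_peaks=min_peaks, max_peaks=max_peaks
    )
    report.n_removed_metadata = len(removed_meta)
    report.n_removed_peakcount = len(removed_count)
    report.removed = removed_meta + removed_count
    return passed, report
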