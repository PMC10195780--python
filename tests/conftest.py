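"""Shared fixtures.

The session-scoped fixtures generate one small and one default-scale
synthetic dataset and run the full pipeline on the latter once; the
end-to-end and batch-correction tests reuse them.
"""

from __future__ import annotations

import pytest

from dhsatlas.pipeline import PipelineConfig, run_all
from dhsatlas.synthetic import SimulationConfig, simulate_dataset

SESSION_SEED = 11


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A fast, small dataset: 6 cell types, 2 chromosomes, 60 true sites."""
    cfg = SimulationConfig(
        n_cell_types=6,
        chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
        n_true_sites=60,
        spurious_per_sample=40,
        seed=SESSION_SEED,
    )
    return cfg, simulate_dataset(cfg, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The default study conditions (20 cell types, 2 batches, 2,000 true
    sites, 2,000 spurious peaks per sample)."""
    cfg = SimulationConfig(seed=SESSION_SEED)
    return cfg, simulate_dataset(cfg, tmp_path_factory.mktemp("default_sim"))


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset.

    ``min_peaks`` is lowered to admit the desk-scale samples (~2,600 peaks
    each); every other knob keeps its default.
    """
    _, ds = default_sim
    cfg = PipelineConfig(
        metadata=ds.metadata_path,
        out_dir=tmp_path_factory.mktemp("default_run"),
        min_peaks=100,
        seed=SESSION_SEED,
    )
    return run_all(cfg)
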