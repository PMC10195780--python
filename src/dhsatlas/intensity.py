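"""Accessibility intensities of replicable clusters and batch correction.

The chain is: (1) assign each (cluster, sample) entry the -log10 p-value of
the most significant member peak of that sample (0 = inaccessible);
(2) scale each sample's column linearly to [0, 1] by dividing by its
maximum, so 0 keeps meaning "absent"; (3) quantile-normalize across samples
using a random subsample of non-zero sites per sample, extending to the
unsampled sites by monotone interpolation — a rank-based correction that
removes monotone batch distortions of intensity introduced by different
generating centers; (4) collapse replicate samples of a cell type by the
median (zeros from samples lacking the site included); (5) keep clusters
whose median intensity exceeds the activity threshold (default 0.25) in at
least one cell type.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import DHSCluster
from .exceptions import ConfigError
from .io import SampleRecord

DEFAULT_N_SUBSAMPLE = 10_000
DEFAULT_ACTIVITY_THRESHOLD = 0.25


def assign_intensities(
    clusters: Sequence[DHSCluster], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Raw intensity matrix: max member -log10 p per (cluster, sample)."""
    index = {sid: j for j, sid in enumerate(sample_ids)}
    X = np.zeros((len(clusters), len(sample_ids)))
    for i, c in enumerate(clusters):
        for p in c.members:
            j = index.get(p.sample_id)
            if j is not None and p.neglog10_p > X[i, j]:
                X[i, j] = p.neglog10_p
    return pd.DataFrame(
        X,
        index=pd.Index([c.cluster_id for c in clusters], name="cluster_id"),
        columns=list(sample_ids),
    )


def scale_per_sample(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column into [0, 1] by dividing by its maximum.

    Zeros are unchanged (they encode absence); an all-zero column is left
    as-is with a warning.
    """
    X = matrix.to_numpy(dtype=np.float64, copy=True)
    if (X < 0).any():
        raise ValueError("intensities must be non-negative")
    colmax = X.max(axis=0)
    zero_cols = colmax == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} sample(s) have no non-zero intensity",
            RuntimeWarning,
            stacklevel=2,
        )
        colmax[zero_cols] = 1.0
    return pd.DataFrame(X / colmax, index=matrix.index, columns=matrix.columns)


def quantile_normalize(
    matrix: pd.DataFrame,
    n_subsample: int = DEFAULT_N_SUBSAMPLE,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsampled quantile normalization across samples.

    Per sample, ``min(n_subsample, #non-zero)`` non-zero entries are drawn
    without replacement and sorted; the reference distribution is the
    rank-wise mean of the sorted subsamples (aligned on a common quantile
    grid when subsample sizes differ). Each sampled value maps to the
    reference value at its rank (ties averaged); the remaining non-zero
    values are mapped through monotone piecewise-linear interpolation of
    the sampled (value -> normalized) pairs, clipped at the extremes.
    Zeros stay zero. With fewer than two usable samples the matrix is
    returned unchanged with a warning.
    """
    if n_subsample < 1:
        raise ConfigError("n_subsample must be >= 1")
    X = matrix.to_numpy(dtype=np.float64, copy=True)
    n_sites, n_samples = X.shape
    rng = np.random.default_rng(seed)
    subs: list[tuple[int, np.ndarray, np.ndarray]] = []  # (col, idx, sorted values)
    for j in range(n_samples):
        nz = np.flatnonzero(X[:, j] > 0)
        if nz.size == 0:
            continue
        m = min(n_subsample, nz.size)
        idx = rng.choice(nz, size=m, replace=False)
        order = np.argsort(X[idx, j], kind="stable")
        idx = idx[order]
        subs.append((j, idx, X[idx, j]))
    if len(subs) < 2:
        warnings.warn(
            "fewer than 2 samples with non-zero intensities; "
            "quantile normalization skipped",
            RuntimeWarning,
            stacklevel=2,
        )
        return matrix.copy()

    sizes = {s[2].size for s in subs}
    L = max(sizes)
    grid = np.linspace(0.0, 1.0, L) if L > 1 else np.array([0.5])
    if len(sizes) == 1:
        # equal subsample sizes: the reference is exactly the rank-wise mean
        ref = np.mean([s for _, _, s in subs], axis=0)
    else:
        acc = np.zeros(L)
        for _, _, s in subs:
            pos = np.linspace(0.0, 1.0, s.size) if s.size > 1 else np.array([0.5])
            acc += np.interp(grid, pos, s)
        ref = acc / len(subs)

    out = np.zeros_like(X)
    for j, idx, s in subs:
        m = s.size
        pos = np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5])
        targets = ref if (m == L and len(sizes) == 1) else np.interp(pos, grid, ref)
        # average targets over tied sampled values so equal inputs map equally
        uniq, inverse = np.unique(s, return_inverse=True)
        t_agg = np.zeros(uniq.size)
        np.add.at(t_agg, inverse, targets)
        t_agg /= np.bincount(inverse)
        col = X[:, j]
        nz_all = col > 0
        out[nz_all, j] = np.interp(col[nz_all], uniq, t_agg)
        out[idx, j] = t_agg[inverse]
    # columns skipped for lack of data stay all-zero
    np.clip(out, 0.0, 1.0, out=out)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_by_celltype(
    matrix: pd.DataFrame, samples: Sequence[SampleRecord] | Mapping[str, str]
) -> pd.DataFrame:
    """Median intensity per (cluster, cell type), zeros included.

    ``samples`` maps sample ids to cell types (a metadata list or a dict).
    Every matrix column must be mapped; the median over an even number of
    samples is the mean of the two middle values.
    """
    if isinstance(samples, Mapping):
        mapping = dict(samples)
    else:
        mapping = {s.sample_id: s.cell_type for s in samples}
    missing = [c for c in matrix.columns if c not in mapping]
    if missing:
        raise ValueError(f"samples without a cell type mapping: {missing}")
    cell_types = pd.Series({c: mapping[c] for c in matrix.columns})
    collapsed = matrix.T.groupby(cell_types).median().T
    collapsed.columns.name = "cell_type"
    return collapsed


def filter_active(
    ct_matrix: pd.DataFrame, threshold: float = DEFAULT_ACTIVITY_THRESHOLD
) -> pd.DataFrame:
    """Keep clusters with median intensity strictly above the threshold
    in at least one cell type."""
    if not 0 <= threshold < 1:
        raise ConfigError(f"activity threshold must be in [0, 1), got {threshold}")
    if ct_matrix.empty:
        return ct_matrix.copy()
    return ct_matrix[ct_matrix.max(axis=1) > threshold].copy()


# ---------------------------------------------------------------------------
# Batch-effect diagnostics


def batch_separation(
    matrix: pd.DataFrame, samples: Sequence[SampleRecord]
) -> float:
    """Mean distance between same-cell-type sample profiles across batches.

    Euclidean distance over cluster rows, averaged over all pairs of
    samples that share a cell type but come from different projects
    (batches). Smaller is better; NaN if no such pair exists.
    """
    by_id = {s.sample_id: s for s in samples}
    cols = [c for c in matrix.columns if c in by_id]
    dists = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sa, sb = by_id[a], by_id[b]
            if sa.cell_type == sb.cell_type and sa.project != sb.project:
                d = float(np.linalg.norm(matrix[a].to_numpy() - matrix[b].to_numpy()))
                dists.append(d)
    return float(np.mean(dists)) if dists else float("nan")


def neighbor_agreement(
    matrix: pd.DataFrame, samples: Sequence[SampleRecord]
) -> tuple[float, float]:
    """Fraction of samples whose nearest neighbour shares (cell type, batch)."""
    by_id = {s.sample_id: s for s in samples}
    cols = [c for c in matrix.columns if c in by_id]
    X = matrix[cols].to_numpy().T
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    same_ct = np.mean(
        [by_id[cols[i]].cell_type == by_id[cols[j]].cell_type for i, j in enumerate(nn)]
    )
    same_batch = np.mean(
        [by_id[cols[i]].project == by_id[cols[j]].project for i, j in enumerate(nn)]
    )
    return float(same_ct), float(same_batch)
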