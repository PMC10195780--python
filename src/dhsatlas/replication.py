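"""Replication-based quality checking of DHS clusters.

A cluster that marks a true regulatory site should be detected consistently
in replicate samples of the same cell type. For each randomized *run* we
pick one pair of replicates per cell type (among cell types with at least
two replicates) and tabulate, over the paired cell types, the 2x2 presence
table of the cluster in (first, second) replicate. The per-run statistic is
the Pearson chi-squared of that table (no continuity correction), which is
chi-squared with df = 1 under the null of no replication structure:

    X2 = T * (n11*n00 - n10*n01)^2 / ((n11+n10)(n01+n00)(n11+n01)(n10+n00))

with two degenerate conventions: a cluster present in both replicates of
every paired cell type (n11 = T) scores the Pearson maximum T, so that
constitutively open sites pass; a cluster absent everywhere (n00 = T)
scores 0; any other constant margin scores 0 (association unidentifiable).

Pairings are redrawn K times (default 10) and the per-run statistics are
summed: under the null the sum is referred to a chi-squared distribution
with df = K, and clusters with upper-tail p <= alpha (default 0.05,
inclusive) are called replicable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .clustering import DHSCluster
from .exceptions import ConfigError
from .io import SampleRecord

_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class ReplicatePairing:
    """One run's choice of replicate pairs: cell_type -> (sample_a, sample_b)."""

    run_index: int
    pairs: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for ct, (a, b) in self.pairs.items():
            if a == b:
                raise ValueError(f"cell type {ct!r}: the two replicates must differ")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 presence counts over paired cell types."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class ReplicationResult:
    """Per-cluster outcome of the combined replication test."""

    cluster_id: str
    run_statistics: tuple[float, ...]
    statistic: float
    df: int
    p_value: float
    replicable: bool


def replicate_groups(samples: Sequence[SampleRecord]) -> dict[str, list[str]]:
    """Cell types with >= 2 replicate samples, each with its sorted sample ids."""
    groups: dict[str, list[str]] = {}
    for s in samples:
        if s.cell_type:
            groups.setdefault(s.cell_type, []).append(s.sample_id)
    return {ct: sorted(ids) for ct, ids in groups.items() if len(ids) >= 2}


def draw_pairings(
    samples: Sequence[SampleRecord], n_runs: int = 10, seed: int = 0
) -> list[ReplicatePairing]:
    """Draw one replicate pair per eligible cell type for each of ``n_runs``.

    Pairs are drawn uniformly over all unordered pairs; run k derives its
    generator from ``seed XOR k`` so the sequence is reproducible run by
    run. Cell types with a single replicate are excluded; cell types with
    exactly two yield the same pair in every run.
    """
    groups = replicate_groups(samples)
    if not groups:
        raise ValueError("no cell type has at least two replicates")
    pairings = []
    for k in range(n_runs):
        rng = np.random.default_rng((seed ^ k) & _SEED_MASK)
        pairs = {}
        for ct in sorted(groups):
            ids = groups[ct]
            i, j = rng.choice(len(ids), size=2, replace=False)
            a, b = ids[min(i, j)], ids[max(i, j)]
            pairs[ct] = (a, b)
        pairings.append(ReplicatePairing(run_index=k, pairs=pairs))
    return pairings


def presence_table(
    cluster: DHSCluster | AbstractSet[str], pairing: ReplicatePairing
) -> ContingencyTable:
    """Tabulate the cluster's presence in each paired cell type's replicates."""
    present = cluster.sample_ids if isinstance(cluster, DHSCluster) else cluster
    n11 = n10 = n01 = n00 = 0
    for a, b in pairing.pairs.values():
        x, y = a in present, b in present
        if x and y:
            n11 += 1
        elif x:
            n10 += 1
        elif y:
            n01 += 1
        else:
            n00 += 1
    return ContingencyTable(n11, n10, n01, n00)


def _pearson_2x2(
    n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray
) -> np.ndarray:
    """Vectorised per-run statistic with the degenerate-table conventions."""
    n11 = np.asarray(n11, dtype=np.int64)
    n10 = np.asarray(n10, dtype=np.int64)
    n01 = np.asarray(n01, dtype=np.int64)
    n00 = np.asarray(n00, dtype=np.int64)
    if min(n11.min(initial=0), n10.min(initial=0), n01.min(initial=0), n00.min(initial=0)) < 0:
        raise ValueError("contingency counts must be >= 0")
    T = n11 + n10 + n01 + n00
    r1 = n11 + n10
    c1 = n11 + n01
    stat = np.zeros(np.broadcast(n11, T).shape, dtype=np.float64)
    ok = (r1 > 0) & (r1 < T) & (c1 > 0) & (c1 < T)
    num = T.astype(np.float64) * (n11 * n00 - n10 * n01).astype(np.float64) ** 2
    den = (r1 * (T - r1) * c1 * (T - c1)).astype(np.float64)
    np.divide(num, den, out=stat, where=ok)
    stat[n11 == T] = T[n11 == T]  # fully concordant-present: Pearson maximum
    return stat


def single_run_statistic(table: ContingencyTable) -> float:
    """Per-run concordance statistic of one 2x2 presence table (df = 1)."""
    if table.total < 1:
        raise ValueError("empty contingency table")
    return float(
        _pearson_2x2(
            np.array([table.n11]),
            np.array([table.n10]),
            np.array([table.n01]),
            np.array([table.n00]),
        )[0]
    )


def _pairing_indices(
    pairings: Sequence[ReplicatePairing], sample_index: Mapping[str, int]
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for pairing in pairings:
        first = []
        second = []
        for ct in sorted(pairing.pairs):
            a, b = pairing.pairs[ct]
            first.append(sample_index[a])
            second.append(sample_index[b])
        out.append((np.asarray(first), np.asarray(second)))
    return out


def run_statistic_matrix(
    presence: np.ndarray,
    sample_ids: Sequence[str],
    pairings: Sequence[ReplicatePairing],
) -> np.ndarray:
    """Per-run statistics for many clusters at once.

    ``presence`` is a boolean (n_clusters, n_samples) matrix aligned with
    ``sample_ids``; the result is (n_clusters, n_runs).
    """
    presence = np.asarray(presence, dtype=bool)
    index = {sid: i for i, sid in enumerate(sample_ids)}
    out = np.empty((presence.shape[0], len(pairings)), dtype=np.float64)
    for k, (first, second) in enumerate(_pairing_indices(pairings, index)):
        X = presence[:, first]
        Y = presence[:, second]
        n11 = (X & Y).sum(axis=1)
        n10 = (X & ~Y).sum(axis=1)
        n01 = (~X & Y).sum(axis=1)
        n00 = (~X & ~Y).sum(axis=1)
        out[:, k] = _pearson_2x2(n11, n10, n01, n00)
    return out


def combine_statistics(run_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-run statistics and refer to chi-squared with df = K."""
    run_stats = np.atleast_2d(np.asarray(run_stats, dtype=np.float64))
    K = run_stats.shape[1]
    if K == 0:
        raise ValueError("at least one run is required")
    S = run_stats.sum(axis=1)
    return S, stats.chi2.sf(S, df=K)


def combined_test(
    cluster: DHSCluster | AbstractSet[str],
    pairings: Sequence[ReplicatePairing],
    alpha: float = 0.05,
    cluster_id: str | None = None,
) -> ReplicationResult:
    """Run the combined K-run replication test for a single cluster."""
    _check_alpha(alpha)
    if len(pairings) == 0:
        raise ValueError("at least one pairing is required")
    per_run = tuple(
        single_run_statistic(presence_table(cluster, pairing)) for pairing in pairings
    )
    S, p = combine_statistics(np.asarray(per_run)[None, :])
    if cluster_id is None:
        cluster_id = cluster.cluster_id if isinstance(cluster, DHSCluster) else ""
    return ReplicationResult(
        cluster_id=cluster_id,
        run_statistics=per_run,
        statistic=float(S[0]),
        df=len(pairings),
        p_value=float(p[0]),
        replicable=bool(p[0] <= alpha),
    )


def presence_matrix(
    clusters: Sequence[DHSCluster], sample_ids: Sequence[str]
) -> np.ndarray:
    """Boolean (clusters x samples) membership matrix."""
    index = {sid: i for i, sid in enumerate(sample_ids)}
    out = np.zeros((len(clusters), len(sample_ids)), dtype=bool)
    for r, c in enumerate(clusters):
        for sid in c.sample_ids:
            if sid in index:
                out[r, index[sid]] = True
    return out


def replication_test(
    clusters: Sequence[DHSCluster],
    samples: Sequence[SampleRecord],
    n_runs: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Combined replication test for every cluster.

    Returns a frame indexed by cluster_id with one ``run_<k>`` column per
    run plus ``statistic`` (the sum), ``df``, ``p_value`` and ``replicable``.
    """
    _check_alpha(alpha)
    pairings = draw_pairings(samples, n_runs=n_runs, seed=seed)
    sample_ids = [s.sample_id for s in samples]
    pres = presence_matrix(clusters, sample_ids)
    run_stats = run_statistic_matrix(pres, sample_ids, pairings)
    S, p = combine_statistics(run_stats)
    df = pd.DataFrame(
        run_stats,
        index=pd.Index([c.cluster_id for c in clusters], name="cluster_id"),
        columns=[f"run_{k}" for k in range(n_runs)],
    )
    df["statistic"] = S
    df["df"] = n_runs
    df["p_value"] = p
    df["replicable"] = p <= alpha
    return df


def filter_replicable(
    results: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Cluster ids whose combined p-value passes ``p <= alpha`` (inclusive)."""
    _check_alpha(alpha)
    mask = results["p_value"] <= alpha
    return results.index[mask].tolist()


def count_in_window(results: pd.DataFrame, lo: float, hi: float) -> int:
    """Number of clusters with ``lo < p <= hi`` (threshold sensitivity)."""
    p = results["p_value"]
    return int(((p > lo) & (p <= hi)).sum())


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")


# ---------------------------------------------------------------------------
# Run-count stability


def stability_analysis(
    clusters: Sequence[DHSCluster],
    samples: Sequence[SampleRecord],
    max_runs: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """How many runs are enough? AUC of N-run calls against the max-run calls.

    The reference labels are the replicable calls from combining all
    ``max_runs`` runs (df = max_runs). For each N = 1..max_runs the p-values
    of the first N runs are scored against those labels with ROC AUC
    (undefined when the labels are all one class; reported as NaN).
    """
    from sklearn.metrics import roc_auc_score

    _check_alpha(alpha)
    pairings = draw_pairings(samples, n_runs=max_runs, seed=seed)
    sample_ids = [s.sample_id for s in samples]
    pres = presence_matrix(clusters, sample_ids)
    run_stats = run_statistic_matrix(pres, sample_ids, pairings)
    _, p_ref = combine_statistics(run_stats)
    labels = p_ref <= alpha
    rows = []
    for N in range(1, max_runs + 1):
        _, p_N = combine_statistics(run_stats[:, :N])
        if labels.all() or not labels.any():
            auc = float("nan")
        else:
            auc = float(roc_auc_score(labels, -p_N))
        rows.append((N, auc))
    return pd.DataFrame(rows, columns=["n_runs", "auc"]).set_index("n_runs")


# ---------------------------------------------------------------------------
# Null calibration utilities


def make_replicate_samples(
    n_cell_types: int, n_replicates: int | Sequence[int]
) -> list[SampleRecord]:
    """Synthetic metadata: ``n_cell_types`` cell types with given replicates."""
    if isinstance(n_replicates, int):
        n_replicates = [n_replicates] * n_cell_types
    samples = []
    for t in range(n_cell_types):
        ct = f"ct{t:03d}"
        for r in range(n_replicates[t]):
            samples.append(
                SampleRecord(f"{ct}_r{r}", ct, f"{ct}_d{r}", "null", "")
            )
    return samples


def simulate_null(
    n_clusters: int,
    n_cell_types: int = 161,
    n_replicates: int = 2,
    p_range: tuple[float, float] = (0.2, 0.8),
    n_runs: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replication-test results for clusters with no replication structure.

    Each cluster draws a presence probability uniformly from ``p_range``
    and every replicate of every cell type is present independently with
    that probability, so the per-run statistic should follow chi-squared
    with df = 1 and the combined statistic chi-squared with df = n_runs.
    """
    samples = make_replicate_samples(n_cell_types, n_replicates)
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=n_clusters)
    presence = rng.random((n_clusters, len(samples))) < p[:, None]
    sample_ids = [s.sample_id for s in samples]
    pairings = draw_pairings(samples, n_runs=n_runs, seed=seed)
    run_stats = run_statistic_matrix(presence, sample_ids, pairings)
    S, pv = combine_statistics(run_stats)
    out = pd.DataFrame(
        run_stats,
        index=pd.Index([f"null{k}" for k in range(n_clusters)], name="cluster_id"),
        columns=[f"run_{k}" for k in range(n_runs)],
    )
    out["statistic"] = S
    out["df"] = n_runs
    out["p_value"] = pv
    out["replicable"] = pv <= alpha
    return out


def fit_chisq_df(values: Iterable[float]) -> float:
    """Maximum-likelihood chi-squared degrees of freedom for a sample.

    Solves the likelihood equation mean(log x) = log 2 + digamma(df / 2)
    on the strictly positive values (the fitted family has no atom at 0;
    exact zeros, which the discrete 2x2 statistic produces with small
    probability, are excluded).
    """
    v = np.asarray(list(values), dtype=np.float64)
    v = v[v > 0]
    if v.size < 2:
        raise ValueError("need at least two positive values to fit df")
    target = float(np.mean(np.log(v)))

    def eqn(df: float) -> float:
        return special.digamma(df / 2.0) + np.log(2.0) - target

    return float(optimize.brentq(eqn, 1e-6, 1e6))
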