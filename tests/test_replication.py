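"""The replicate-concordance test: pairings, per-run statistic, combination."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dhsatlas.exceptions import ConfigError
from dhsatlas.io import SampleRecord
from dhsatlas.replication import (
    ContingencyTable,
    ReplicatePairing,
    combined_test,
    count_in_window,
    draw_pairings,
    filter_replicable,
    fit_chisq_df,
    make_replicate_samples,
    presence_table,
    replication_test,
    simulate_null,
    single_run_statistic,
    stability_analysis,
)


class TestDrawPairings:
    def test_two_replicates_give_identical_pair_every_run(self):
        samples = make_replicate_samples(3, 2)
        pairings = draw_pairings(samples, n_runs=10, seed=1)
        for ct in ("ct000", "ct001", "ct002"):
            pairs = {p.pairs[ct] for p in pairings}
            assert len(pairs) == 1

    def test_single_replicate_cell_type_is_excluded(self):
        samples = make_replicate_samples(2, [2, 1])
        pairings = draw_pairings(samples, n_runs=3, seed=0)
        assert all(set(p.pairs) == {"ct000"} for p in pairings)

    def test_no_eligible_cell_type_is_an_error(self):
        with pytest.raises(ValueError):
            draw_pairings(make_replicate_samples(2, 1), seed=0)

    def test_pairs_are_uniform_over_all_pairs(self):
        # 3 replicates -> 3 possible pairs, each with frequency 1/3 +- 0.01
        samples = make_replicate_samples(1, 3)
        counts = {}
        n_draws = 30_000
        pairings = draw_pairings(samples, n_runs=n_draws, seed=42)
        for p in pairings:
            counts[p.pairs["ct000"]] = counts.get(p.pairs["ct000"], 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / n_draws - 1 / 3) < 0.01

    def test_deterministic_given_seed(self):
        samples = make_replicate_samples(5, 4)
        a = draw_pairings(samples, n_runs=5, seed=7)
        b = draw_pairings(samples, n_runs=5, seed=7)
        assert [p.pairs for p in a] == [p.pairs for p in b]

    def test_pair_members_must_differ(self):
        with pytest.raises(ValueError):
            ReplicatePairing(0, {"ct": ("s1", "s1")})


def pairing(pairs):
    return ReplicatePairing(0, pairs)


class TestPresenceTable:
    def test_present_in_both_replicates_everywhere(self):
        pairs = {f"ct{i}": (f"a{i}", f"b{i}") for i in range(5)}
        present = {s for ab in pairs.values() for s in ab}
        t = presence_table(present, pairing(pairs))
        assert (t.n11, t.n10, t.n01, t.n00) == (5, 0, 0, 0)

    def test_absent_everywhere(self):
        pairs = {f"ct{i}": (f"a{i}", f"b{i}") for i in range(4)}
        t = presence_table(set(), pairing(pairs))
        assert (t.n11, t.n10, t.n01, t.n00) == (0, 0, 0, 4)

    def test_mixed_membership_matches_hand_enumeration(self):
        pairs = {
            "ct0": ("a0", "b0"),  # both present      -> n11
            "ct1": ("a1", "b1"),  # first only        -> n10
            "ct2": ("a2", "b2"),  # second only       -> n01
            "ct3": ("a3", "b3"),  # neither           -> n00
        }
        t = presence_table({"a0", "b0", "a1", "b2", "zzz"}, pairing(pairs))
        assert (t.n11, t.n10, t.n01, t.n00) == (1, 1, 1, 1)


class TestSingleRunStatistic:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((50, 0, 0, 50), 100.0),  # perfect association: Pearson value = T
            ((25, 25, 25, 25), 0.0),  # exact independence
            ((30, 20, 20, 30), 4.0),  # T*(900-400)^2/50^4
            ((100, 0, 0, 0), 100.0),  # all-present degenerate: statistic = T
            ((0, 0, 0, 100), 0.0),    # all-absent degenerate
            ((0, 100, 0, 0), 0.0),    # other constant margin
            ((50, 50, 0, 0), 0.0),    # second replicate constant
        ],
    )
    def test_examples_and_degenerate_rules(self, table, expected):
        assert single_run_statistic(ContingencyTable(*table)) == pytest.approx(expected)

    def test_matches_scipy_pearson_on_nondegenerate_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = rng.integers(1, 40, size=4)
            t = ContingencyTable(*map(int, n))
            expected = stats.chi2_contingency(
                [[t.n11, t.n10], [t.n01, t.n00]], correction=False
            ).statistic
            assert single_run_statistic(t) == pytest.approx(expected)

    def test_symmetry_under_replicate_swap(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n11, n10, n01, n00 = map(int, rng.integers(0, 30, 4))
            a = single_run_statistic(ContingencyTable(n11, n10, n01, n00))
            b = single_run_statistic(ContingencyTable(n11, n01, n10, n00))
            assert a == pytest.approx(b)

    def test_monotone_in_concordance(self):
        # moving a discordant cell type into agreement never lowers the
        # statistic while the association is positive
        prev = single_run_statistic(ContingencyTable(20, 20, 10, 50))
        for k in range(1, 21):
            cur = single_run_statistic(ContingencyTable(20 + k, 20 - k, 10, 50))
            assert cur >= prev
            prev = cur

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 10)


class TestCombinedTest:
    def _pairings(self, n_ct=5, n_runs=10):
        samples = make_replicate_samples(n_ct, 2)
        return draw_pairings(samples, n_runs=n_runs, seed=0)

    def test_all_zero_statistics_give_p_one(self):
        res = combined_test(set(), self._pairings(), cluster_id="c")
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.replicable

    def test_chi2_boundary_is_replicable_under_inclusive_threshold(self):
        crit = stats.chi2.isf(0.05, df=10)  # ~18.307
        assert stats.chi2.sf(crit, df=10) == pytest.approx(0.05, abs=1e-12)
        assert stats.chi2.sf(18.307, df=10) == pytest.approx(0.05, abs=1e-4)
        # a p-value exactly at alpha passes the inclusive filter
        import pandas as pd

        results = pd.DataFrame({"p_value": [0.05, 0.050001]},
                               index=["at", "above"])
        assert filter_replicable(results) == ["at"]

    def test_fully_concordant_everywhere_is_overwhelming(self):
        samples = make_replicate_samples(161, 2)
        pairings = draw_pairings(samples, n_runs=10, seed=0)
        present = {s.sample_id for s in samples}
        res = combined_test(present, pairings, cluster_id="c")
        assert res.statistic == pytest.approx(1610.0)
        assert res.p_value < 1e-300
        assert res.replicable

    def test_no_pairings_is_an_error(self):
        with pytest.raises(ValueError):
            combined_test(set(), [], cluster_id="c")

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigError):
            combined_test(set(), self._pairings(), alpha=1.5)


class TestFilterAndWindow:
    def _results(self):
        import pandas as pd

        rng = np.random.default_rng(19)
        return pd.DataFrame({"p_value": rng.random(500)})

    def test_empty_window_counts_zero(self):
        assert count_in_window(self._results(), 0.05, 0.05) == 0

    def test_window_counts_match_linear_scan(self):
        res = self._results()
        for lo, hi in [(0.05, 0.0501), (0.05, 0.0505), (0.1, 0.5)]:
            expected = sum(1 for p in res["p_value"] if lo < p <= hi)
            assert count_in_window(res, lo, hi) == expected

    def test_threshold_changes_only_the_flag_not_statistics(self):
        samples = make_replicate_samples(6, 3)
        rng = np.random.default_rng(2)
        from dhsatlas.clustering import DHSCluster
        from dhsatlas.io import GenomicInterval, Peak

        clusters = []
        sids = [s.sample_id for s in samples]
        for k in range(20):
            members = tuple(
                Peak(GenomicInterval("chr1", 100 * k, 100 * k + 50), sid, 1.0)
                for sid in rng.choice(sids, size=rng.integers(1, len(sids)),
                                      replace=False)
            )
            clusters.append(
                DHSCluster(f"c{k}", members, GenomicInterval("chr1", 100 * k, 100 * k + 50))
            )
        a = replication_test(clusters, samples, alpha=0.05, seed=3)
        b = replication_test(clusters, samples, alpha=0.0505, seed=3)
        assert np.allclose(a["statistic"], b["statistic"])
        assert (a["replicable"] != b["replicable"]).sum() == (
            ((a["p_value"] > 0.05) & (a["p_value"] <= 0.0505)).sum()
        )


class TestStability:
    def _presence_clusters(self, rng, samples, n=200, rho=0.7):
        """Clusters with a mix of concordant and null presence."""
        from dhsatlas.clustering import DHSCluster
        from dhsatlas.io import GenomicInterval, Peak

        clusters = []
        for k in range(n):
            present = set()
            concordant = k < n // 2
            for ct, ids in itertools.groupby(samples, key=lambda s: s.cell_type):
                ids = [s.sample_id for s in ids]
                if concordant:
                    if rng.random() < 0.5:
                        present.update(ids)
                else:
                    present.update(i for i in ids if rng.random() < 0.4)
            members = tuple(
                Peak(GenomicInterval("chr1", 10 * k, 10 * k + 5), sid, 1.0)
                for sid in present
            ) or (Peak(GenomicInterval("chr1", 10 * k, 10 * k + 5), "none", 1.0),)
            clusters.append(
                DHSCluster(f"c{k}", members, GenomicInterval("chr1", 10 * k, 10 * k + 5))
            )
        return clusters

    def test_reference_run_count_classifies_itself_perfectly(self):
        rng = np.random.default_rng(4)
        samples = make_replicate_samples(12, 3)
        clusters = self._presence_clusters(rng, samples)
        auc = stability_analysis(clusters, samples, max_runs=8, seed=4)
        assert auc.loc[8, "auc"] == pytest.approx(1.0)

    def test_degenerate_labels_report_nan(self):
        samples = make_replicate_samples(161, 2)
        present = {s.sample_id for s in samples}
        from dhsatlas.clustering import DHSCluster
        from dhsatlas.io import GenomicInterval, Peak

        clusters = [
            DHSCluster(
                "c0",
                tuple(Peak(GenomicInterval("chr1", 0, 5), sid, 1.0) for sid in present),
                GenomicInterval("chr1", 0, 5),
            )
        ]
        auc = stability_analysis(clusters, samples, max_runs=4, seed=0)
        assert np.isnan(auc["auc"]).all()

    def test_auc_rises_with_run_count_on_average(self):
        samples = make_replicate_samples(12, 3)
        first, last = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            clusters = self._presence_clusters(rng, samples)
            auc = stability_analysis(clusters, samples, max_runs=10, seed=seed)
            first.append(auc.loc[1, "auc"])
            last.append(auc.loc[9, "auc"])
        assert np.mean(last) >= np.mean(first)
        assert np.mean(last) > 0.9


class TestNullCalibrationHelpers:
    def test_fit_recovers_df_of_chi_squared_draws(self):
        rng = np.random.default_rng(0)
        for df in (1, 5, 10):
            v = stats.chi2.rvs(df, size=20_000, random_state=rng)
            assert fit_chisq_df(v) == pytest.approx(df, rel=0.05)

    def test_simulate_null_margins_and_shape(self):
        res = simulate_null(100, n_cell_types=20, n_replicates=3, n_runs=4, seed=0)
        assert res.shape[0] == 100
        assert {"statistic", "p_value", "replicable"} <= set(res.columns)
        assert (res["p_value"] >= 0).all() and (res["p_value"] <= 1).all()
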