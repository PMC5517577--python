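import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dfcstates as d

from ._oracles import best_partition_exhaustive, signed_q_direct


def two_cliques(n_per=4):
    """Two disconnected unit-weight cliques."""
    w = np.zeros((2 * n_per, 2 * n_per))
    w[:n_per, :n_per] = 1.0
    w[n_per:, n_per:] = 1.0
    np.fill_diagonal(w, 0.0)
    return w


class TestSignedModularity:
    def test_single_module_positive_network_is_zero(self, rng):
        w = np.abs(rng.standard_normal((6, 6)))
        w = (w + w.T) / 2
        assert d.signed_modularity(w, np.zeros(6)) == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_component_partition_scores_half(self):
        w = two_cliques()
        membership = np.array([0] * 4 + [1] * 4)
        assert d.signed_modularity(w, membership) == pytest.approx(0.5, abs=1e-12)
        # and exhaustive enumeration confirms this is the global optimum
        best_q, best_m = best_partition_exhaustive(w)
        assert best_q == pytest.approx(0.5, abs=1e-12)
        assert len(np.unique(best_m)) == 2

    def test_signed_toy_network_matches_direct_summation(self):
        w = np.array([
            [0.0, 1.0, -0.5, 0.2],
            [1.0, 0.0, 0.3, -0.5],
            [-0.5, 0.3, 0.0, 0.8],
            [0.2, -0.5, 0.8, 0.0],
        ])
        for membership in ([0, 0, 1, 1], [0, 1, 0, 1], [0, 0, 0, 0], [0, 1, 2, 3]):
            assert d.signed_modularity(w, np.array(membership)) == pytest.approx(
                signed_q_direct(w, np.array(membership)), abs=1e-12
            )

    def test_positive_network_matches_newman_modularity(self, rng):
        """For all-positive weights Q_W reduces to classical weighted
        modularity (networkx as independent reference)."""
        w = np.abs(rng.standard_normal((8, 8)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        membership = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        g = nx.from_numpy_array(w)
        communities = [
            {i for i in range(8) if membership[i] == c} for c in range(3)
        ]
        expected = nx.algorithms.community.modularity(g, communities, weight="weight")
        assert d.signed_modularity(w, membership) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_network_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            q = d.signed_modularity(np.zeros((4, 4)), np.arange(4))
        assert q == 0.0

    @given(st.integers(0, 2**31 - 1), st.integers(4, 6))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_agrees_with_exhaustive_oracle_on_random_signed_networks(self, seed, n):
        rng = np.random.default_rng(seed)
        w = rng.uniform(-1, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        rand_membership = rng.integers(0, 3, n)
        assert d.signed_modularity(w, rand_membership) == pytest.approx(
            signed_q_direct(w, rand_membership), abs=1e-12
        )


class TestLouvain:
    def test_recovers_disconnected_cliques(self):
        res = d.louvain_maximize(two_cliques(), iterations=10, seed=0)
        assert res.q == pytest.approx(0.5, abs=1e-12)
        m = res.partition
        assert len(set(m[:4])) == 1 and len(set(m[4:])) == 1 and m[0] != m[4]

    def test_complete_graph_has_zero_optimum(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0.0)
        res = d.louvain_maximize(w, iterations=10, seed=0)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        best_q, _ = best_partition_exhaustive(w)
        assert best_q == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self, rng):
        w = rng.uniform(-1, 1, (10, 10))
        w = (w + w.T) / 2
        a = d.louvain_maximize(w, iterations=10, seed=4)
        b = d.louvain_maximize(w, iterations=10, seed=4)
        np.testing.assert_array_equal(a.partition, b.partition)
        assert a.q == b.q

    def test_result_q_consistent_with_own_partition(self, rng):
        w = rng.uniform(-1, 1, (12, 12))
        w = (w + w.T) / 2
        res = d.louvain_maximize(w, iterations=20, seed=1)
        assert res.q == pytest.approx(
            d.signed_modularity(w, res.partition), abs=1e-12
        )

    def test_never_below_single_module_for_positive_networks(self, rng):
        w = np.abs(rng.standard_normal((9, 9)))
        w = (w + w.T) / 2
        res = d.louvain_maximize(w, iterations=10, seed=2)
        assert res.q >= 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_best_of_restarts_finds_global_optimum_small(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        w = rng.uniform(-1, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        res = d.louvain_maximize(w, iterations=30, seed=0)
        best_q, _ = best_partition_exhaustive(w)
        assert res.q == pytest.approx(best_q, abs=1e-9)


class TestNodeStrength:
    def test_star_network(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        np.testing.assert_array_equal(d.node_strength(w), [4, 1, 1, 1, 1])

    def test_matches_row_sums(self, rng):
        w = rng.uniform(-1, 1, (7, 7))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        np.testing.assert_allclose(d.node_strength(w), w.sum(axis=1), atol=1e-12)

    def test_zero_network(self):
        np.testing.assert_array_equal(d.node_strength(np.zeros((3, 3))), np.zeros(3))


class TestAggregateStructural:
    def test_singleton_regions_identity(self, rng):
        w = rng.uniform(0, 1, (4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        out, regions = d.aggregate_structural(w, ["a", "b", "c", "d"])
        np.testing.assert_allclose(out, w, atol=1e-12)
        assert regions == ["a", "b", "c", "d"]

    def test_hand_summed_two_region_case(self):
        w = np.array([
            [0.0, 1.0, 2.0, 3.0],
            [1.0, 0.0, 4.0, 5.0],
            [2.0, 4.0, 0.0, 6.0],
            [3.0, 5.0, 6.0, 0.0],
        ])
        out, regions = d.aggregate_structural(w, ["A", "A", "B", "B"])
        # A-B weight: w02+w03+w12+w13 = 2+3+4+5 = 14; diagonal zeroed
        assert out[regions.index("A"), regions.index("B")] == 14.0
        assert out[0, 0] == 0.0 and out[1, 1] == 0.0

    def test_invariant_to_node_permutation(self, rng):
        w = rng.uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        members = ["A", "B", "A", "B", "A", "B"]
        out1, _ = d.aggregate_structural(w, members)
        perm = rng.permutation(6)
        out2, _ = d.aggregate_structural(
            w[np.ix_(perm, perm)], [members[i] for i in perm]
        )
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_unmapped_node_rejected(self):
        with pytest.raises(ValueError):
            d.aggregate_structural(np.zeros((3, 3)), ["A", None, "B"])


class TestScFcCorrelation:
    def test_identical_matrices_give_one(self, rng):
        m = rng.uniform(0, 1, (6, 6))
        m = (m + m.T) / 2
        assert d.sc_fc_correlation(m, m) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self, rng):
        rs = []
        for _ in range(20):
            a = rng.standard_normal((30, 30))
            b = rng.standard_normal((30, 30))
            rs.append(d.sc_fc_correlation((a + a.T) / 2, (b + b.T) / 2))
        assert np.abs(np.mean(rs)) < 0.05
        assert np.mean(np.abs(rs) < 0.15) > 0.9

    def test_subset_restriction(self, rng):
        m = rng.uniform(0, 1, (8, 8))
        m = (m + m.T) / 2
        other = m.copy()
        other[6:, :] = 0.0
        other[:, 6:] = 0.0
        assert d.sc_fc_correlation(m, other, subset=range(6)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            d.sc_fc_correlation(m, other, subset=[0, 1])

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            d.sc_fc_correlation(np.ones((4, 4)), np.ones((4, 4)))


class TestStageContrast:
    def test_identical_stages_nothing_significant(self, rng):
        mats = rng.standard_normal((6, 5, 5))
        mats = (mats + mats.transpose(0, 2, 1)) / 2
        res = d.stage_contrast(mats, mats.copy())
        assert not res.significant.any()
        np.testing.assert_allclose(res.mean_difference, 0.0, atol=1e-12)

    def test_planted_uniform_drop_detected_globally(self, rng):
        base = rng.standard_normal((20, 6, 6)) * 0.02
        base = (base + base.transpose(0, 2, 1)) / 2
        a = base + 0.5
        b = base + 0.3  # uniform drop of 0.2 in stage B
        res = d.stage_contrast(a, b)
        iu = np.triu_indices(6, 1)
        assert res.significant[iu].all()
        assert res.mean_difference[iu].mean() == pytest.approx(0.2, abs=0.02)

    def test_fdr_rejections_match_hand_computed_bh(self, rng):
        a = rng.standard_normal((10, 6, 6))
        a = (a + a.transpose(0, 2, 1)) / 2
        b = a + rng.standard_normal((10, 6, 6)) * 0.3
        b = (b + b.transpose(0, 2, 1)) / 2
        res = d.stage_contrast(a, b, alpha=0.05)
        iu = np.triu_indices(6, 1)
        p = res.p_values[iu]
        # Benjamini-Hochberg by hand: largest i with p_(i) <= i/m * alpha
        order = np.argsort(p)
        m = len(p)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        below = np.nonzero(np.sort(p) <= thresh)[0]
        expected = np.zeros(m, dtype=bool)
        if len(below):
            expected[order[: below.max() + 1]] = True
        np.testing.assert_array_equal(res.significant[iu], expected)

    def test_rsn_blocks_report_means_and_counts(self, rng):
        base = rng.standard_normal((8, 6, 6)) * 0.02
        base = (base + base.transpose(0, 2, 1)) / 2
        labels = ["DMN", "DMN", "DMN", "DAN", "DAN", "DAN"]
        res = d.stage_contrast(base + 0.4, base, rsn_labels=labels)
        assert res.block_mean.loc["DMN", "DAN"] == pytest.approx(0.4, abs=0.05)
        assert res.block_sig_count.loc["DMN", "DMN"] == 3  # 3 within-DMN edges

    def test_too_few_participants_rejected(self, rng):
        mats = rng.standard_normal((3, 4, 4))
        with pytest.raises(ValueError):
            d.stage_contrast(mats, mats)


class TestStageSummaries:
    def test_stage_means_built_from_matching_windows_only(self):
        cohort = d.sleep_cohort(n_subjects=3, n_regions=8, duration=1040.0, seed=2)
        summary = d.stage_mean_matrices(cohort)
        spec = d.WindowSpec(50)
        ts, hyp = cohort[0]
        mats = d.windowed_connectivity(ts, spec)
        stages = d.window_stage_labels(hyp, [(m.start, m.stop) for m in mats], ts.tr)
        for stage in set(stages):
            expected = np.mean(
                [m.matrix for m, s in zip(mats, stages) if s == stage], axis=0
            )
            np.testing.assert_allclose(
                summary[stage][ts.subject], expected, atol=1e-12
            )

    def test_modularity_and_sc_fc_tables_cover_all_pairs(self):
        cohort = d.sleep_cohort(n_subjects=3, n_regions=8, duration=1040.0, seed=2)
        summary = d.stage_mean_matrices(cohort)
        qdf = d.stage_modularity(summary, iterations=5, seed=0)
        n_pairs = sum(len(v) for v in summary.values())
        assert len(qdf) == n_pairs
        assert ((qdf.q_w >= -1) & (qdf.q_w <= 1)).all()
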