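import numpy as np
import pytest
from scipy import stats

import ednanet as en
from ednanet.metrics import PairScore
from conftest import make_index, simulate_index


def ps(a, b, metric, score):
    d = "unsigned"
    if metric in {"pearson", "spearman"}:
        d = "copresence" if score >= 0 else "exclusion"
    return PairScore(a, b, metric, score, d)


class TestSelectTails:
    def test_counts_both_tails(self):
        scores = [ps("A", f"B{i}", "pearson", s)
                  for i, s in enumerate(np.linspace(-0.9, 0.9, 10))]
        cands = en.select_tails(scores, top_k=3, bottom_k=3)
        selected = [c for c in cands if "pearson" in c.metric_directions]
        assert len(selected) == 6

    def test_all_selected_when_pool_small(self):
        scores = [ps("A", f"B{i}", "pearson", 0.1 * i) for i in range(5)]
        cands = en.select_tails(scores, top_k=500, bottom_k=500)
        assert sum("pearson" in c.metric_directions for c in cands) == 5

    def test_tie_break_prefers_smaller_pair_id(self):
        scores = [
            ps("A", "Z", "pearson", 0.5),
            ps("A", "B", "pearson", 0.5),  # tied at the boundary
            ps("A", "M", "pearson", 0.9),
        ]
        cands = en.select_tails(scores, top_k=2, bottom_k=0)
        chosen = {c.pair for c in cands if "pearson" in c.metric_directions}
        assert chosen == {("A", "M"), ("A", "B")}

    def test_dissimilarity_direction_by_tail(self):
        scores = [ps("A", f"B{i}", "bray_curtis", v)
                  for i, v in enumerate(np.linspace(0.05, 0.95, 10))]
        cands = en.select_tails(scores, top_k=2, bottom_k=2)
        dirs = {c.pair: c.metric_directions.get("bray_curtis") for c in cands
                if "bray_curtis" in c.metric_directions}
        assert list(dirs.values()).count("copresence") == 2
        assert list(dirs.values()).count("exclusion") == 2

    def test_mutual_information_never_selects_bottom(self):
        scores = [ps("A", f"B{i}", "mutual_information", 0.1 * i) for i in range(10)]
        cands = en.select_tails(scores, top_k=3, bottom_k=3)
        sel = [c for c in cands if "mutual_information" in c.metric_directions]
        assert len(sel) == 3
        assert all(c.metric_scores["mutual_information"] >= 0.7 for c in sel)


class TestConsensusFilter:
    def make(self, directions):
        c = en.EdgeCandidate("A", "B")
        c.metric_directions = dict(directions)
        c.metric_scores = {m: 0.5 for m in directions}
        return c

    def test_unanimous_pair_kept_with_sign(self):
        kept, _ = en.consensus_filter(
            [self.make({"pearson": "copresence", "spearman": "copresence"})]
        )
        assert len(kept) == 1 and kept[0].sign == "copresence"

    def test_conflicting_directions_dropped(self):
        kept, dropped = en.consensus_filter(
            [self.make({"pearson": "copresence", "bray_curtis": "exclusion"})]
        )
        assert kept == [] and dropped["conflicting_sign"] == 1

    def test_mi_only_is_below_support(self):
        kept, dropped = en.consensus_filter([self.make({"mutual_information": "unsigned"})])
        assert kept == [] and dropped["low_support"] == 1

    def test_mi_contributes_support_but_not_sign(self):
        kept, _ = en.consensus_filter(
            [self.make({"mutual_information": "unsigned", "kld": "exclusion"})]
        )
        assert len(kept) == 1 and kept[0].sign == "exclusion" and kept[0].support == 2


class TestRebootAndBootstrap:
    def test_null_sample_contract(self, small_null_index):
        a, b = small_null_index.otu_ids[:2]
        null = en.reboot_null(small_null_index, a, b, "pearson", n_perm=50, seed=3)
        again = en.reboot_null(small_null_index, a, b, "pearson", n_perm=50, seed=3)
        assert null.shape == (50,)
        np.testing.assert_array_equal(null, again)
        assert en.reboot_null(small_null_index, a, b, "pearson", n_perm=50,
                              seed=4)[0] != null[0]

    def test_null_centers_on_independence(self, small_null_index):
        a, b = small_null_index.otu_ids[:2]
        null = en.reboot_null(small_null_index, a, b, "pearson", n_perm=200, seed=0)
        assert abs(null.mean()) < 0.15

    def test_bootstrap_of_perfect_correlation(self):
        x = np.linspace(0.1, 1.0, 30)
        idx = make_index(np.vstack([x, x]), otus=["A", "B"])
        boot = en.bootstrap_scores(idx, "A", "B", "pearson", n_boot=40, seed=1)
        assert boot.shape == (40,)
        np.testing.assert_allclose(boot, 1.0)

    def test_bootstrap_deterministic(self, small_null_index):
        a, b = small_null_index.otu_ids[2:4]
        b1 = en.bootstrap_scores(small_null_index, a, b, "spearman", n_boot=30, seed=9)
        b2 = en.bootstrap_scores(small_null_index, a, b, "spearman", n_boot=30, seed=9)
        np.testing.assert_array_equal(b1, b2)


class TestMetricPvalue:
    def test_observed_at_null_mean(self):
        null = np.array([0.0, 0.1, -0.1, 0.05, -0.05])
        p, _ = en.metric_pvalue(null.mean(), null, np.array([0.5, 0.6]))
        assert p == pytest.approx(1.0)

    def test_five_sigma(self):
        rng = np.random.default_rng(0)
        null = rng.normal(0, 1, 2000)
        obs = null.mean() + 5 * null.std(ddof=1)
        p, _ = en.metric_pvalue(obs, null, np.array([0.5, 0.6]))
        assert p == pytest.approx(2 * stats.norm.sf(5), rel=1e-9)

    def test_stability_requires_null_mean_outside_boot_ci(self):
        null = np.random.default_rng(1).normal(0, 0.1, 100)
        boot_containing = np.random.default_rng(2).normal(0.0, 0.2, 100)
        _, (_, _, stable) = en.metric_pvalue(0.9, null, boot_containing)
        assert not stable
        boot_away = np.random.default_rng(3).normal(0.9, 0.02, 100)
        _, (_, _, stable) = en.metric_pvalue(0.9, null, boot_away)
        assert stable

    def test_zero_variance_null(self):
        null = np.zeros(100)
        p_eq, _ = en.metric_pvalue(0.0, null, np.array([1.0, 2.0]))
        p_ne, _ = en.metric_pvalue(0.5, null, np.array([1.0, 2.0]))
        assert p_eq == 1.0
        assert p_ne == pytest.approx(1 / 101)


class TestBrownMerge:
    def test_independence_limit_is_fisher(self):
        rng = np.random.default_rng(0)
        null = rng.uniform(size=(5000, 2))
        merged = en.brown_merge([0.5, 0.5], null, floor=1e-6)
        X = -2 * np.log(0.5) * 2
        assert merged == pytest.approx(stats.chi2.sf(X, 4), abs=0.02)

    def test_duplicated_pvalues_collapse_to_common_p(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(size=5000)
        null = np.column_stack([u, u])  # perfectly dependent replicates
        merged = en.brown_merge([0.3, 0.3], null, floor=1e-6)
        assert merged == pytest.approx(0.3, abs=0.02)

    def test_all_ones_merge_to_one(self):
        null = np.random.default_rng(2).uniform(size=(200, 3))
        assert en.brown_merge([1.0, 1.0, 1.0], null) == pytest.approx(1.0)

    def test_single_pvalue_passes_through(self):
        assert en.brown_merge([0.07], np.ones((10, 1))) == pytest.approx(0.07)

    def test_zero_pvalue_clamped_to_floor(self):
        null = np.random.default_rng(3).uniform(size=(500, 2))
        merged = en.brown_merge([0.0, 0.5], null, floor=1 / 101)
        assert 0 < merged < 1


def brute_bh(p):
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        q[i] = prev
    return q


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.07], [0.07]),
            ([0.05, 1.0], [0.10, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(en.bh_adjust(p), expected)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(en.bh_adjust(p), brute_bh(p), atol=1e-12)


class TestInferNetwork:
    def test_same_seed_gives_byte_identical_edge_table(self):
        params = en.CommunityParams(n_otus=12, n_samples=40, n_env_gradients=1,
                                    planted_edges=(), seed=8)
        idx, _ = simulate_index(params)
        cfg = en.InferenceConfig(n_perm=40, n_boot=40, seed=8)
        t1 = en.infer_network(idx, cfg).edge_table().to_csv(index=False)
        t2 = en.infer_network(idx, cfg).edge_table().to_csv(index=False)
        assert t1 == t2

    def test_q_threshold_monotonicity(self):
        planted = en.default_planted_edges(3, 1, 0.9, 16)
        params = en.CommunityParams(n_otus=16, n_samples=40, planted_edges=planted, seed=2)
        idx, _ = simulate_index(params)
        loose = en.infer_network(idx, en.InferenceConfig(n_perm=40, n_boot=40,
                                                         q_threshold=0.2, seed=2))
        strict = en.infer_network(idx, en.InferenceConfig(n_perm=40, n_boot=40,
                                                          q_threshold=0.01, seed=2))
        assert strict.edge_pairs() <= loose.edge_pairs()

    def test_recovers_strong_planted_pair(self):
        planted = (("OTU00", "OTU01", "copresence", 0.95),)
        params = en.CommunityParams(n_otus=12, n_samples=50, n_env_gradients=0,
                                    planted_edges=planted, seed=4)
        idx, _ = simulate_index(params)
        net = en.infer_network(idx, en.InferenceConfig(n_perm=60, n_boot=60, seed=4))
        assert ("OTU00", "OTU01") in net.edge_pairs()
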