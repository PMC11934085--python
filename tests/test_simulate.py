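from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import ednanet as en


class TestGenerateCommunity:
    def test_null_latent_correlations_center_on_zero(self):
        params = en.CommunityParams(n_otus=40, n_samples=200, n_env_gradients=0,
                                    planted_edges=(), rare_fraction=0.0, seed=0)
        truth = en.generate_community(params)
        log_ab = np.log(truth.abundance.to_numpy())
        corr = np.corrcoef(log_ab)
        vals = corr[np.triu_indices_from(corr, k=1)][:500]
        assert abs(np.mean(vals)) < 0.05

    def test_planted_pair_strongly_correlated(self):
        planted = (("OTU00", "OTU01", "copresence", 0.9),)
        params = en.CommunityParams(n_otus=30, n_samples=200, rare_fraction=0.0,
                                    planted_edges=planted, seed=1)
        truth = en.generate_community(params)
        log_ab = np.log(truth.abundance.to_numpy())
        r = np.corrcoef(log_ab[0], log_ab[1])[0, 1]
        assert r > 0.6

    def test_planted_exclusion_negatively_correlated(self):
        planted = (("OTU00", "OTU01", "exclusion", 0.9),)
        params = en.CommunityParams(n_otus=30, n_samples=200, rare_fraction=0.0,
                                    planted_edges=planted, seed=2)
        truth = en.generate_community(params)
        log_ab = np.log(truth.abundance.to_numpy())
        assert np.corrcoef(log_ab[0], log_ab[1])[0, 1] < -0.6

    def test_deterministic_under_seed(self):
        params = en.CommunityParams(n_otus=20, n_samples=30, seed=5)
        t1 = en.generate_community(params)
        t2 = en.generate_community(params)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        assert t1.marker_panels == t2.marker_panels

    def test_rare_otus_thinned_below_quarter_occupancy(self):
        params = en.CommunityParams(n_otus=40, n_samples=60, rare_fraction=0.2, seed=3)
        truth = en.generate_community(params)
        occupancy = (truth.abundance.to_numpy() > 0).mean(axis=1)
        assert (occupancy < 0.25).sum() >= 6  # floor(0.2 * 40) = 8 thinned

    def test_unknown_planted_otu_rejected(self):
        params = en.CommunityParams(n_otus=10, n_samples=20,
                                    planted_edges=(("NOPE", "OTU1", "copresence", 0.5),))
        with pytest.raises(ValueError, match="unknown OTU"):
            en.generate_community(params)

    def test_panels_cover_community_and_overlap(self):
        params = en.CommunityParams(seed=4)
        truth = en.generate_community(params)
        a, b = map(set, truth.marker_panels)
        assert a | b == set(truth.otu_ids)
        assert a & b  # panels overlap to exercise the ensemble


class TestSampleReads:
    def test_column_sums_equal_drawn_depths_across_markers(self):
        truth = en.generate_community(en.CommunityParams(n_otus=30, n_samples=20, seed=6))
        t1, t2 = en.sample_reads(truth)
        # both markers observe the same per-sample sequencing depths
        np.testing.assert_array_equal(
            t1.counts.sum(axis=0).to_numpy(), t2.counts.sum(axis=0).to_numpy()
        )

    def test_structural_zeros_outside_panel(self):
        truth = en.generate_community(en.CommunityParams(n_otus=30, n_samples=20, seed=6))
        tables = en.sample_reads(truth)
        for t, panel in zip(tables, truth.marker_panels):
            assert set(t.otu_ids) == set(panel)

    def test_higher_efficiency_raises_read_share(self):
        m = 10
        eff = np.ones((m, 1))
        eff[0, 0] = 10.0
        base = en.CommunityParams(n_otus=m, n_samples=40, n_markers=1,
                                  marker_coverage=(1.0,), rare_fraction=0.0,
                                  amplification_efficiencies=tuple(map(tuple, eff)),
                                  seed=7)
        flat = en.CommunityParams(n_otus=m, n_samples=40, n_markers=1,
                                  marker_coverage=(1.0,), rare_fraction=0.0,
                                  amplification_efficiencies=tuple(map(tuple, np.ones((m, 1)))),
                                  seed=7)
        reads_hi = en.sample_reads(en.generate_community(base))[0]
        reads_flat = en.sample_reads(en.generate_community(flat))[0]
        share_hi = reads_hi.counts.loc["OTU0"].sum() / reads_hi.counts.to_numpy().sum()
        share_flat = reads_flat.counts.loc["OTU0"].sum() / reads_flat.counts.to_numpy().sum()
        assert share_hi > share_flat

    def test_zero_efficiency_forbidden(self):
        eff = tuple(map(tuple, np.zeros((5, 1))))
        params = en.CommunityParams(n_otus=5, n_samples=10, n_markers=1,
                                    marker_coverage=(1.0,),
                                    amplification_efficiencies=eff)
        with pytest.raises(ValueError, match="positive"):
            en.sample_reads(en.generate_community(params))


class TestPlantedMetaweb:
    def test_full_fraction_reproduces_planted_pairs(self):
        planted = en.default_planted_edges(4, 2, 0.9, 20)
        truth = en.generate_community(
            en.CommunityParams(n_otus=20, n_samples=15, planted_edges=planted, seed=8)
        )
        records = en.planted_metaweb(truth, 1.0, 0)
        assert {(r.consumer_otu, r.resource_otu) for r in records} == {
            (a, b) for a, b, _, _ in planted
        }

    def test_extra_records_disjoint_from_planted(self):
        planted = en.default_planted_edges(3, 0, 0.9, 20)
        truth = en.generate_community(
            en.CommunityParams(n_otus=20, n_samples=15, planted_edges=planted, seed=9)
        )
        records = en.planted_metaweb(truth, 0.0, 5)
        assert len(records) == 5
        planted_sets = {frozenset((a, b)) for a, b, _, _ in planted}
        assert all(
            frozenset((r.consumer_otu, r.resource_otu)) not in planted_sets
            for r in records
        )

    def test_deterministic(self):
        truth = en.generate_community(en.CommunityParams(n_otus=15, n_samples=10, seed=10))
        assert en.planted_metaweb(truth, 0.0, 4) == en.planted_metaweb(truth, 0.0, 4)


class TestRecoveryMetrics:
    def fake_net(self, edges, nodes):
        return SimpleNamespace(
            edges=[SimpleNamespace(otu_a=a, otu_b=b, sign=s) for a, b, s in edges],
            nodes=list(nodes),
        )

    def truth_with(self, planted, n=10):
        return en.generate_community(
            en.CommunityParams(n_otus=n, n_samples=15, planted_edges=planted, seed=11)
        )

    def test_perfect_recovery(self):
        planted = (("OTU0", "OTU1", "copresence", 0.9),)
        truth = self.truth_with(planted)
        net = self.fake_net([("OTU0", "OTU1", "copresence")], truth.otu_ids)
        out = en.recovery_metrics(net, truth)
        assert out["precision"] == out["recall"] == out["sign_accuracy"] == 1.0

    def test_empty_inference(self):
        planted = (("OTU0", "OTU1", "copresence", 0.9),)
        truth = self.truth_with(planted)
        out = en.recovery_metrics(self.fake_net([], truth.otu_ids), truth)
        assert out["recall"] == 0.0 and out["precision"] is None

    def test_half_recovered(self):
        planted = (("OTU0", "OTU1", "copresence", 0.9),
                   ("OTU2", "OTU3", "exclusion", 0.9))
        truth = self.truth_with(planted)
        net = self.fake_net([("OTU0", "OTU1", "copresence")], truth.otu_ids)
        out = en.recovery_metrics(net, truth)
        assert out["precision"] == 1.0 and out["recall"] == 0.5
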