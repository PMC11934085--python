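import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis as scipy_braycurtis

import ednanet as en
from ednanet.metrics import UndefinedScoreError, _equal_frequency_bins
from conftest import make_index


class TestPearsonSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # cov/(sx*sy) by hand
        ],
    )
    def test_pearson_known_values(self, x, y, expected):
        assert en.pearson(x, y) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 8, 27), 1.0),  # monotone nonlinear
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # ranks equal values here
        ],
    )
    def test_spearman_known_values(self, x, y, expected):
        assert en.spearman(x, y) == pytest.approx(expected)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            en.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedScoreError):
            en.spearman([1, 2, 3], [5, 5, 5])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(20), rng.random(20)
        assert en.pearson(3 * x + 2, y) == pytest.approx(en.pearson(x, y))
        assert en.spearman(np.exp(x), y) == pytest.approx(en.spearman(x, y))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 0), (0, 1), 1.0),
            ((2, 1), (1, 1), 0.2),  # |1|+|0| over 5
        ],
    )
    def test_known_values(self, x, y, expected):
        assert en.bray_curtis(x, y) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedScoreError):
            en.bray_curtis([0, 0], [0, 0])

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(15), rng.random(15)
        assert en.bray_curtis(7 * x, 7 * y) == pytest.approx(en.bray_curtis(x, y))


class TestKld:
    def test_identical_distributions_zero(self):
        assert en.kld([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            assert en.kld(rng.random(10), rng.random(10)) >= 0

    def test_jeffreys_closed_form(self):
        # KL(P||Q) + KL(Q||P) for P=(.5,.5), Q=(.9,.1), no pseudocount
        p, q = (0.5, 0.5), (0.9, 0.1)
        expected = sum(
            pi * math.log(pi / qi) + qi * math.log(qi / pi) for pi, qi in zip(p, q)
        )
        assert en.kld(p, q, pseudocount=0.0) == pytest.approx(expected)


class TestMutualInformation:
    def test_constant_vectors_share_no_information(self):
        assert en.mutual_information([1, 1, 1, 1], [7, 7, 7, 7], 2) == 0.0

    @pytest.mark.parametrize("n_bins", [2, 4])
    def test_identity_gives_log2_bins(self, n_bins):
        x = np.arange(16.0)
        assert en.mutual_information(x, x, n_bins) == pytest.approx(math.log2(n_bins))

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(30), rng.random(30)
        assert en.mutual_information(x, y) == pytest.approx(en.mutual_information(y, x))

    def test_tied_values_share_a_bin(self):
        bins = _equal_frequency_bins(np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0]), 4)
        assert len(set(bins[:3])) == 1

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            en.mutual_information([1, 2, 3], [1, 2, 3], n_bins=4)


def brute_mi(x, y, n_bins):
    bx = _equal_frequency_bins(np.asarray(x, float), n_bins)
    by = _equal_frequency_bins(np.asarray(y, float), n_bins)
    n = len(x)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            pij = np.mean((bx == i) & (by == j))
            pi, pj = np.mean(bx == i), np.mean(by == j)
            if pij > 0:
                mi += pij * math.log2(pij / (pi * pj))
    return mi


class TestOracleEquivalence:
    """Each measure matches an independent reference on random pairs."""

    def test_all_metrics_match_references(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            x, y = rng.random(20), rng.random(20)
            assert en.pearson(x, y) == pytest.approx(
                stats.pearsonr(x, y).statistic, abs=1e-10
            )
            assert en.spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-10
            )
            assert en.bray_curtis(x, y) == pytest.approx(
                scipy_braycurtis(x, y), abs=1e-10
            )
            p = (x + 1e-8) / (x + 1e-8).sum()
            q = (y + 1e-8) / (y + 1e-8).sum()
            jeffreys = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
            assert en.kld(x, y) == pytest.approx(jeffreys, abs=1e-10)
            assert en.mutual_information(x, y, 4) == pytest.approx(
                brute_mi(x, y, 4), abs=1e-10
            )


class TestScoreAllPairs:
    def test_pair_and_metric_counts(self):
        idx = make_index(np.random.default_rng(4).random((4, 10)))
        scores, skipped = en.score_all_pairs(idx)
        assert len(scores) == 6 * 5 and not skipped

    def test_constant_otu_recorded_as_skip(self):
        vals = np.vstack([np.full(10, 0.5), np.random.default_rng(5).random(10)])
        idx = make_index(vals, otus=["const", "var"])
        scores, skipped = en.score_all_pairs(idx, metrics=("pearson",))
        assert scores == []
        assert skipped == [("const", "var", "pearson")]

    def test_study_scale_pair_count(self):
        idx = make_index(np.random.default_rng(6).random((54, 10)))
        scores, _ = en.score_all_pairs(idx, metrics=("pearson",))
        assert len(scores) == 1431  # C(54, 2)

    def test_symmetry_of_all_measures(self):
        rng = np.random.default_rng(7)
        x, y = rng.random(25), rng.random(25)
        for f in (en.pearson, en.spearman, en.bray_curtis, en.kld,
                  en.mutual_information):
            assert f(x, y) == pytest.approx(f(y, x), abs=1e-12)
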