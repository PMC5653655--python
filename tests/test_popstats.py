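"""Population statistics: closed forms, oracles, invariances."""

import numpy as np
import pytest

from gclayer import popstats
from gclayer.popstats import (
    DegenerateCovarianceError,
    mean_pairwise_pearson,
    normalized_metric,
    population_correlation,
    population_correlation_hetero,
    population_sparseness,
    robustness,
    subsample_curve,
    total_variance,
)


class TestSparseness:
    @pytest.mark.parametrize("x,expected", [
        ([[1, 0, 0, 0]], 1.0),          # single active neuron
        ([[1, 1, 1, 1]], 0.0),          # uniform activity
        ([[1, 1, 0, 0]], 2 / 3),        # hand evaluation
    ])
    def test_hand_values(self, x, expected):
        assert population_sparseness(np.array(x, dtype=float)) == pytest.approx(expected)

    def test_all_zero_pattern_counts_as_one(self):
        X = np.array([[0, 0, 0, 0], [1, 0, 0, 0]], dtype=float)
        assert population_sparseness(X) == pytest.approx(1.0)

    def test_needs_two_neurons(self):
        with pytest.raises(ValueError):
            population_sparseness(np.ones((3, 1)))


class TestTotalVariance:
    def test_constant_ensemble_is_zero(self):
        assert total_variance(np.ones((10, 4))) == 0.0

    def test_additivity_of_independent_variances(self, rng):
        X = (rng.random((40_000, 2)) < 0.5).astype(float)  # var 0.25 each
        assert total_variance(X) == pytest.approx(0.5, rel=0.05)

    def test_bernoulli_closed_form(self, rng):
        N, f = 30, 0.2
        X = (rng.random((40_000, N)) < f).astype(float)
        assert total_variance(X) == pytest.approx(N * f * (1 - f), rel=0.05)

    def test_single_pattern_rejected(self):
        with pytest.raises(ValueError):
            total_variance(np.ones((1, 4)))


class TestPopulationCorrelation:
    def test_identity_covariance_is_zero(self):
        for n in (2, 5, 50):
            assert population_correlation(cov=np.eye(n)) == 0.0

    def test_rank_one_is_one(self):
        assert population_correlation(cov=np.ones((4, 4))) == pytest.approx(1.0)

    def test_identical_neurons_ensemble(self, rng):
        col = rng.random(100)
        X = np.tile(col[:, None], (1, 4))
        assert population_correlation(X) == pytest.approx(1.0)

    def test_two_neuron_closed_form(self):
        # eigenvalues 1.6, 0.4; 2*(sqrt(1.6)/(sqrt(1.6)+sqrt(0.4)) - 1/2) = 1/3
        val = population_correlation(cov=np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert val == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_characteristic_polynomial_oracle(self, rng):
        # brute-force eigenvalues of a 2x2 covariance via the quadratic formula
        X = rng.random((200, 2)) @ rng.random((2, 2))
        c = np.cov(X, rowvar=False, ddof=1)
        tr, det = c[0, 0] + c[1, 1], c[0, 0] * c[1, 1] - c[0, 1] ** 2
        disc = np.sqrt(tr**2 - 4 * det)
        lam = np.array([(tr + disc) / 2, (tr - disc) / 2])
        expected = 2.0 * (np.sqrt(lam).max() / np.sqrt(lam).sum() - 0.5)
        assert population_correlation(X) == pytest.approx(expected, abs=1e-10)

    def test_permutation_and_scale_invariance(self, rng):
        X = rng.random((100, 6))
        base = population_correlation(X)
        perm = rng.permutation(6)
        assert population_correlation(X[:, perm]) == pytest.approx(base, abs=1e-12)
        assert population_correlation(3.7 * X) == pytest.approx(base, abs=1e-10)

    def test_zero_covariance_raises_distinct_error(self):
        with pytest.raises(DegenerateCovarianceError):
            population_correlation(cov=np.zeros((3, 3)))


class TestHeteroVariant:
    def test_identity_and_rank_one(self):
        assert population_correlation_hetero(cov=np.eye(4)) == 0.0
        assert population_correlation_hetero(cov=np.ones((4, 4))) == pytest.approx(1.0)

    def test_unequal_diagonal_dissociation(self):
        cov = np.diag([1.0, 4.0, 9.0])
        assert population_correlation_hetero(cov=cov) == 0.0
        assert population_correlation(cov=cov) > 0.0

    def test_zero_variance_neuron_dropped(self, rng):
        X = rng.random((50, 3))
        X[:, 1] = 2.0
        val = population_correlation_hetero(X)
        assert val == pytest.approx(population_correlation_hetero(X[:, [0, 2]]))


class TestPearson:
    def test_independent_near_zero(self, rng):
        X = rng.random((5000, 4))
        assert abs(mean_pairwise_pearson(X)) < 0.05

    def test_identical_neurons(self, rng):
        X = np.tile(rng.random(50)[:, None], (1, 3))
        assert mean_pairwise_pearson(X) == pytest.approx(1.0)

    def test_matches_bruteforce_pairwise(self, rng):
        X = rng.random((100, 3))
        X[:, 2] = -X[:, 0] + 0.1 * rng.random(100)
        vals = []
        for i in range(3):
            for j in range(i + 1, 3):
                vals.append(np.corrcoef(X[:, i], X[:, j])[0, 1])
        assert mean_pairwise_pearson(X) == pytest.approx(np.mean(vals), abs=1e-12)


class TestNormalizedAndRobustness:
    def test_ratio_and_log(self):
        assert normalized_metric(1.0, 1.0) == 1.0
        assert normalized_metric(1.0, 1.0, log10=True) == 0.0
        assert normalized_metric(0.05, 0.1) == pytest.approx(0.5)
        assert normalized_metric(8.0, 1.0) == 8.0

    def test_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            normalized_metric(1.0, 0.0)

    @pytest.mark.parametrize("vals,expected", [
        ([2.0, 3.0], 1.0), ([0.5, 0.9], 0.0),
        ([0.5, 2, 3, 0.1, 1.5, 9, 0.2, 0.3, 1.01, 0.99], 0.5),
    ])
    def test_robustness_counting(self, vals, expected):
        assert robustness(vals) == expected

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            robustness([])


class TestSubsampleCurve:
    def test_full_population_equals_direct_ratio(self, rng):
        X_out = rng.random((200, 20))
        X_in = rng.random((200, 10))
        df = subsample_curve(X_out, X_in, fractions=[1.0], seed=0)
        direct = population_correlation(X_out) / population_correlation(X_in)
        assert df["mean"].iloc[0] == pytest.approx(direct)
        assert df["sd"].iloc[0] == 0.0

    def test_small_fractions_skipped(self, rng):
        X = rng.random((50, 10))
        df = subsample_curve(X, X, fractions=[0.05, 0.5], n_resamples=3, seed=0)
        assert len(df) == 1
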