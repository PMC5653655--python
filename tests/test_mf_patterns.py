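"""Dichotomized-Gaussian generator: kernel, fit, sampling, rate mapping."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from gclayer import mf_patterns
from gclayer.mf_patterns import (
    CorrelationSpec,
    fit_dichotomized_gaussian,
    joint_active_probability,
    make_correlated_patterns,
    patterns_to_rates,
    sample_patterns,
    target_binary_correlation,
)


class TestCorrelationKernel:
    def test_sigma_zero_gives_identity(self, geom):
        R = target_binary_correlation(geom.mf_positions, 0.0)
        assert np.array_equal(R, np.eye(geom.n_mf))

    @pytest.mark.parametrize("d,sigma", [(20.0, 20.0), (5.0, 5.0)])
    def test_distance_equal_to_radius(self, d, sigma):
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        R = target_binary_correlation(pos, sigma)
        assert R[0, 1] == pytest.approx(np.exp(-0.5))  # ~0.6065

    def test_monotone_decay_with_distance(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [15.0, 0, 0], [40.0, 0, 0]])
        R = target_binary_correlation(pos, 20.0)
        decays = R[0, 1:]
        assert (np.diff(decays) < 0).all()
        assert (np.diag(R) == 1).all()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CorrelationSpec(f_mf=1.5, sigma=10.0)
        with pytest.raises(ValueError):
            CorrelationSpec(f_mf=0.5, sigma=-1.0)


class TestOrthantProbability:
    def test_matches_scipy_bivariate_cdf(self):
        # independent dual route: Owen's T closed form vs numerical MVN CDF
        for f in (0.2, 0.5, 0.8):
            t = norm.ppf(1 - f)
            for rho in (-0.6, 0.0, 0.4, 0.9):
                mvn = multivariate_normal(
                    mean=[0, 0], cov=[[1, rho], [rho, 1]]
                )
                # P(Z1>t, Z2>t) = Phi2(-t, -t; rho) by symmetry
                expected = mvn.cdf([-t, -t])
                got = joint_active_probability(t, np.array([rho]))[0]
                assert got == pytest.approx(expected, abs=1e-6)


class TestDGFit:
    def test_closed_form_latent_at_half_activity(self):
        # at f = 0.5 the latent correlation is sin(pi * r / 2) exactly
        for r in (0.1, 0.3, 0.5, 0.8):
            dg = fit_dichotomized_gaussian(0.5, np.array([[1.0, r], [r, 1.0]]))
            assert dg.latent_corr[0, 1] == pytest.approx(np.sin(np.pi * r / 2), abs=1e-6)

    def test_independence_maps_to_zero(self):
        dg = fit_dichotomized_gaussian(0.5, np.eye(2))
        assert dg.latent_corr[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_latent_monotone_in_target(self):
        rs = np.linspace(0.0, 0.9, 10)
        for f in (0.2, 0.5, 0.7):
            lams = [
                fit_dichotomized_gaussian(f, np.array([[1, r], [r, 1.0]])).latent_corr[0, 1]
                for r in rs
            ]
            assert (np.diff(lams) > 0).all()

    def test_threshold_matches_marginal(self):
        dg = fit_dichotomized_gaussian(0.3, np.eye(3))
        assert 1 - norm.cdf(dg.threshold) == pytest.approx(0.3)

    def test_invalid_f(self):
        for f in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                fit_dichotomized_gaussian(f, np.eye(2))

    def test_psd_repair_unit_diagonal(self, geom):
        R = target_binary_correlation(geom.mf_positions, 20.0)
        dg = fit_dichotomized_gaussian(0.3, R)
        np.testing.assert_allclose(np.diag(dg.latent_corr), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(dg.latent_corr).min() > -1e-8
        assert dg.psd_distortion > 0  # repair was needed at sigma=20


class TestSampling:
    def test_sigma_zero_reduces_to_bernoulli(self):
        pos = np.zeros((2, 3))
        pos[1, 0] = 100.0
        dg = fit_dichotomized_gaussian(0.5, np.eye(2))
        ens = sample_patterns(dg, 10_000, seed=0)
        emp = np.corrcoef(ens.X.T.astype(float))[0, 1]
        assert abs(emp) < 3 / np.sqrt(10_000)
        assert ens.X.mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20_000))

    def test_pair_correlation_matches_fit(self):
        dg = fit_dichotomized_gaussian(0.5, np.array([[1, 0.5], [0.5, 1.0]]))
        ens = sample_patterns(dg, 100_000, seed=1)
        emp = np.corrcoef(ens.X.T.astype(float))[0, 1]
        assert emp == pytest.approx(0.5, abs=0.01)

    def test_mean_activity_and_histogram_spread(self, geom):
        ens = make_correlated_patterns(geom.mf_positions, 0.3, 20.0, 640, seed=2)
        frac = ens.X.mean(axis=1)
        assert frac.mean() == pytest.approx(0.3, abs=0.03)
        # correlated inputs widen the per-pattern active-fraction histogram
        assert frac.std() > np.sqrt(0.3 * 0.7 / geom.n_mf)

    def test_binary_output(self, geom):
        ens = make_correlated_patterns(geom.mf_positions, 0.5, 10.0, 32, seed=3)
        assert ens.is_binary()
        assert ens.n_patterns == 32 and ens.n_neurons == geom.n_mf


class TestRateMapping:
    def test_basic_mapping(self):
        rates = patterns_to_rates(np.array([[1, 0, 1]]), 50.0, 0.0)
        np.testing.assert_array_equal(rates, [[50.0, 0.0, 50.0]])

    def test_all_silent_and_all_active(self):
        assert (patterns_to_rates(np.zeros((2, 4))) == 0).all()
        assert (patterns_to_rates(np.ones((2, 4))) == 50.0).all()

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            patterns_to_rates(np.array([[0.5, 1.0]]))
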