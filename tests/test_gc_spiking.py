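"""Spiking granule-cell layer: Poisson inputs, LIF dynamics, count windows."""

import numpy as np
import pytest
from scipy.stats import kstest

from gclayer.anatomy import Connectivity
from gclayer.gc_spiking import (
    SpikeTrainSet,
    SpikingConfig,
    lif_rate_constant_current,
    run_spiking_condition,
    sample_mf_spikes,
    simulate_gc_layer,
)


def _single_gc(n_mf=4):
    return Connectivity(
        C=np.ones((1, n_mf), np.uint8), n_syn=n_mf,
        mf_indices=np.arange(n_mf)[None, :],
        dendrite_lengths=np.full((1, n_mf), 15.0),
    )


class TestMFSpikes:
    def test_zero_rate_is_empty(self):
        sp = sample_mf_spikes([0.0], 1000.0, seed=0)
        assert sp.trains[0].size == 0

    def test_realized_rate_matches_nominal(self):
        sp = sample_mf_spikes([50.0], 100_000.0, seed=1)
        rate = 1000.0 * sp.trains[0].size / 100_000.0
        assert rate == pytest.approx(50.0, abs=1.0)

    def test_refractory_respected(self):
        sp = sample_mf_spikes([200.0], 10_000.0, refractory=2.0, seed=2)
        assert np.diff(sp.trains[0]).min() >= 2.0

    def test_isi_matches_dead_time_exponential(self):
        # ISI - dead time ~ Exp(hazard) with hazard = r/(1 - r*t_ref)
        sp = sample_mf_spikes([50.0], 200_000.0, refractory=2.0, seed=3)
        isi = np.diff(sp.trains[0])
        hazard = 0.05 / (1 - 0.05 * 2.0)
        _, p = kstest((isi - 2.0) * hazard, "expon")
        assert p > 0.001

    def test_infeasible_rate(self):
        with pytest.raises(ValueError):
            sample_mf_spikes([600.0], 100.0, refractory=2.0)

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            sample_mf_spikes([-1.0], 100.0)


def test_spike_train_text_round_trip(tmp_path):
    sp = sample_mf_spikes([50.0, 0.0, 20.0], 500.0, seed=4)
    path = tmp_path / "spikes.tsv"
    sp.save_text(path)
    back = SpikeTrainSet.load_text(path, 500.0)
    assert len(back.trains) == 3
    for a, b in zip(sp.trains, back.trains):
        np.testing.assert_allclose(a, b, atol=1e-4)


class TestLIFReduction:
    def test_constant_current_matches_analytic_rate(self):
        """With synapses off, the integrator reproduces the closed-form LIF rate."""
        cfg = SpikingConfig()
        tau = cfg.c_m / cfg.g_leak
        for i_pa in (45.0, 60.0, 90.0):
            vinf = cfg.e_leak + i_pa / cfg.g_leak
            t_isi = cfg.t_ref + tau * np.log(
                (vinf - cfg.v_reset) / (vinf - cfg.v_threshold)
            )
            analytic = 1000.0 / t_isi
            simulated = lif_rate_constant_current(i_pa, cfg, duration=5000.0, dt=0.01)
            assert simulated == pytest.approx(analytic, rel=0.02)

    def test_subthreshold_current_is_silent(self):
        cfg = SpikingConfig()
        i_rheo = cfg.g_leak * (cfg.v_threshold - cfg.e_leak)  # 40 pA
        assert lif_rate_constant_current(0.9 * i_rheo, cfg) == 0.0


class TestSimulateGCLayer:
    def test_no_input_no_output(self):
        cfg = SpikingConfig()
        sp = sample_mf_spikes([0.0] * 4, cfg.t_settle + cfg.t_window, seed=0)
        counts, _ = simulate_gc_layer(sp, _single_gc(), cfg)
        assert (counts == 0).all()

    def test_three_input_threshold_calibration(self):
        """~3 concurrently active 50 Hz MFs are needed to drive spiking."""
        cfg = SpikingConfig()
        conn = _single_gc()
        p_spike = []
        for k in range(5):
            rates = [50.0] * k + [0.0] * (4 - k)
            fired = 0
            for rep in range(30):
                sp = sample_mf_spikes(rates, cfg.t_settle + cfg.t_window,
                                      seed=np.random.default_rng(100 * k + rep))
                counts, _ = simulate_gc_layer(sp, conn, cfg)
                fired += int(counts[0] > 0)
            p_spike.append(fired / 30)
        assert p_spike[0] == 0.0 and p_spike[1] <= 0.05
        assert p_spike[2] < 0.5 <= p_spike[3] <= p_spike[4]

    def test_counts_window_and_dtype(self, geom, conn4):
        cfg = SpikingConfig()
        rng = np.random.default_rng(5)
        rates = np.where(rng.random(geom.n_mf) < 0.5, 50.0, 0.0)
        sp = sample_mf_spikes(rates, cfg.t_settle + cfg.t_window, seed=rng)
        counts, _ = simulate_gc_layer(sp, conn4, cfg)
        assert counts.dtype == np.int64 and (counts >= 0).all()

    def test_dt_halving_stability(self):
        """Halving dt changes window counts by at most 1 spike per GC."""
        conn = _single_gc()
        rng = np.random.default_rng(7)
        cfg = SpikingConfig()
        sp = sample_mf_spikes([50.0] * 4, cfg.t_settle + cfg.t_window, seed=rng)
        c1, _ = simulate_gc_layer(sp, conn, cfg)
        from dataclasses import replace
        c2, _ = simulate_gc_layer(sp, conn, replace(cfg, dt=0.05))
        assert abs(int(c1[0]) - int(c2[0])) <= 1

    def test_voltage_bounded_by_threshold(self):
        cfg = SpikingConfig()
        sp = sample_mf_spikes([50.0] * 4, cfg.t_settle + cfg.t_window,
                              seed=np.random.default_rng(11))
        counts, v = simulate_gc_layer(sp, _single_gc(), cfg, record_voltage=True)
        assert np.nanmax(v) <= cfg.v_threshold + 5.0  # one-dt overshoot only

    def test_short_trains_rejected(self):
        sp = sample_mf_spikes([50.0] * 4, 50.0, seed=0)
        with pytest.raises(ValueError):
            simulate_gc_layer(sp, _single_gc(), SpikingConfig())


class TestRunCondition:
    def test_silent_pattern_gives_zero_row(self, geom, conn4):
        X = np.zeros((1, geom.n_mf), dtype=np.uint8)
        gc, mf = run_spiking_condition(X, conn4, SpikingConfig(), seed=0)
        assert (gc.X == 0).all() and (mf.X == 0).all()

    def test_poisson_variability_across_seeds(self, geom, conn4):
        X = np.tile((np.arange(geom.n_mf) < geom.n_mf // 2).astype(np.uint8), (1, 1))
        c1, _ = run_spiking_condition(X, conn4, SpikingConfig(), seed=1)
        c2, _ = run_spiking_condition(X, conn4, SpikingConfig(), seed=2)
        assert (c1.X != c2.X).any()

    def test_deterministic_under_seed(self, geom, conn4):
        X = np.tile((np.arange(geom.n_mf) % 2).astype(np.uint8), (2, 1))
        a, _ = run_spiking_condition(X, conn4, SpikingConfig(), seed=9)
        b, _ = run_spiking_condition(X, conn4, SpikingConfig(), seed=9)
        assert np.array_equal(a.X, b.X)

    def test_rejects_non_binary(self, conn4):
        with pytest.raises(ValueError):
            run_spiking_condition(np.full((1, conn4.n_mf), 2.0), conn4)
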