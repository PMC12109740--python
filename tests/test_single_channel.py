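"""Amplitude histograms, mixture fits, activity, lags, unitary conductance."""

import numpy as np
import pytest

from photokv import simulate, single_channel as sc
from photokv.traces import BLUE, UV, CurrentTrace, LightEvent


def _trace(i_pA, dt=0.04, v=120.0, events=()):
    n = len(i_pA)
    return CurrentTrace(
        time_ms=np.arange(n) * dt, i_pA=np.asarray(i_pA, float),
        v_mV=v, events=list(events), sampling_rate_khz=1.0 / dt,
    )


class TestHistogram:
    def test_constant_segment_single_occupied_bin(self):
        tr = _trace(np.zeros(1000))
        h = sc.build_histogram(tr, 0.0, 30.0)
        assert np.count_nonzero(h.counts) == 1
        assert h.counts.sum() == h.n_samples

    def test_fifty_percent_open_two_equal_levels(self):
        i = np.tile([0.0] * 10 + [19.0] * 10, 100)
        tr = _trace(i)
        h = sc.build_histogram(tr, 0.0, tr.time_ms[-1])
        occupied = h.counts[h.counts > 0]
        assert len(occupied) == 2
        assert occupied[0] == occupied[1]

    def test_transient_windows_masked(self):
        ev = LightEvent(10.0, 5.0, BLUE)
        i = np.zeros(2000)
        tr = _trace(i, events=[ev])
        h = sc.build_histogram(tr, 0.0, 79.0, mask_transients_ms=5.0)
        t = tr.time_ms
        expected = int(np.sum((t <= 79.0) & ~((t >= 5.0) & (t <= 15.0))))
        assert h.n_samples == expected
        assert h.n_samples < np.sum(t <= 79.0)

    def test_empty_segment_rejected(self):
        tr = _trace(np.zeros(100))
        with pytest.raises(ValueError):
            sc.build_histogram(tr, 2.0, 1.0)

    def test_generator_trace_modes_spaced_by_unitary_amplitude(self):
        gs = simulate.GatingSpec(n_channels=3, p_open_cis=0.3, p_open_trans=0.3,
                                 noise_sd_pA=1.0, transient_amp_pA=0.0)
        tr = simulate.simulate_single_channel(gs, [], 120.0, 3000.0, dt_ms=0.1, seed=0)
        h = sc.build_histogram(tr, 0.0, 3000.0)
        fit = sc.fit_mixture(h, max_components=4, baseline_guess_pA=0.0)
        assert len(fit.components) >= 2
        assert fit.unitary_amplitude_pA == pytest.approx(
            190.0 * 120.0 * 1e-3, rel=0.05
        )


class TestMixtureFit:
    def test_two_equal_gaussians_recover_half_half(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20000), rng.normal(20, 1, 20000)])
        tr = _trace(x)
        h = sc.build_histogram(tr, 0.0, tr.time_ms[-1])
        fit = sc.fit_mixture(h, max_components=4, baseline_guess_pA=0.0)
        assert len(fit.components) == 2
        assert fit.components[0].area == pytest.approx(0.5, abs=0.02)
        assert fit.components[1].area == pytest.approx(0.5, abs=0.02)

    def test_single_component_data_selects_one_component(self, rng):
        x = rng.normal(0, 1, 30000)
        tr = _trace(x)
        h = sc.build_histogram(tr, 0.0, tr.time_ms[-1])
        fit = sc.fit_mixture(h, max_components=4)
        assert len(fit.components) == 1

    def test_areas_sum_to_one(self, rng):
        x = np.concatenate([rng.normal(0, 1, 9000), rng.normal(19, 1.5, 3000)])
        tr = _trace(x)
        h = sc.build_histogram(tr, 0.0, tr.time_ms[-1])
        fit = sc.fit_mixture(h, max_components=3, baseline_guess_pA=0.0)
        assert sum(c.area for c in fit.components) == pytest.approx(1.0, rel=1e-9)

    def test_occupancy_recovery_against_hidden_state(self):
        gs = simulate.GatingSpec(n_channels=2, p_open_cis=0.25, p_open_trans=0.25,
                                 noise_sd_pA=1.0, transient_amp_pA=0.0)
        tr = simulate.simulate_single_channel(gs, [], 120.0, 5000.0, dt_ms=0.1, seed=1)
        h = sc.build_histogram(tr, 0.0, 5000.0)
        fit = sc.fit_mixture(h, max_components=4, baseline_guess_pA=0.0)
        true_closed = float(np.mean(tr.n_open == 0))
        est_closed = fit.components[fit.baseline_index].area
        assert est_closed == pytest.approx(true_closed, abs=0.03)

    def test_matches_sklearn_gmm_cross_check(self, rng):
        # independent EM-based mixture on the raw samples agrees on means
        from sklearn.mixture import GaussianMixture

        x = np.concatenate([rng.normal(0, 1, 8000), rng.normal(19, 1, 4000)])
        tr = _trace(x)
        h = sc.build_histogram(tr, 0.0, tr.time_ms[-1])
        fit = sc.fit_mixture(h, max_components=2, baseline_guess_pA=0.0)
        gmm = GaussianMixture(2, random_state=0).fit(x[:, None])
        ref = np.sort(gmm.means_.ravel())
        ours = [c.mean_pA for c in fit.components]
        assert ours == pytest.approx(ref, abs=0.15)


class TestActivity:
    def _fit(self, areas, baseline_index=0):
        comps = tuple(
            sc.MixtureComponent(mean_pA=19.0 * k, sd_pA=1.0, area=a)
            for k, a in enumerate(areas)
        )
        return sc.MixtureFit(components=comps, baseline_index=baseline_index,
                             gof=0.0, bic=0.0)

    def test_all_area_in_baseline_gives_zero(self):
        act = sc.channel_activity(self._fit([1.0, 0.0]))
        assert act.activity_area == 0.0
        assert act.activity_any_open == 0.0

    def test_no_baseline_area_gives_one(self):
        act = sc.channel_activity(self._fit([0.0, 0.6, 0.4]))
        assert act.activity_area == 1.0
        assert act.activity_any_open == 1.0

    def test_both_definitions_in_unit_interval_and_coincide(self):
        act = sc.channel_activity(self._fit([0.55, 0.3, 0.15]))
        assert 0.0 <= act.activity_area <= 1.0
        assert act.activity_area == pytest.approx(act.activity_any_open)
        assert act.n_open_states == 2

    def test_monotone_in_true_open_probability(self):
        ests, truths = [], []
        for p in (0.2, 0.5, 0.8):
            gs = simulate.GatingSpec(n_channels=1, p_open_cis=p, p_open_trans=p,
                                     noise_sd_pA=1.0, transient_amp_pA=0.0)
            tr = simulate.simulate_single_channel(gs, [], 120.0, 3000.0,
                                                  dt_ms=0.1, seed=int(p * 10))
            h = sc.build_histogram(tr, 0.0, 3000.0)
            fit = sc.fit_mixture(h, max_components=2, baseline_guess_pA=0.0)
            ests.append(sc.channel_activity(fit).activity_any_open)
            truths.append(float(np.mean(tr.n_open > 0)))
        assert ests == sorted(ests)
        assert np.allclose(ests, truths, atol=0.03)


class TestLagTimes:
    def test_opening_and_closing_lags_recovered_per_event(self):
        gs = simulate.GatingSpec(n_channels=1, p_open_cis=0.0, p_open_trans=1.0,
                                 k_total_per_ms=4.0, noise_sd_pA=1.0)
        events = [LightEvent(100.0, 40.0, BLUE), LightEvent(600.0, 40.0, UV)]
        tr = simulate.simulate_single_channel(gs, events, 100.0, 1000.0, seed=6)
        h = sc.build_histogram(tr, 0.0, 1000.0)
        fit = sc.fit_mixture(h, max_components=2, baseline_guess_pA=0.0)
        res = sc.lag_times(tr, fit)
        # realized per-channel toggle delays from the simulator bookkeeping
        true_open = tr.toggle_times_ms[0, 0] - (100.0 + gs.switch_time_ms)
        true_close = tr.toggle_times_ms[0, 1] - (600.0 + gs.switch_time_ms)
        assert len(res.lags_open_ms) == 1 and len(res.lags_close_ms) == 1
        assert res.lags_open_ms[0] == pytest.approx(max(true_open, 1.5), abs=2.0)
        assert res.lags_close_ms[0] == pytest.approx(max(true_close, 1.5), abs=2.0)

    def test_no_state_change_records_no_lag(self):
        gs = simulate.GatingSpec(n_channels=1, p_open_cis=0.0, p_open_trans=0.0,
                                 noise_sd_pA=1.0)
        tr = simulate.simulate_single_channel(
            gs, [LightEvent(100.0, 40.0, BLUE)], 100.0, 500.0, seed=7
        )
        comps = (sc.MixtureComponent(0.0, 1.0, 0.9),
                 sc.MixtureComponent(19.0, 1.0, 0.1))
        m = sc.MixtureFit(components=comps, baseline_index=0, gof=0.0, bic=0.0)
        res = sc.lag_times(tr, m)
        assert res.lags_open_ms == [] and res.lags_close_ms == []


class TestUnitaryConductance:
    def test_exact_ohmic_line_gives_190_pS(self):
        v = np.array([-100.0, -50.0, 0.0, 50.0, 100.0, 150.0])
        fit = sc.unitary_conductance(v, 0.190 * v)
        assert fit.g_pS == pytest.approx(190.0, rel=1e-12)
        assert fit.v_rev_mV == pytest.approx(0.0, abs=1e-9)

    def test_two_voltages_rejected(self):
        with pytest.raises(ValueError):
            sc.unitary_conductance(np.array([0.0, 100.0]), np.array([0.0, 19.0]))

    def test_noisy_slope_within_two_se(self, rng):
        v = np.linspace(-60.0, 120.0, 7)
        i = 0.190 * (v - 5.0)
        i_noisy = i + rng.normal(0.0, 0.03 * np.abs(i).mean(), v.size)
        fit = sc.unitary_conductance(v, i_noisy)
        assert abs(fit.g_pS - 190.0) < 2 * fit.se_g_pS
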