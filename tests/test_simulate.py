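"""Synthetic-data generators: determinism, level structure, kinetics."""

import numpy as np
import pytest

from photokv import simulate
from photokv.ensemble import BoltzmannParams, boltzmann_current
from photokv.tension import TensionParams
from photokv.traces import BLUE, UV, InvalidProtocolError, LightEvent


def _blue(t=100.0):
    return LightEvent(t, 40.0, BLUE)


class TestSingleChannel:
    def test_identical_seed_identical_trace(self):
        gs = simulate.GatingSpec()
        a = simulate.simulate_single_channel(gs, [_blue()], 120.0, 500.0, seed=7)
        b = simulate.simulate_single_channel(gs, [_blue()], 120.0, 500.0, seed=7)
        assert np.array_equal(a.i_pA, b.i_pA)
        c = simulate.simulate_single_channel(gs, [_blue()], 120.0, 500.0, seed=8)
        assert not np.array_equal(a.i_pA, c.i_pA)

    def test_silent_channels_give_flat_trace_apart_from_transients(self):
        gs = simulate.GatingSpec(p_open_cis=0.0, p_open_trans=0.0, noise_sd_pA=0.0)
        tr = simulate.simulate_single_channel(gs, [_blue()], 120.0, 500.0, seed=1)
        # exclude the biexponential transient tail (decay 1 ms; negligible 30 ms on)
        outside = (tr.time_ms < 100.0) | (tr.time_ms > 130.0)
        assert np.allclose(tr.i_pA[outside], 0.0)
        inside = (tr.time_ms >= 100.0) & (tr.time_ms < 105.0)
        assert np.max(np.abs(tr.i_pA[inside])) > 0  # the optocapacitive spike

    def test_unitary_amplitude_is_ohmic(self):
        # 190 pS at a 100 mV driving force -> 19 pA open-level amplitude
        gs = simulate.GatingSpec(
            n_channels=1, g_unitary_pS=190.0, p_open_cis=0.5, p_open_trans=0.5,
            noise_sd_pA=0.0, transient_amp_pA=0.0,
        )
        tr = simulate.simulate_single_channel(gs, [], 100.0, 500.0, seed=2)
        levels = np.unique(tr.i_pA)
        assert set(np.round(levels, 9)) <= {0.0, 19.0}

    def test_noiseless_multichannel_levels_are_unitary_multiples(self):
        gs = simulate.GatingSpec(
            n_channels=4, p_open_cis=0.4, p_open_trans=0.4,
            noise_sd_pA=0.0, transient_amp_pA=0.0,
        )
        tr = simulate.simulate_single_channel(gs, [], 100.0, 300.0, seed=3)
        unit = 190.0 * 100.0 * 1e-3
        assert np.allclose(tr.i_pA / unit, np.round(tr.i_pA / unit), atol=1e-12)

    def test_stationary_open_fraction_matches_spec(self):
        gs = simulate.GatingSpec(
            n_channels=1, p_open_cis=0.3, p_open_trans=0.3, k_total_per_ms=1.0,
            noise_sd_pA=0.0, transient_amp_pA=0.0,
        )
        tr = simulate.simulate_single_channel(
            gs, [], 100.0, 20_000.0, dt_ms=0.2, seed=4
        )
        assert tr.n_open.mean() == pytest.approx(0.30, abs=0.02)

    def test_overlapping_events_rejected(self):
        gs = simulate.GatingSpec()
        bad = [LightEvent(100.0, 40.0, BLUE), LightEvent(120.0, 40.0, UV)]
        with pytest.raises(InvalidProtocolError):
            simulate.simulate_single_channel(gs, bad, 120.0, 500.0, seed=0)

    def test_regime_toggles_recorded_per_channel_and_event(self):
        gs = simulate.GatingSpec(n_channels=3)
        events = [_blue(), LightEvent(400.0, 40.0, UV)]
        tr = simulate.simulate_single_channel(gs, events, 120.0, 800.0, seed=5)
        assert tr.toggle_times_ms.shape == (3, 2)
        assert np.all(tr.toggle_times_ms[:, 0] >= 100.0 + gs.switch_time_ms)


class TestEnsembleSweeps:
    def test_noiseless_steady_current_matches_boltzmann(self):
        bp = BoltzmannParams(0.0, 2.0, 120.9, 15.0)
        es = simulate.EnsembleSpec(boltz_cis=bp, boltz_trans=bp, sweep_noise_sd_pA=0.0)
        sw = simulate.simulate_ensemble_sweeps(es, [80.0, 120.9, 160.0], "trans",
                                               seed=0, step_ms=300.0)
        for s in sw.sweeps:
            expected = boltzmann_current(s.v_step_mV, 0.0, 2.0, 120.9, 15.0)
            assert s.i_pA[-1] == pytest.approx(expected, rel=1e-9)

    def test_midpoint_current_is_half_envelope(self):
        bp = BoltzmannParams(0.0, 2.0, 120.9, 15.0)
        assert boltzmann_current(120.9, 0.0, 2.0, 120.9, 15.0) == pytest.approx(
            (120.9 - 0.0) * 2.0 / 2
        )

    def test_empty_protocol_rejected(self):
        bp = BoltzmannParams(0.0, 2.0, 120.9, 15.0)
        es = simulate.EnsembleSpec(boltz_cis=bp, boltz_trans=bp)
        with pytest.raises(ValueError):
            simulate.simulate_ensemble_sweeps(es, [], "trans", seed=0)


class TestCmTrace:
    def test_minimum_to_baseline_ratio(self):
        cs = simulate.CmSpec(dc_frac=-0.06, noise_sd_pF=0.0)
        # dt chosen so a sample lands exactly on the switch-completion time
        tr = simulate.simulate_cm_trace(cs, _blue(), 500.0, dt_ms=0.05, seed=0)
        assert tr.cm_pF.min() / tr.cm_pF[0] == pytest.approx(0.94, abs=1e-6)

    def test_half_recovery_at_log2_tau_after_minimum(self):
        cs = simulate.CmSpec(dc_frac=-0.06, tau_relax_ms=23.0, noise_sd_pF=0.0,
                             recovery_frac=1.0)
        tr = simulate.simulate_cm_trace(cs, _blue(), 500.0, dt_ms=0.01, seed=0)
        i_min = int(np.argmin(tr.cm_pF))
        t_min = tr.time_ms[i_min]
        half_depth = tr.cm_pF[0] - 0.5 * (tr.cm_pF[0] - tr.cm_pF[i_min])
        i_half = i_min + int(np.argmax(tr.cm_pF[i_min:] >= half_depth))
        assert tr.time_ms[i_half] - t_min == pytest.approx(23.0 * np.log(2), abs=0.05)

    def test_duration_must_cover_relaxation(self):
        cs = simulate.CmSpec()
        with pytest.raises(ValueError):
            simulate.simulate_cm_trace(cs, _blue(), 150.0, seed=0)


class TestProfileStack:
    def test_deterministic_per_seed(self):
        ps = simulate.ProfileSpec()
        a = simulate.simulate_profile_stack(ps, seed=11)
        b = simulate.simulate_profile_stack(ps, seed=11)
        assert np.array_equal(a.frames, b.frames)

    def test_static_radius_frames_identical_up_to_noise(self):
        ps = simulate.ProfileSpec(
            tension=TensionParams(29.5, 29.5, 4.0, 500.0, 23.0), noise_sd=0.0
        )
        stack = simulate.simulate_profile_stack(ps, seed=0)
        assert np.allclose(stack.frames, stack.frames[0])

    def test_profile_span_validated(self):
        with pytest.raises(ValueError):
            simulate.ProfileSpec(n_pixels=64, pixel_um=0.35)

    def test_generators_produce_finite_output(self):
        ps = simulate.ProfileSpec()
        stack = simulate.simulate_profile_stack(ps, seed=1)
        assert np.all(np.isfinite(stack.frames))
        gs = simulate.GatingSpec()
        tr = simulate.simulate_single_channel(gs, [_blue()], 120.0, 300.0, seed=1)
        assert np.all(np.isfinite(tr.i_pA))
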