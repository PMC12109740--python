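"""Stage implementations behind :func:`photokv.io.run_pipeline`.

Each stage reads its section of the config dict, simulates (or loads) its
input, runs the corresponding analysis, writes delimited-text artifacts to
the output directory, and returns (report, paths).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import capacitance, ensemble, profiles, simulate, single_channel, tension
from .io import write_events, write_trace
from .traces import BLUE, UV, LightEvent


def _tension_params(cfg: dict) -> tension.TensionParams:
    t = cfg.get("tension", {})
    return tension.TensionParams(
        r0_um=t.get("r0_um", 29.5),
        rin_um=t.get("rin_um", 27.5),
        sigma0_mN_per_m=t.get("sigma0_mN_per_m", 4.0),
        eta_h_nNs_per_m=t.get("eta_h_nNs_per_m", 500.0),
        tau_ms=t.get("tau_ms", 23.0),
    )


def stage_tension(cfg: dict, out: Path, seed: int):
    p = _tension_params(cfg)
    alpha = tension.alpha_from_geometry(p)
    tc = tension.tension_time_course(p)
    t = np.linspace(0.0, p.tau_ms, 101)
    df = pd.DataFrame({
        "t_ms": t,
        "r_um": tension.radius_closed_form(p, t),
        "sigma_mN_per_m": tension.sigma_at(p, t),
    })
    path = out / "tension_trajectory.csv"
    df.to_csv(path, index=False, float_format="%.8g")
    report = {
        "alpha": alpha,
        "alpha_percent": 100.0 * alpha,
        "sigma0_mN_per_m": p.sigma0_mN_per_m,
        "sigma_at_0_mN_per_m": tc.B_coef_mN_per_m,
    }
    return report, {"trajectory": path}


def stage_cm(cfg: dict, out: Path, seed: int):
    c = cfg.get("cm", {})
    spec = simulate.CmSpec(
        c_base_pF=c.get("c_base_pF", 80.0),
        dc_frac=c.get("dc_frac", -0.06),
        tau_relax_ms=c.get("tau_relax_ms", 23.0),
        noise_sd_pF=c.get("noise_sd_pF", 0.05),
    )
    event = LightEvent(c.get("t_on_ms", 100.0), c.get("pulse_ms", 40.0), BLUE)
    trace = simulate.simulate_cm_trace(
        spec, event, duration_ms=c.get("duration_ms", 500.0), seed=seed
    )
    path = out / "cm_trace.csv"
    write_trace(trace, path)
    ext = capacitance.detect_switch_extremum(trace, event)
    fit = capacitance.fit_cm_relaxation(
        trace, start_ms=ext.t_ms, window_ms=10.0 * spec.tau_relax_ms
    )
    report = {
        "extremum_t_ms": ext.t_ms,
        "rel_change": ext.rel_change,
        "tau_relax_ms": fit.tau_relax_ms,
        "se_tau_ms": fit.se_tau_ms,
        "c_plateau_pF": fit.c_plateau_pF,
    }
    return report, {"trace": path}


def stage_profiles(cfg: dict, out: Path, seed: int):
    pr = cfg.get("profiles", {})
    spec = simulate.ProfileSpec(
        tension=_tension_params(cfg),
        frame_ms=pr.get("frame_ms", 40.0),
        noise_sd=pr.get("noise_sd", 0.02),
        n_frames=pr.get("n_frames", 8),
        switch_frame=pr.get("switch_frame", 3),
    )
    stack = simulate.simulate_profile_stack(spec, seed=seed)
    path = out / "profile_stack.tsv"
    write_trace(stack, path)
    bound = profiles.bound_from_stack(stack, ref_frame=spec.switch_frame)
    report = {
        "tau_upper_bound_ms": bound.bound_ms,
        "deflection_free_lag_frames": bound.lag_frames,
        "per_lag_deflection": {str(k): v for k, v in bound.per_lag_deflection.items()},
    }
    return report, {"stack": path}


def stage_single_channel(cfg: dict, out: Path, seed: int):
    sc = cfg.get("single_channel", {})
    spec = simulate.GatingSpec(
        n_channels=sc.get("n_channels", 3),
        p_open_cis=sc.get("p_open_cis", 0.05),
        p_open_trans=sc.get("p_open_trans", 0.30),
        noise_sd_pA=sc.get("noise_sd_pA", 1.0),
    )
    duration = sc.get("duration_ms", 3000.0)
    events = [
        LightEvent(duration * 0.25, 40.0, BLUE),
        LightEvent(duration * 0.75, 40.0, UV),
    ]
    trace = simulate.simulate_single_channel(
        spec, events, voltage_mV=sc.get("voltage_mV", 120.0),
        duration_ms=duration, seed=seed,
    )
    path = out / "single_channel_trace.csv"
    write_trace(trace, path)
    ev_path = out / "single_channel_events.json"
    write_events(events, ev_path)
    hist = single_channel.build_histogram(trace, events[0].t_off_ms, events[1].t_on_ms)
    fit = single_channel.fit_mixture(hist, max_components=spec.n_channels + 1,
                                     baseline_guess_pA=0.0)
    act = single_channel.channel_activity(fit)
    lags = single_channel.lag_times(trace, fit)
    report = {
        "activity_area": act.activity_area,
        "activity_any_open": act.activity_any_open,
        "n_open_states": act.n_open_states,
        "components": [
            {"mean_pA": c.mean_pA, "sd_pA": c.sd_pA, "area": c.area}
            for c in fit.components
        ],
        "lags_open_ms": lags.lags_open_ms,
        "lags_close_ms": lags.lags_close_ms,
    }
    return report, {"trace": path, "events": ev_path}


def stage_iv(cfg: dict, out: Path, seed: int):
    iv = cfg.get("iv", {})
    spec = simulate.EnsembleSpec(
        boltz_cis=ensemble.BoltzmannParams(
            v_rev_mV=0.0, g_max_nS=iv.get("g_max_nS", 2.0),
            v_half_mV=iv.get("v_half_cis_mV", 158.6), v_s_mV=iv.get("v_s_mV", 15.0),
        ),
        boltz_trans=ensemble.BoltzmannParams(
            v_rev_mV=0.0, g_max_nS=iv.get("g_max_nS", 2.0),
            v_half_mV=iv.get("v_half_trans_mV", 120.9), v_s_mV=iv.get("v_s_mV", 15.0),
        ),
        sweep_noise_sd_pA=iv.get("noise_sd_pA", 5.0),
    )
    protocol = list(np.arange(-40.0, 161.0, 20.0))
    fits, tables = {}, {}
    for k, state in enumerate(("cis", "trans")):
        sweeps = simulate.simulate_ensemble_sweeps(
            spec, protocol, state=state, seed=seed + k,
            n_replicates=iv.get("n_replicates", 5),
        )
        # the cis/trans comparison uses currents after tension has relaxed,
        # so steady-state extraction is the appropriate default here
        table = ensemble.extract_currents(sweeps, mode=iv.get("mode", "steady"))
        path = out / f"iv_{state}.csv"
        table.to_csv(path, index=False, float_format="%.8g")
        tables[state] = path
        fits[state] = ensemble.fit_boltzmann(table)
    cmp_res = ensemble.compare_photostates(fits["cis"], fits["trans"],
                                           v_test_mV=iv.get("v_test_mV", 120.0))
    report = {
        state: {
            "v_half_mV": f.v_half_mV, "se_v_half": f.se_v_half,
            "v_s_mV": f.v_s_mV, "g_max_nS": f.g_max_nS, "v_rev_mV": f.v_rev_mV,
        }
        for state, f in fits.items()
    }
    report["delta_v_half_mV"] = cmp_res.delta_v_half_mV
    report["se_delta_v_half"] = cmp_res.se_delta_v_half
    report["rel_conductance_change"] = cmp_res.rel_conductance_change
    return report, tables
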