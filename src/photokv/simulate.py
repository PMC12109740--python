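"""Seeded generators for every record type the analysis pipeline consumes.

These emulate the study conditions of a photoswitchable planar lipid
bilayer (PLB) doped with an azobenzene photolipid and carrying reconstituted
KvAP channels:

* multi-channel stochastic gating traces whose open probability switches
  between the thin (cis) and thick (trans) bilayer states after UV/blue
  light pulses, with per-channel response lags and optocapacitive transient
  spikes at pulse onsets;
* ensemble voltage-step sweep families drawn around a Boltzmann I/V curve
  per photostate;
* membrane-capacitance records that step at the photoisomerization and then
  relax monoexponentially;
* equatorial line-profile stacks in which the torus edges move along the
  closed-form radius trajectory of the tension-relaxation model, with
  camera frames modelled as exposure averages.

Identical spec + seed gives bit-identical output; different seeds differ
only in the noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .ensemble import BoltzmannParams, Sweep, SweepSet, boltzmann_current
from .tension import TensionParams, radius_closed_form
from .traces import (
    BLUE,
    UV,
    CapacitanceTrace,
    CurrentTrace,
    LightEvent,
    LineProfileStack,
    validate_events,
)

__all__ = [
    "GatingSpec",
    "EnsembleSpec",
    "CmSpec",
    "ProfileSpec",
    "simulate_single_channel",
    "simulate_ensemble_sweeps",
    "simulate_cm_trace",
    "simulate_profile_stack",
    "simulate_profile_lines",
]


@dataclass(frozen=True)
class GatingSpec:
    """Parameters of the two-state (closed/open) multi-channel gating model.

    Each channel is an independent Markov chain whose stationary open
    probability depends on the current bilayer photostate; ``k_total`` is
    the sum of opening and closing rates and sets the dwell-time scale.
    The bilayer reaches its photostationary state ``switch_time_ms`` after
    pulse onset; each channel's kinetic regime follows after an additional
    exponentially distributed lag whose mean depends on direction
    (the observed openings after blue lag ~10 ms, closings after UV ~40 ms).
    """

    n_channels: int = 1
    g_unitary_pS: float = 190.0
    v_rev_mV: float = 0.0
    p_open_cis: float = 0.05
    p_open_trans: float = 0.30
    k_total_per_ms: float = 1.0
    switch_time_ms: float = 1.5
    switch_delay_blue_ms: float = 10.0
    switch_delay_uv_ms: float = 40.0
    noise_sd_pA: float = 1.0
    transient_amp_pA: float = 50.0
    transient_rise_ms: float = 0.1
    transient_decay_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.g_unitary_pS <= 0:
            raise ValueError("unitary conductance must be positive")
        for p in (self.p_open_cis, self.p_open_trans):
            if not 0.0 <= p <= 1.0:
                raise ValueError("open probabilities must lie in [0, 1]")
        if self.k_total_per_ms <= 0:
            raise ValueError("k_total must be positive")

    def p_open(self, state: str) -> float:
        return self.p_open_cis if state == "cis" else self.p_open_trans


def _transient(t_ms: np.ndarray, ev: LightEvent, gs: GatingSpec) -> np.ndarray:
    """Optocapacitive spike at pulse onset: biexponential, sign by kind.

    UV raises membrane capacitance (thinner bilayer) -> positive transient;
    blue lowers it -> negative.  Only presence and sign matter downstream.
    """
    dt = t_ms - ev.t_on_ms
    shape = np.where(
        dt >= 0,
        np.exp(-np.maximum(dt, 0) / gs.transient_decay_ms)
        - np.exp(-np.maximum(dt, 0) / gs.transient_rise_ms),
        0.0,
    )
    sign = 1.0 if ev.kind == UV else -1.0
    return sign * gs.transient_amp_pA * shape


def simulate_single_channel(
    gs: GatingSpec,
    events: list[LightEvent],
    voltage_mV: float,
    duration_ms: float,
    dt_ms: float = 0.04,
    seed: int | None = 0,
    initial_state: str = "cis",
) -> CurrentTrace:
    """Simulate a voltage-clamp current trace with light-switched gating.

    Fixed-step Markov updates use exact per-step transition probabilities
    1 - exp(-k*dt).  The hidden open-channel count per sample is attached as
    ``trace.n_open`` for oracle use in tests.
    """
    if dt_ms > 0.2:
        raise ValueError("dt must be <= 0.2 ms to resolve gating kinetics")
    validate_events(events)
    if events and events[-1].t_off_ms > duration_ms:
        raise ValueError("duration must cover all light events")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms / dt_ms))
    t = np.arange(n) * dt_ms

    # per-channel regime schedule: list of (effective switch time, new state)
    n_ch = gs.n_channels
    regime = np.empty((n_ch, n), dtype=np.uint8)  # 0 = cis, 1 = trans
    toggles = np.empty((n_ch, len(events)))
    state0 = 0 if initial_state == "cis" else 1
    for c in range(n_ch):
        row = np.full(n, state0, dtype=np.uint8)
        for j, ev in enumerate(events):
            mean = gs.switch_delay_blue_ms if ev.kind == BLUE else gs.switch_delay_uv_ms
            lag = rng.exponential(mean) if mean > 0 else 0.0
            t_eff = ev.t_on_ms + gs.switch_time_ms + lag
            toggles[c, j] = t_eff
            new = 1 if ev.kind == BLUE else 0
            idx = int(np.searchsorted(t, t_eff))
            row[idx:] = new
        regime[c] = row

    # per-step stay/flip probabilities for both regimes
    p_open_by_state = np.array([gs.p_open_cis, gs.p_open_trans])
    k_open = p_open_by_state * gs.k_total_per_ms
    k_close = (1.0 - p_open_by_state) * gs.k_total_per_ms
    p_co = 1.0 - np.exp(-k_open * dt_ms)   # closed -> open
    p_oc = 1.0 - np.exp(-k_close * dt_ms)  # open -> closed

    n_open = np.zeros(n, dtype=np.int32)
    for c in range(n_ch):
        u = rng.random(n)
        reg = regime[c]
        st = 1 if u[0] < p_open_by_state[reg[0]] else 0  # stationary start
        states = np.empty(n, dtype=np.int8)
        states[0] = st
        pco, poc = p_co, p_oc
        for i in range(1, n):
            r = reg[i]
            if st == 0:
                if u[i] < pco[r]:
                    st = 1
            else:
                if u[i] < poc[r]:
                    st = 0
            states[i] = st
        n_open += states

    i_gate = n_open * gs.g_unitary_pS * (voltage_mV - gs.v_rev_mV) * 1e-3  # pA
    i_pA = i_gate + (rng.normal(0.0, gs.noise_sd_pA, n) if gs.noise_sd_pA > 0 else 0.0)
    for ev in events:
        i_pA = i_pA + _transient(t, ev, gs)
    return CurrentTrace(
        time_ms=t,
        i_pA=i_pA,
        v_mV=np.full(n, voltage_mV),
        events=list(events),
        sampling_rate_khz=1.0 / dt_ms,
        n_open=n_open,
        toggle_times_ms=toggles,
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Generator settings for ensemble voltage-step families."""

    boltz_cis: BoltzmannParams
    boltz_trans: BoltzmannParams
    tau_act_ms: float = 10.0
    sweep_noise_sd_pA: float = 5.0

    def __post_init__(self) -> None:
        if self.tau_act_ms <= 0:
            raise ValueError("activation time constant must be positive")


def simulate_ensemble_sweeps(
    es: EnsembleSpec,
    protocol_mV: list[float],
    state: str = "trans",
    seed: int | None = 0,
    n_replicates: int = 1,
    pre_ms: float = 20.0,
    step_ms: float = 200.0,
    dt_ms: float = 0.5,
) -> SweepSet:
    """Voltage-step sweep family drawn around the photostate's Boltzmann curve.

    Per step voltage the steady current follows the Boltzmann I/V relation;
    activation onsets monoexponentially with ``tau_act_ms``; Gaussian noise
    of ``sweep_noise_sd_pA`` is added per sample.
    """
    if not protocol_mV:
        raise ValueError("protocol must list at least one step voltage")
    if state not in ("cis", "trans"):
        raise ValueError("state must be 'cis' or 'trans'")
    bp = es.boltz_cis if state == "cis" else es.boltz_trans
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, pre_ms + step_ms, dt_ms)
    in_step = t >= pre_ms
    sweeps = []
    for _rep in range(n_replicates):
        for v in protocol_mV:
            i_ss = float(boltzmann_current(v, bp.v_rev_mV, bp.g_max_nS,
                                           bp.v_half_mV, bp.v_s_mV))
            i = np.zeros_like(t)
            i[in_step] = i_ss * (1.0 - np.exp(-(t[in_step] - pre_ms) / es.tau_act_ms))
            if es.sweep_noise_sd_pA > 0:
                i = i + rng.normal(0.0, es.sweep_noise_sd_pA, t.size)
            sweeps.append(Sweep(
                v_step_mV=float(v), time_ms=t.copy(), i_pA=i,
                step_start_ms=pre_ms, step_end_ms=pre_ms + step_ms,
            ))
    return SweepSet(sweeps=sweeps, holding_mV=-100.0, inter_sweep_delay_s=5.0)


def simulate_iv_table(
    bp: BoltzmannParams,
    voltages_mV: list[float],
    noise_sd_pA: float,
    n_replicates: int = 5,
    seed: int | None = 0,
):
    """Replicate-averaged I/V table drawn around a Boltzmann curve.

    Per voltage, ``n_replicates`` currents are drawn N(I(V), noise_sd) and
    reduced to mean, sample variance and count — the same columns
    :func:`photokv.ensemble.extract_currents` produces from sweep families.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for v in voltages_mV:
        i_true = float(boltzmann_current(v, bp.v_rev_mV, bp.g_max_nS,
                                         bp.v_half_mV, bp.v_s_mV))
        draws = i_true + (rng.normal(0.0, noise_sd_pA, n_replicates)
                          if noise_sd_pA > 0 else np.zeros(n_replicates))
        rows.append((float(v), float(draws.mean()),
                     float(draws.var(ddof=1)) if n_replicates > 1 else 0.0,
                     n_replicates))
    return pd.DataFrame(rows, columns=["v_mV", "i_pA", "var_pA2", "n"])


@dataclass(frozen=True)
class CmSpec:
    """Generator settings for a light-switched capacitance record.

    The capacitance ramps by ``dc_frac`` over ``switch_time_ms`` at pulse
    onset (the photostationary state is reached within 1-2 ms) and then
    relaxes monoexponentially toward a plateau that recovers a fraction
    ``recovery_frac`` of the step, emulating the torus retraction.
    """

    c_base_pF: float = 80.0
    dc_frac: float = -0.06
    tau_relax_ms: float = 23.0
    switch_time_ms: float = 1.5
    recovery_frac: float = 0.6
    noise_sd_pF: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < abs(self.dc_frac) < 1.0:
            raise ValueError("dc_frac must satisfy 0 < |dc_frac| < 1")
        if self.tau_relax_ms <= 0:
            raise ValueError("tau_relax must be positive")
        if not 0.0 <= self.recovery_frac <= 1.0:
            raise ValueError("recovery_frac must lie in [0, 1]")


def simulate_cm_trace(
    cs: CmSpec,
    event: LightEvent,
    duration_ms: float,
    dt_ms: float = 0.2,
    seed: int | None = 0,
) -> CapacitanceTrace:
    """Capacitance step-and-relax record around one light pulse."""
    if duration_ms <= event.t_off_ms + 5.0 * cs.tau_relax_ms:
        raise ValueError("duration must extend >= 5 relaxation constants past the pulse")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, dt_ms)
    c_min = cs.c_base_pF * (1.0 + cs.dc_frac)
    step = cs.c_base_pF * cs.dc_frac
    plateau = cs.c_base_pF + step * (1.0 - cs.recovery_frac)
    t_sw = event.t_on_ms + cs.switch_time_ms

    cm = np.full(t.shape, cs.c_base_pF)
    ramp = (t >= event.t_on_ms) & (t < t_sw)
    cm[ramp] = cs.c_base_pF + step * (t[ramp] - event.t_on_ms) / cs.switch_time_ms
    after = t >= t_sw
    cm[after] = plateau + (c_min - plateau) * np.exp(-(t[after] - t_sw) / cs.tau_relax_ms)
    if cs.noise_sd_pF > 0:
        cm = cm + rng.normal(0.0, cs.noise_sd_pF, t.size)
    return CapacitanceTrace(time_ms=t, cm_pF=cm, events=[event])


@dataclass(frozen=True)
class ProfileSpec:
    """Generator settings for equatorial torus line-profile stacks.

    Frames are exposure averages: within each frame interval the rim radius
    is sub-sampled along the closed-form relaxation trajectory and the
    resulting edge profiles averaged, emulating camera motion blur.  The
    light switch occurs at the start of frame ``switch_frame + 1`` (frame
    ``switch_frame`` is the last fully pre-switch frame).
    """

    tension: TensionParams = field(
        default_factory=lambda: TensionParams(29.5, 27.5, 4.0, 500.0, 23.0)
    )
    n_pixels: int = 256
    pixel_um: float = 0.35
    frame_ms: float = 40.0
    n_frames: int = 8
    switch_frame: int = 3
    edge_sigma_px: float = 2.0
    noise_sd: float = 0.02
    n_lines: int = 11
    exposure_ms: float | None = None  # None -> full frame interval
    n_subsamples: int = 32

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame interval must be positive")
        if not 0 <= self.switch_frame < self.n_frames - 1:
            raise ValueError("switch_frame must leave at least one post-switch frame")
        span_um = self.n_pixels * self.pixel_um
        if span_um < 2.2 * self.tension.r0_um:
            raise ValueError(
                f"profile spans {span_um:.1f} um but must cover twice the torus "
                f"radius ({2 * self.tension.r0_um:.1f} um) with margin"
            )


def _edge_profile(x_um: np.ndarray, r_um: float, center_um: float,
                  sigma_um: float) -> np.ndarray:
    """Smoothed bright top-hat of half-width r: half-max exactly at +-r."""
    s = sigma_um * np.sqrt(2.0)
    left = erf((x_um - (center_um - r_um)) / s)
    right = erf((x_um - (center_um + r_um)) / s)
    return 0.5 * (left - right)


def _radius_at(ps: ProfileSpec, t_ms: float) -> float:
    """Rim radius at absolute time t: r0 before the switch and after full
    relaxation, the closed-form trajectory in between."""
    p = ps.tension
    t_switch = (ps.switch_frame + 1) * ps.frame_ms
    dt = t_ms - t_switch
    if dt < 0 or dt > p.tau_ms:
        return p.r0_um
    return float(radius_closed_form(p, dt))


def simulate_profile_lines(ps: ProfileSpec, seed: int | None = 0) -> np.ndarray:
    """Raw camera lines, shape (n_frames, n_lines, n_pixels).

    Every line of a frame shares the frame's exposure-averaged geometry and
    carries an independent noise realization, so averaging the lines reduces
    the noise sd by ~sqrt(n_lines).
    """
    rng = np.random.default_rng(seed)
    x_um = np.arange(ps.n_pixels) * ps.pixel_um
    center = x_um[-1] / 2.0
    sigma_um = ps.edge_sigma_px * ps.pixel_um
    exposure = ps.frame_ms if ps.exposure_ms is None else ps.exposure_ms
    lines = np.empty((ps.n_frames, ps.n_lines, ps.n_pixels))
    for k in range(ps.n_frames):
        t0 = k * ps.frame_ms
        sub = t0 + (np.arange(ps.n_subsamples) + 0.5) / ps.n_subsamples * exposure
        prof = np.mean(
            [_edge_profile(x_um, _radius_at(ps, ts), center, sigma_um) for ts in sub],
            axis=0,
        )
        noise = rng.normal(0.0, ps.noise_sd, (ps.n_lines, ps.n_pixels)) \
            if ps.noise_sd > 0 else 0.0
        lines[k] = prof[None, :] + noise
    return lines


def simulate_profile_stack(ps: ProfileSpec, seed: int | None = 0) -> LineProfileStack:
    """Averaged line-profile stack (mean over the frame's raw lines)."""
    lines = simulate_profile_lines(ps, seed=seed)
    return LineProfileStack(
        frames=lines.mean(axis=1),
        pixel_um=ps.pixel_um,
        frame_ms=ps.frame_ms,
        n_lines_averaged=ps.n_lines,
    )
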