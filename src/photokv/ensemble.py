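"""Ensemble current extraction and Boltzmann conductance-voltage fitting.

Macroscopic K+ currents from voltage-step families are reduced to an I/V
table (peak or steady-state current per test potential) and fitted with the
Boltzmann relation

    I(V) = (V - Vrev) * Gmax / (1 + exp((V - V1/2) / Vs))

whose parameters are the reversal potential Vrev (mV), maximum conductance
Gmax (nS), half-maximal activation voltage V1/2 (mV) and slope factor Vs
(mV).  Fits are weighted by the inverse of the per-voltage replicate
variance, and standard errors come from the covariance at the optimum.
A leftward V1/2 shift between photostates quantifies light-induced gating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BoltzmannParams",
    "Sweep",
    "SweepSet",
    "boltzmann_current",
    "extract_currents",
    "fit_boltzmann",
    "compare_photostates",
]


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries residual diagnostics."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class BoltzmannParams:
    """Fitted (or generator) Boltzmann parameters with standard errors."""

    v_rev_mV: float
    g_max_nS: float
    v_half_mV: float
    v_s_mV: float
    se_v_rev: float = float("nan")
    se_g_max: float = float("nan")
    se_v_half: float = float("nan")
    se_v_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.v_s_mV <= 0:
            raise ValueError("slope factor v_s must be positive")
        if self.g_max_nS < 0:
            raise ValueError("g_max must be non-negative")

    def current(self, v_mV):
        return boltzmann_current(
            v_mV, self.v_rev_mV, self.g_max_nS, self.v_half_mV, self.v_s_mV
        )

    def conductance(self, v_mV):
        """Chord conductance G(V) = Gmax / (1 + exp((V - V1/2)/Vs)), nS."""
        v = np.asarray(v_mV, dtype=float)
        return self.g_max_nS / (1.0 + np.exp((self.v_half_mV - v) / self.v_s_mV))


def boltzmann_current(v_mV, v_rev, g_max, v_half, v_s):
    """Boltzmann I/V: (V - Vrev)*Gmax / (1 + exp((V1/2 - V)/Vs)), pA.

    Written with (V1/2 - V) in the exponent so that conductance rises with
    depolarization; nS x mV gives pA directly.
    """
    v = np.asarray(v_mV, dtype=float)
    return (v - v_rev) * g_max / (1.0 + np.exp(np.clip((v_half - v) / v_s, -500, 500)))


@dataclass
class Sweep:
    """One voltage-step sweep: a current segment around a command step."""

    v_step_mV: float
    time_ms: np.ndarray
    i_pA: np.ndarray
    step_start_ms: float
    step_end_ms: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)


@dataclass
class SweepSet:
    """Voltage-step family, possibly with replicates per voltage."""

    sweeps: list[Sweep] = field(default_factory=list)
    holding_mV: float = -100.0
    inter_sweep_delay_s: float = 5.0


def extract_currents(
    s: SweepSet, mode: str = "peak", window_ms: float = 20.0,
    peak_smooth_ms: float = 5.0,
) -> pd.DataFrame:
    """Reduce a sweep family to an I/V table.

    Per sweep, the pre-step epoch median is subtracted as baseline; the step
    current is either the extreme value over the step ("peak", the default)
    or the mean over the trailing ``window_ms`` of the step ("steady").
    Peak picking operates on a boxcar-smoothed segment (``peak_smooth_ms``)
    so the extreme value reports the macroscopic current, not the largest
    noise excursion.  Replicates at the same voltage are averaged and their
    variance retained for inverse-variance fit weighting.

    Returns a DataFrame with columns ``v_mV, i_pA, var_pA2, n`` sorted by
    voltage.
    """
    if mode not in ("peak", "steady"):
        raise ValueError(f"mode must be 'peak' or 'steady', got {mode!r}")
    per_sweep: list[tuple[float, float]] = []
    for sw in s.sweeps:
        pre = sw.i_pA[sw.time_ms < sw.step_start_ms]
        baseline = float(np.median(pre)) if pre.size else 0.0
        in_step = (sw.time_ms >= sw.step_start_ms) & (sw.time_ms <= sw.step_end_ms)
        if not np.any(in_step):
            raise ValueError(
                f"sweep at {sw.v_step_mV} mV has no samples inside its step epoch"
            )
        seg = sw.i_pA[in_step] - baseline
        if mode == "peak":
            dt = float(np.median(np.diff(sw.time_ms))) if len(sw.time_ms) > 1 else 1.0
            w = max(int(round(peak_smooth_ms / dt)), 1)
            if w > 1 and len(seg) >= w:
                seg = np.convolve(seg, np.ones(w) / w, mode="valid")
            val = float(seg[np.argmax(np.abs(seg))])
        else:
            t_seg = sw.time_ms[in_step]
            if window_ms > sw.step_end_ms - sw.step_start_ms:
                raise ValueError("steady window exceeds the step epoch")
            tail = seg[t_seg >= sw.step_end_ms - window_ms]
            val = float(np.mean(tail))
        per_sweep.append((sw.v_step_mV, val))
    df = pd.DataFrame(per_sweep, columns=["v_mV", "i_pA"])
    g = df.groupby("v_mV")["i_pA"]
    out = pd.DataFrame(
        {
            "v_mV": g.mean().index,
            "i_pA": g.mean().to_numpy(),
            "var_pA2": g.var(ddof=1).fillna(0.0).to_numpy(),
            "n": g.count().to_numpy(),
        }
    ).sort_values("v_mV", ignore_index=True)
    return out


def _start_values(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float, float]:
    # Vrev from the low-voltage quasi-linear region; Gmax from the steepest
    # chord; V1/2 at half-maximal chord conductance; Vs = 15 mV generic.
    order = np.argsort(v)
    v, i = v[order], i[order]
    v_rev0 = float(v[np.argmin(np.abs(i))])
    with np.errstate(divide="ignore", invalid="ignore"):
        chord = np.where(np.abs(v - v_rev0) > 1e-9, i / (v - v_rev0), np.nan)
    g_max0 = float(np.nanmax(np.abs(chord)))
    if not math.isfinite(g_max0) or g_max0 <= 0:
        g_max0 = max(np.max(np.abs(i)) / max(np.ptp(v), 1.0), 1e-6)
    half = g_max0 / 2.0
    above = np.where(np.nan_to_num(chord) >= half)[0]
    v_half0 = float(v[above[0]]) if above.size else float(np.median(v))
    return v_rev0, g_max0, v_half0, 15.0


def fit_boltzmann(
    iv: pd.DataFrame, weighting: str = "inverse-variance"
) -> BoltzmannParams:
    """Weighted nonlinear least-squares fit of the Boltzmann I/V relation.

    ``weighting`` is "inverse-variance" (1/var per row, with zero or missing
    variances floored to the smallest positive variance in the table) or
    "none".  Weights are relative: uniformly rescaling all variances leaves
    the fit and its standard errors unchanged.  On failure from the default
    start, a multi-start over a V1/2 grid (0..200 mV in 40 mV steps) is
    attempted before raising :class:`FitFailureError`.
    """
    if len(iv) < 5:
        raise ValueError("need >= 5 voltages spanning the activation range")
    v = iv["v_mV"].to_numpy(dtype=float)
    i = iv["i_pA"].to_numpy(dtype=float)
    if weighting == "inverse-variance":
        var = iv["var_pA2"].to_numpy(dtype=float).copy()
        pos = var[var > 0]
        floor = float(pos.min()) if pos.size else 1.0
        var[~(var > 0)] = floor
        sigma = np.sqrt(var)
    elif weighting == "none":
        sigma = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    v_rev0, g_max0, v_half0, v_s0 = _start_values(v, i)
    starts = [(v_rev0, g_max0, v_half0, v_s0)]
    starts += [(v_rev0, g_max0, vh, v_s0) for vh in np.arange(0.0, 201.0, 40.0)]

    # keep Vrev and V1/2 near the sampled voltage range: unbounded, the
    # linear prefactor can degenerate (g_max -> 0 with v_rev -> -inf)
    span = float(np.ptp(v))
    lo = [v.min() - span, 0.0, v.min() - 2 * span, 1e-6]
    hi = [v.max() + span, np.inf, v.max() + 2 * span, 10 * span]
    last_err: Exception | None = None
    for p0 in starts:
        p0 = tuple(np.clip(p0, lo, hi))
        try:
            popt, pcov = curve_fit(
                boltzmann_current, v, i, p0=p0, sigma=sigma,
                absolute_sigma=False, maxfev=20000, bounds=(lo, hi),
            )
            se = np.sqrt(np.diag(pcov))
            return BoltzmannParams(
                v_rev_mV=float(popt[0]), g_max_nS=float(popt[1]),
                v_half_mV=float(popt[2]), v_s_mV=float(popt[3]),
                se_v_rev=float(se[0]), se_g_max=float(se[1]),
                se_v_half=float(se[2]), se_v_s=float(se[3]),
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    res = i - boltzmann_current(v, *starts[0])
    raise FitFailureError(f"Boltzmann fit did not converge: {last_err}", res)


@dataclass(frozen=True)
class PhotostateComparison:
    """cis-vs-trans comparison of fitted voltage dependence."""

    delta_v_half_mV: float      # V1/2(cis) - V1/2(trans); positive = leftward shift
    se_delta_v_half: float      # quadrature-propagated standard error
    rel_conductance_change: float  # (G_trans - G_cis)/G_cis at v_test
    v_test_mV: float


def compare_photostates(
    fit_cis: BoltzmannParams, fit_trans: BoltzmannParams, v_test_mV: float = 120.0
) -> PhotostateComparison:
    """Quantify the photoswitch effect on voltage-dependent activation.

    Reports the V1/2 shift (cis minus trans; positive when blue light moves
    activation leftward) with quadrature-propagated standard error, and the
    relative chord-conductance change at ``v_test_mV`` between the two
    fitted curves.
    """
    dv = fit_cis.v_half_mV - fit_trans.v_half_mV
    se = math.hypot(
        0.0 if math.isnan(fit_cis.se_v_half) else fit_cis.se_v_half,
        0.0 if math.isnan(fit_trans.se_v_half) else fit_trans.se_v_half,
    )
    g_cis = float(fit_cis.conductance(v_test_mV))
    g_trans = float(fit_trans.conductance(v_test_mV))
    rel = (g_trans - g_cis) / g_cis if g_cis != 0 else float("inf")
    return PhotostateComparison(
        delta_v_half_mV=dv, se_delta_v_half=se,
        rel_conductance_change=rel, v_test_mV=v_test_mV,
    )
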