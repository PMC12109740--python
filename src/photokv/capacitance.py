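"""Membrane-capacitance analysis: switch amplitude, relaxation kinetics, QC.

Photoisomerization of the bilayer's photolipid steps the membrane
capacitance Cm (blue light thickens the membrane, lowering Cm; UV thins it,
raising Cm).  Cm then relaxes monoexponentially as the solvent torus
retracts and the bilayer area recovers; the fitted time constant is the
same relaxation time that governs the torus tension model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .traces import BLUE, CapacitanceTrace, LightEvent

__all__ = [
    "SwitchExtremum",
    "CmRelaxationFit",
    "detect_switch_extremum",
    "fit_cm_relaxation",
    "specific_capacitance",
]


class DetectionFailureError(RuntimeError):
    """No qualifying extremum found in the search window."""


class FitFailureError(RuntimeError):
    """Relaxation fit did not converge or is unidentifiable."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class SwitchExtremum:
    """Capacitance extremum reached at completion of photoisomerization."""

    t_ms: float
    cm_pF: float
    baseline_pF: float
    rel_change: float  # (extremum - baseline) / baseline


@dataclass(frozen=True)
class CmRelaxationFit:
    """Monoexponential relaxation c(t) = c_plateau - amplitude*exp(-(t-start)/tau)."""

    c_plateau_pF: float
    amplitude_pF: float  # signed: positive when relaxing upward to the plateau
    tau_relax_ms: float
    rss: float
    se_tau_ms: float
    start_ms: float


def detect_switch_extremum(
    tr: CapacitanceTrace,
    ev: LightEvent,
    window_ms: float = 20.0,
    baseline_window_ms: float = 100.0,
    smooth_samples: int = 5,
) -> SwitchExtremum:
    """Locate the Cm extremum reached when photoisomerization completes.

    Blue light drives Cm to a minimum, UV to a maximum.  The trace is
    lightly smoothed (moving median over ``smooth_samples``) to suppress
    lock-in impulse noise, then the first local extremum after pulse onset
    is taken.  The pre-pulse baseline is the median of the
    ``baseline_window_ms`` window before onset.
    """
    t, cm = tr.time_ms, tr.cm_pF
    if t[-1] < ev.t_on_ms + window_ms or t[0] > ev.t_on_ms:
        raise ValueError("trace does not cover the detection window after the event")
    sm = median_filter(cm, size=smooth_samples, mode="nearest")
    pre = cm[(t >= ev.t_on_ms - baseline_window_ms) & (t < ev.t_on_ms)]
    if pre.size == 0:
        raise ValueError("no pre-event samples for the baseline")
    baseline = float(np.median(pre))

    sel = (t >= ev.t_on_ms) & (t <= ev.t_on_ms + window_ms)
    idx = np.flatnonzero(sel)
    seg = sm[idx] if ev.kind == BLUE else -sm[idx]
    # first interior local minimum of seg (minimum for blue, maximum for UV)
    interior = np.flatnonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] < seg[2:])) + 1
    span = float(np.ptp(seg))
    noise = 1.4826 * float(np.median(np.abs(np.diff(cm)))) if len(cm) > 1 else 0.0
    if interior.size == 0 or span <= max(5.0 * noise, 1e-12):
        raise DetectionFailureError(
            "no capacitance extremum found after the light pulse"
        )
    # among interior extrema keep the first that is deep relative to the span,
    # then refine to the raw-trace extremum in the smoothing neighbourhood
    depth_ok = interior[seg[interior] <= seg.min() + 0.25 * span]
    k = int(depth_ok[0] if depth_ok.size else interior[0])
    raw = cm[idx] if ev.kind == BLUE else -cm[idx]
    lo_k = max(k - smooth_samples, 0)
    hi_k = min(k + smooth_samples + 1, len(raw))
    k = lo_k + int(np.argmin(raw[lo_k:hi_k]))
    i = int(idx[k])
    return SwitchExtremum(
        t_ms=float(t[i]),
        cm_pF=float(sm[i]),
        baseline_pF=baseline,
        rel_change=(float(sm[i]) - baseline) / baseline,
    )


def _mono_exp(t, c_plateau, amplitude, tau):
    return c_plateau - amplitude * np.exp(-t / tau)


def fit_cm_relaxation(
    tr: CapacitanceTrace,
    start_ms: float,
    window_ms: float,
    tau_guess_ms: float | None = None,
) -> CmRelaxationFit:
    """Least-squares monoexponential fit of the Cm relaxation.

    Fits c(t) = c_plateau - amplitude*exp(-(t - start)/tau) over
    [start, start + window].  Standard errors come from the fit covariance.
    A fit whose relative tau uncertainty exceeds 100% (e.g. a window that
    contains only plateau) raises :class:`FitFailureError`.
    """
    sel = (tr.time_ms >= start_ms) & (tr.time_ms <= start_ms + window_ms)
    t = tr.time_ms[sel] - start_ms
    c = tr.cm_pF[sel]
    if t.size < 20:
        raise ValueError("need >= 20 samples in the fit window")
    if tau_guess_ms is None:
        tau_guess_ms = max(window_ms / 10.0, t[1] - t[0])
    amp0 = float(c[-1] - c[0])
    p0 = (float(c[-1]), amp0 if amp0 != 0 else 1e-3, float(tau_guess_ms))
    try:
        popt, pcov = curve_fit(
            _mono_exp, t, c, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, 1e-9], np.inf),
        )
    except (RuntimeError, ValueError) as err:
        raise FitFailureError(f"relaxation fit did not converge: {err}",
                              c - _mono_exp(t, *p0)) from err
    resid = c - _mono_exp(t, *popt)
    se_tau = float(np.sqrt(pcov[2, 2]))
    if not np.isfinite(se_tau) or (popt[2] > 0 and se_tau / popt[2] > 1.0):
        raise FitFailureError(
            "relaxation time unidentifiable in this window "
            f"(tau = {popt[2]:.3g} ms, se = {se_tau:.3g} ms)", resid)
    return CmRelaxationFit(
        c_plateau_pF=float(popt[0]),
        amplitude_pF=float(popt[1]),
        tau_relax_ms=float(popt[2]),
        rss=float(np.sum(resid**2)),
        se_tau_ms=se_tau,
        start_ms=start_ms,
    )


def specific_capacitance(
    cm_pF: float, bilayer_area_um2: float, threshold_uF_per_cm2: float = 0.75
) -> tuple[float, bool]:
    """Specific capacitance in uF/cm^2 and its pass/fail QC flag.

    Solvent-depleted bilayers are accepted above 0.75 uF/cm^2 (residual
    alkane between the leaflets lowers the value); the threshold is
    configurable.  1 pF/um^2 == 100 uF/cm^2.
    """
    if bilayer_area_um2 <= 0:
        raise ValueError("bilayer area must be positive")
    spec = cm_pF / bilayer_area_um2 * 100.0
    return spec, spec >= threshold_uF_per_cm2
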