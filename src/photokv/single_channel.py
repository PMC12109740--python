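"""Single-channel analysis: amplitude histograms, Gaussian-mixture activity,
light-response lag times, and unitary conductance.

Activity is quantified from the amplitude histogram of a trace segment:
the histogram is fitted with multiple Gaussians and the activity statistic
is the fitted area attributed to open-channel levels relative to the total
area.  Lag times measure the delay between completed photoisomerization of
the bilayer and the first channel opening (after blue light) or closing
(after UV).  Unitary conductance comes from an ordinary least-squares line
through single-channel current amplitudes across voltages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.optimize import least_squares

from .traces import BLUE, UV, CurrentTrace

__all__ = [
    "AmplitudeHistogram",
    "MixtureComponent",
    "MixtureFit",
    "ActivityResult",
    "LagResult",
    "build_histogram",
    "fit_mixture",
    "channel_activity",
    "lag_times",
    "unitary_conductance",
    "lowpass_zero_phase",
]


class FitFailureError(RuntimeError):
    """Mixture fit failed at every component count."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class AmplitudeHistogram:
    bin_edges_pA: np.ndarray
    counts: np.ndarray
    n_samples: int

    @property
    def centers_pA(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pA[:-1] + self.bin_edges_pA[1:])

    @property
    def bin_width_pA(self) -> float:
        return float(self.bin_edges_pA[1] - self.bin_edges_pA[0])


@dataclass(frozen=True)
class MixtureComponent:
    mean_pA: float
    sd_pA: float
    area: float  # fraction of total fitted area


@dataclass(frozen=True)
class MixtureFit:
    components: tuple[MixtureComponent, ...]  # sorted by mean
    baseline_index: int  # which component is the closed (all-channels-shut) state
    gof: float  # residual sum of squares of the density fit
    bic: float

    @property
    def unitary_amplitude_pA(self) -> float:
        """Median spacing between adjacent level means (pA)."""
        means = [c.mean_pA for c in self.components]
        if len(means) < 2:
            raise ValueError("unitary amplitude needs >= 2 mixture components")
        return float(np.median(np.diff(means)))


@dataclass(frozen=True)
class ActivityResult:
    activity_area: float      # open-area fraction of the mixture (Methods definition)
    activity_any_open: float  # 1 - closed-component area fraction
    n_open_states: int


@dataclass(frozen=True)
class LagResult:
    lags_open_ms: list[float]   # post-blue first-opening delays
    lags_close_ms: list[float]  # post-UV first-closing delays


def lowpass_zero_phase(i_pA: np.ndarray, sampling_khz: float,
                       cutoff_khz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (forward-backward)."""
    nyq = sampling_khz / 2.0
    if cutoff_khz >= nyq:
        return np.asarray(i_pA, dtype=float)
    b, a = signal.butter(4, cutoff_khz / nyq)
    return signal.filtfilt(b, a, i_pA)


def _transient_mask(tr: CurrentTrace, half_width_ms: float) -> np.ndarray:
    """Boolean mask of samples NOT inside any event-onset transient window."""
    keep = np.ones(tr.time_ms.shape, bool)
    for ev in tr.events:
        keep &= ~(
            (tr.time_ms >= ev.t_on_ms - half_width_ms)
            & (tr.time_ms <= ev.t_on_ms + half_width_ms)
        )
    return keep


def build_histogram(
    tr: CurrentTrace,
    t0_ms: float,
    t1_ms: float,
    mask_transients_ms: float = 5.0,
    filter_cutoff_khz: float | None = None,
    min_bin_width_pA: float = 0.05,
) -> AmplitudeHistogram:
    """Amplitude histogram of a trace segment.

    Samples within ``mask_transients_ms`` of any light-pulse onset are
    excluded (optocapacitive spikes are switching artifacts, not gating).
    Binning follows the Freedman-Diaconis rule with a floor of
    ``min_bin_width_pA``.  An optional zero-phase low-pass (the customary
    0.5-1 kHz display filter) is applied before binning.
    """
    if t1_ms <= t0_ms:
        raise ValueError("segment end must exceed segment start")
    i = tr.i_pA
    if filter_cutoff_khz is not None:
        i = lowpass_zero_phase(i, tr.sampling_rate_khz, filter_cutoff_khz)
    sel = (tr.time_ms >= t0_ms) & (tr.time_ms <= t1_ms)
    sel &= _transient_mask(tr, mask_transients_ms)
    x = i[sel]
    if x.size == 0:
        raise ValueError("segment contains no samples after transient masking")
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    width = max(2.0 * iqr / x.size ** (1 / 3), min_bin_width_pA)
    lo, hi = float(x.min()), float(x.max())
    n_bins = max(int(np.ceil((hi - lo) / width)), 1)
    edges = lo - width / 2 + np.arange(n_bins + 2) * width
    counts, edges = np.histogram(x, bins=edges)
    return AmplitudeHistogram(bin_edges_pA=edges, counts=counts, n_samples=int(x.size))


def _gauss_sum(centers: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; params = [mu1, sd1, a1, mu2, sd2, a2, ...]."""
    out = np.zeros_like(centers)
    for j in range(0, len(params), 3):
        mu, sd, a = params[j], params[j + 1], params[j + 2]
        out += a / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((centers - mu) / sd) ** 2)
    return out


def _init_means(h: AmplitudeHistogram, k: int) -> np.ndarray:
    """Seed component means from histogram peaks, topped up with quantiles."""
    c = h.centers_pA
    sm = np.convolve(h.counts.astype(float), np.ones(3) / 3.0, mode="same")
    peaks, props = signal.find_peaks(sm, prominence=0.02 * sm.max() if sm.max() > 0 else 0)
    order = np.argsort(props["prominences"])[::-1] if peaks.size else np.array([], int)
    means = list(c[peaks[order[:k]]])
    if len(means) < k:
        w = h.counts / h.counts.sum()
        cdf = np.cumsum(w)
        for q in (np.arange(k) + 0.5) / k:
            means.append(float(c[np.searchsorted(cdf, q)]))
    return np.sort(np.asarray(means[:k]))


def fit_mixture(
    h: AmplitudeHistogram,
    max_components: int = 4,
    equal_sd: bool = False,
    baseline_guess_pA: float | None = None,
) -> MixtureFit:
    """Least-squares multi-Gaussian fit to the amplitude histogram.

    Fits the histogram density with k = 1..``max_components`` Gaussians and
    selects k by the Bayesian information criterion computed from the
    binned residuals.  ``baseline_guess_pA`` identifies the closed state:
    the component whose mean is nearest to it (defaults to the histogram's
    weighted median, i.e. the pre-stimulus level for a mostly closed
    segment).  With ``equal_sd`` all components share one width.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    centers = h.centers_pA
    density = h.counts / (h.n_samples * h.bin_width_pA)
    span = float(centers[-1] - centers[0]) if len(centers) > 1 else 1.0
    sd0 = max(span / 20.0, h.bin_width_pA)

    best: tuple[float, np.ndarray, int] | None = None  # (bic, params, k)
    failures: dict[int, str] = {}
    n_bins = len(centers)
    for k in range(1, max_components + 1):
        means0 = _init_means(h, k)
        if equal_sd:
            p0 = np.concatenate([means0, [sd0], np.full(k, 1.0 / k)])

            def model(p, k=k):
                params = np.empty(3 * k)
                params[0::3] = p[:k]
                params[1::3] = p[k]
                params[2::3] = p[k + 1:]
                return _gauss_sum(centers, params)

            lb = np.concatenate([np.full(k, -np.inf), [h.bin_width_pA / 4],
                                 np.zeros(k)])
            n_par = 2 * k + 1
        else:
            p0 = np.empty(3 * k)
            p0[0::3] = means0
            p0[1::3] = sd0
            p0[2::3] = 1.0 / k

            def model(p):
                return _gauss_sum(centers, p)

            lb = np.tile([-np.inf, h.bin_width_pA / 4, 0.0], k)
            n_par = 3 * k
        try:
            res = least_squares(lambda p: model(p) - density, p0, bounds=(lb, np.inf),
                                max_nfev=20000)
        except ValueError as err:
            failures[k] = str(err)
            continue
        rss = float(np.sum(res.fun**2))
        bic = n_bins * np.log(max(rss / n_bins, 1e-300)) + n_par * np.log(n_bins)
        if best is None or bic < best[0]:
            if equal_sd:
                p = np.empty(3 * k)
                p[0::3] = res.x[:k]
                p[1::3] = res.x[k]
                p[2::3] = res.x[k + 1:]
            else:
                p = res.x
            best = (bic, p, k)
    if best is None:
        raise FitFailureError("mixture fit failed at every component count", failures)

    bic, params, k = best
    comps = sorted(
        (MixtureComponent(float(params[j]), float(params[j + 1]), float(params[j + 2]))
         for j in range(0, 3 * k, 3)),
        key=lambda comp: comp.mean_pA,
    )
    total = sum(comp.area for comp in comps)
    comps = [MixtureComponent(comp.mean_pA, comp.sd_pA, comp.area / total)
             for comp in comps if comp.area / total > 1e-12] or [
        MixtureComponent(comps[0].mean_pA, comps[0].sd_pA, 1.0)
    ]
    if baseline_guess_pA is None:
        w = h.counts / h.counts.sum()
        cdf = np.cumsum(w)
        baseline_guess_pA = float(centers[np.searchsorted(cdf, 0.5)])
    base = int(np.argmin([abs(comp.mean_pA - baseline_guess_pA) for comp in comps]))
    rss = float(np.sum((_gauss_sum(centers, np.array(
        [v for comp in comps for v in (comp.mean_pA, comp.sd_pA, comp.area)]
    )) - density) ** 2))
    return MixtureFit(components=tuple(comps), baseline_index=base,
                      gof=rss, bic=float(bic))


def channel_activity(m: MixtureFit) -> ActivityResult:
    """Activity statistics from the fitted mixture.

    ``activity_area`` is the summed area of open-state components over the
    total fitted area; ``activity_any_open`` is one minus the closed-state
    area fraction.  With areas normalized over one histogram the two
    coincide; both are reported for transparency.
    """
    closed = m.components[m.baseline_index].area
    total = sum(c.area for c in m.components)
    open_area = total - closed
    return ActivityResult(
        activity_area=open_area / total,
        activity_any_open=1.0 - closed / total,
        n_open_states=len(m.components) - 1,
    )


def _first_sustained(cond: np.ndarray, n_sustain: int) -> int | None:
    """Index of the first run of True of length >= n_sustain, else None."""
    if not cond.any():
        return None
    x = cond.astype(np.int8)
    edges = np.diff(np.concatenate([[0], x, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    ok = np.flatnonzero(ends - starts >= n_sustain)
    return int(starts[ok[0]]) if ok.size else None


def lag_times(
    tr: CurrentTrace,
    m: MixtureFit,
    photostationary_delay_ms: float = 1.5,
    sustain_ms: float = 1.0,
    transient_mask_ms: float = 3.0,
    filter_cutoff_khz: float | None = None,
) -> LagResult:
    """Delays between completed photoisomerization and the channel response.

    For each blue pulse, the lag to the first sustained (>= ``sustain_ms``)
    crossing above the half-level between the pre-pulse level and the next
    level up (an additional channel opening); for each UV pulse, the lag to
    the first sustained crossing below the half-level beneath the pre-pulse
    level (a channel closing).  t = 0 is pulse onset plus
    ``photostationary_delay_ms``, the time at which the bilayer reaches its
    photostationary composition.  Samples inside the optocapacitive
    transient window after onset are ignored.  Events with no qualifying
    crossing contribute nothing (empty lists are not an error).
    """
    i = tr.i_pA
    if filter_cutoff_khz is not None:
        i = lowpass_zero_phase(i, tr.sampling_rate_khz, filter_cutoff_khz)
    dt = tr.dt_ms
    n_sustain = max(int(round(sustain_ms / dt)), 1)
    unitary = m.unitary_amplitude_pA if len(m.components) > 1 else None
    lags_open: list[float] = []
    lags_close: list[float] = []
    for ev in tr.events:
        pre = i[(tr.time_ms >= ev.t_on_ms - 5.0) & (tr.time_ms < ev.t_on_ms)]
        if pre.size == 0:
            continue
        ref = float(np.median(pre))
        if unitary is None:
            continue
        t0 = ev.t_on_ms + photostationary_delay_ms
        start = max(t0, ev.t_on_ms + transient_mask_ms)
        sel = tr.time_ms >= start
        seg = i[sel]
        t_seg = tr.time_ms[sel]
        if ev.kind == BLUE:
            cond = seg > ref + 0.5 * unitary
        else:
            cond = seg < ref - 0.5 * unitary
        idx = _first_sustained(cond, n_sustain)
        if idx is None:
            continue
        lag = float(t_seg[idx] - t0)
        (lags_open if ev.kind == BLUE else lags_close).append(max(lag, 0.0))
    return LagResult(lags_open_ms=lags_open, lags_close_ms=lags_close)


@dataclass(frozen=True)
class ConductanceFit:
    g_pS: float
    v_rev_mV: float
    se_g_pS: float
    se_v_rev_mV: float


def unitary_conductance(
    voltages_mV: np.ndarray, amplitudes_pA: np.ndarray
) -> ConductanceFit:
    """Unitary conductance from the single-channel I/V relationship.

    Ordinary least-squares line i = g*(V - Vrev) through the per-voltage
    unitary current amplitudes; the slope in pA/mV converts to pS (x1000)
    and the x-intercept gives the reversal potential.  Requires >= 3
    distinct voltages.
    """
    v = np.asarray(voltages_mV, dtype=float)
    a = np.asarray(amplitudes_pA, dtype=float)
    if v.shape != a.shape or len(np.unique(v)) < 3:
        raise ValueError("need matching arrays with >= 3 distinct voltages")
    fit = stats.linregress(v, a)
    slope, icept = fit.slope, fit.intercept
    if slope == 0:
        raise ValueError("zero slope: conductance undefined")
    v_rev = -icept / slope
    # delta-method propagation, covariance term neglected
    se_vrev = abs(v_rev) * np.hypot(
        fit.stderr / slope, fit.intercept_stderr / icept if icept != 0 else 0.0
    ) if icept != 0 else fit.intercept_stderr / abs(slope)
    return ConductanceFit(
        g_pS=slope * 1e3,
        v_rev_mV=v_rev,
        se_g_pS=fit.stderr * 1e3,
        se_v_rev_mV=float(se_vrev),
    )
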