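"""Single-channel activity and light-response lags from a gating trace.

Simulates a three-channel recording at +120 mV in which a blue pulse
(thicker membrane) raises the open probability and a later UV pulse lowers
it again, then runs the amplitude-histogram mixture analysis and the lag
estimator.
"""

import numpy as np

from photokv import simulate, single_channel as sc
from photokv.traces import BLUE, UV, LightEvent

gs = simulate.GatingSpec(n_channels=3, g_unitary_pS=190.0,
                         p_open_cis=0.05, p_open_trans=0.30)
events = [LightEvent(750.0, 40.0, BLUE), LightEvent(2250.0, 40.0, UV)]
trace = simulate.simulate_single_channel(gs, events, voltage_mV=120.0,
                                         duration_ms=3000.0, seed=1)

for label, (t0, t1) in {"cis (pre-blue)": (0.0, 740.0),
                        "trans (post-blue)": (800.0, 2240.0)}.items():
    hist = sc.build_histogram(trace, t0, t1)
    fit = sc.fit_mixture(hist, max_components=4, baseline_guess_pA=0.0)
    act = sc.channel_activity(fit)
    print(f"{label:18s}: {len(fit.components)} fitted levels, "
          f"activity (any channel open) = {act.activity_any_open:.3f}")

hist = sc.build_histogram(trace, 0.0, 3000.0)
fit = sc.fit_mixture(hist, max_components=4, baseline_guess_pA=0.0)
lags = sc.lag_times(trace, fit)
print(f"unitary amplitude {fit.unitary_amplitude_pA:.1f} pA at +120 mV "
      f"({fit.unitary_amplitude_pA / 0.120:.0f} pS)")
print(f"first-opening lags after blue: {np.round(lags.lags_open_ms, 1)} ms")
print(f"first-closing lags after UV:  {np.round(lags.lags_close_ms, 1)} ms")
print("\nBlue light (thicker bilayer) raises the open-channel area fraction;")
print("the channels respond with a lag after the bilayer itself has switched.")
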