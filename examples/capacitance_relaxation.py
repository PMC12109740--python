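"""Fit the membrane-capacitance relaxation after a blue-light switch.

Simulates a lock-in capacitance record that steps down ~6% as the bilayer
thickens, then relaxes with tau = 23 ms; the analysis detects the switch
extremum and fits the monoexponential recovery.
"""

from photokv import capacitance, simulate
from photokv.traces import BLUE, LightEvent

event = LightEvent(t_on_ms=100.0, duration_ms=40.0, kind=BLUE)
spec = simulate.CmSpec(c_base_pF=80.0, dc_frac=-0.06, tau_relax_ms=23.0,
                       noise_sd_pF=0.05)
trace = simulate.simulate_cm_trace(spec, event, duration_ms=500.0, seed=1)

ext = capacitance.detect_switch_extremum(trace, event)
fit = capacitance.fit_cm_relaxation(trace, start_ms=ext.t_ms, window_ms=230.0)
spec_cap, ok = capacitance.specific_capacitance(trace.cm_pF[0], 9000.0)

print(f"switch extremum at t = {ext.t_ms:.1f} ms, "
      f"relative change {100 * ext.rel_change:.2f} %")
print(f"relaxation tau = {fit.tau_relax_ms:.2f} +- {fit.se_tau_ms:.2f} ms")
print(f"specific capacitance {spec_cap:.2f} uF/cm^2 -> QC {'pass' if ok else 'fail'}")
print("\nThe ~6% capacitance drop reports bilayer thickening; its 23 ms")
print("recovery tracks the torus retraction and bounds how long any excess")
print("tension can persist.")
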