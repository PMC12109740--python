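"""Photoswitching shifts the voltage dependence of channel activation.

Simulates ensemble voltage-step families for the cis (thin) and trans
(thick) bilayer states, extracts steady-state I/V tables, fits the
Boltzmann relation with inverse-variance weighting, and reports the V1/2
shift between photostates.
"""

import numpy as np

from photokv import ensemble, simulate

spec = simulate.EnsembleSpec(
    boltz_cis=ensemble.BoltzmannParams(v_rev_mV=0.0, g_max_nS=2.0,
                                       v_half_mV=158.6, v_s_mV=15.0),
    boltz_trans=ensemble.BoltzmannParams(v_rev_mV=0.0, g_max_nS=2.0,
                                         v_half_mV=120.9, v_s_mV=15.0),
    sweep_noise_sd_pA=5.0,
)
protocol = list(np.arange(-40.0, 161.0, 20.0))  # 20 mV steps

fits = {}
for k, state in enumerate(("cis", "trans")):
    sweeps = simulate.simulate_ensemble_sweeps(spec, protocol, state=state,
                                               seed=k, n_replicates=5)
    iv = ensemble.extract_currents(sweeps, mode="steady")
    fits[state] = ensemble.fit_boltzmann(iv)
    f = fits[state]
    print(f"{state:5s}: V1/2 = {f.v_half_mV:6.1f} +- {f.se_v_half:4.1f} mV, "
          f"Vs = {f.v_s_mV:.1f} mV, Gmax = {f.g_max_nS:.2f} nS")

cmp_res = ensemble.compare_photostates(fits["cis"], fits["trans"], v_test_mV=120.0)
print(f"delta V1/2 (cis - trans) = {cmp_res.delta_v_half_mV:.1f} "
      f"+- {cmp_res.se_delta_v_half:.1f} mV")
print("\nA positive shift means the thick (trans) membrane activates at lower")
print("voltage: light-induced thickening facilitates voltage-sensor movement.")
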