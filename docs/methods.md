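# Methods

This note records the models, estimators and numerical choices behind
`photokv`, and what the synthetic generators do and do not emulate.

## The physical setting

A planar lipid bilayer (PLB) folded across a PTFE aperture is anchored by a
solvent torus and doped with an azobenzene photolipid (OptoDArG). UV light
(375 nm) drives the photolipid trans→cis — larger area per lipid, thinner
membrane, higher specific capacitance; blue light (488 nm) drives cis→trans —
smaller area, thicker membrane, lower capacitance. Reconstituted KvAP
channels in the bilayer respond to the thickness change with altered gating.
The package quantifies four strands of evidence: (i) the transient tension
generated by the area jump is tiny; (ii) the tension relaxes within tens of
milliseconds (capacitance and imaging kinetics agree); (iii) single-channel
activity switches with the photostate, after a measurable lag; (iv) the
ensemble conductance–voltage relation shifts leftward in the thick state.

## Torus tension-relaxation model (`photokv.tension`)

When blue light shrinks the bilayer area, the rim radius jumps inward from
r0 to r_in and the lateral tension rises from σ0 to σ0(1 + α). Assuming the
excess tension decays linearly over the relaxation interval [0, τ],
σ(t) = A·t + B with A = −ασ0/τ and B = σ0(1 + α), and radial viscous flow
of lipid obeys

    dr/dt = r · (σ(t) − σ0) / (2 η_h),

where η_h is the surface viscosity (membrane viscosity × thickness). The
driving term is the *excess* tension σ − σ0: at σ = σ0 the rim is in
equilibrium and does not move. (The bare flow law is sometimes written with
σ alone; only the excess-tension form satisfies that equilibrium condition
and the boundary behaviour below, so that is what is implemented.)
Integrating with r(0) = r_in and r(τ) = r0 gives the closed form

    r(t) = r_in · exp[ ln(r0/r_in) · (2τ − t) t / τ² ],
    α    = 4 ln(r0/r_in) · η_h / (σ0 τ).

Parameters and defaults (the worked case):

| parameter | meaning | unit | worked value |
|---|---|---|---|
| r0 | equilibrium mid-torus radius | µm | 29.5 |
| r_in | radius right after the blue switch | µm | 27.5 |
| σ0 | resting lateral tension | mN/m | 4 |
| τ | relaxation time constant | ms | 23 |
| η_h | surface viscosity | nN·s/m | 4 (solvent-depleted PLB) or 500 (upper bound for lipid domains) |

Both viscosity values are exposed as plain inputs; neither is privileged as
a default truth, since literature estimates span orders of magnitude. With
the worked geometry, α = 0.0012% at η_h = 4 nN·s/m and 0.15% at
500 nN·s/m (σ rising from 4 to 4.006 mN/m) — either way far below anything
known to gate a Kv channel.

Numerics: public parameters stay in the units above; a single conversion
layer maps to SI before quantities combine (α depends on radii only through
their ratio, so the geometry unit cancels). `radius_ode_oracle` integrates
the flow ODE with a fixed-step classical 4th-order Runge–Kutta scheme —
fixed-step for bit-reproducibility — and agrees with the closed form to
better than 1e-6 relative at 1e4 steps across the tested parameter ranges.
Times outside [0, τ] are rejected rather than extrapolated (the linear-σ
model is only defined on the relaxation interval); endpoint float roundoff
up to 1e-9·τ is clamped.

## Synthetic generators (`photokv.simulate`)

The generators produce every input the analyses consume, with the
statistical structure the analyses assume, so the pipeline is testable
without the original recordings.

**Gating traces.** Each channel is an independent two-state (closed/open)
Markov chain updated at fixed dt with exact per-step transition
probabilities 1 − exp(−k·dt). The stationary open probability depends on
the bilayer photostate (defaults p_open = 0.05 cis, 0.30 trans, the
direction of the observed effect); k_total = k_open + k_close (default
1 ms⁻¹) sets dwell times. The bilayer reaches its photostationary
composition 1.5 ms after pulse onset (within the observed 1–2 ms); each
channel's kinetic regime then follows after an exponentially distributed
lag whose mean is direction-specific (10 ms for post-blue openings, 40 ms
for post-UV closings, matching the observed lag scales). The exponential
shape is a generator choice — the true lag distribution is not known.
Open channels add g·(V − Vrev) each (default 190 pS); an optocapacitive
transient is injected at each pulse onset as an amplitude-scaled
biexponential spike (positive for UV, which raises capacitance; negative
for blue) — a shape proxy, not a C(t)·dV/dt circuit model, since only its
presence and sign matter to the detectors that mask it. Two-state gating
deliberately omits inactivation: the emulated observation windows are too
short to resolve it.

**Ensemble sweeps.** Per step voltage, the steady current follows the
Boltzmann I/V relation of the chosen photostate with a monoexponential
activation onset (τ_act default 10 ms) and per-sample Gaussian noise;
replicates give the per-voltage variance the weighted fit consumes.
`simulate_iv_table` draws replicate currents directly around the Boltzmann
curve for table-level recovery studies.

**Capacitance records.** Cm ramps by dc_frac (default −6%, the observed
steady-state change) over the 1.5 ms switch, then relaxes monoexponentially
(τ default 23 ms) toward a plateau recovering a configurable fraction of
the step (default 0.6), emulating the partial area recovery as the torus
retracts.

**Line-profile stacks.** Each frame is the mean of 11 synthetic camera
lines (per-line Gaussian noise); the underlying profile is a smoothed
bright top-hat whose half-maximum edges sit at ±r(t). Frames are exposure
averages: the radius is sub-sampled along the closed-form trajectory
within each frame interval. This motion blur is essential — the relaxation
completes within one 40 ms frame, so the lag-1 difference deflection the
detector looks for arises entirely from intra-frame motion. The generator
does not model EMCCD noise statistics, 2-D torus shape, or illumination
gradients; consequently the profile tests validate the detector logic and
geometry read-back, not camera physics.

All generators are seeded (`numpy.random.default_rng`); identical spec +
seed gives bit-identical output.

## Capacitance analysis (`photokv.capacitance`)

The switch extremum (minimum for blue, maximum for UV) is found on a
5-sample moving-median-smoothed trace — lock-in records carry impulse noise
at light onsets — then refined to the raw-trace extremum within the
smoothing neighbourhood. The baseline is the median of a 100 ms pre-event
window; the relative change is reported against that baseline. The
relaxation is fitted as c(t) = c_plateau − A·exp(−(t − start)/τ) by
nonlinear least squares, with standard errors from the covariance; the fit
treats the relaxation as a single exponential and makes no attempt to
decompose area- vs thickness-driven contributions. A window containing
only plateau yields an unidentifiable τ (relative se > 100%) and raises a
fit failure rather than returning a number. Specific capacitance is
cm/area (1 pF/µm² = 100 µF/cm²) with a configurable QC threshold of
0.75 µF/cm² for solvent-depleted bilayers.

## Profile differencing (`photokv.profiles`)

Raw lines are averaged per frame (mean only, no filtering). A difference
Z_a − Z_b is flagged as a deflection when its largest magnitude exceeds
k = 5 robust noise sd (MAD-based, estimated from the same difference; the
moving edges occupy a minority of pixels, so the MAD is dominated by the
static background). The visual judgement of the original analysis is thus
replaced by a fixed, reproducible multiple. Edge positions are half-maximum
crossings with linear sub-sample interpolation; ~1 px accuracy suffices
because the tension model depends only on ln(r0/r_in). The relaxation bound
is (smallest deflection-free lag) × frame interval; when several switching
events are available, difference profiles are averaged across events before
detection (averaging detections instead is also supported).

## Single-channel analysis (`photokv.single_channel`)

Histograms use Freedman–Diaconis binning floored at 0.05 pA; samples within
±5 ms of pulse onsets are masked (transients are switching artifacts, not
gating). An optional zero-phase Butterworth low-pass (the customary
0.5–1 kHz display filter) can be applied first; it defaults to off so that
level structure is preserved exactly on clean data. The mixture fit is
least-squares multi-Gaussian on the histogram density, with the component
count chosen by BIC over 1..max_components (computed from the binned RSS) —
"several Gaussians" needs an explicit rule to be reproducible. Components
may have free widths (filtering broadens open levels differently); an
equal-width constraint is available. The closed state is the component
whose mean is nearest a caller-supplied baseline guess (default: the
histogram's weighted median).

Activity is reported two ways: the open-component area fraction
(Σ open areas / Σ all areas) and 1 − closed-area fraction. Over a single
normalized mixture these are algebraically identical; both fields exist so
downstream code can state explicitly which definition it used.

Lag times: t = 0 is pulse onset + 1.5 ms (photostationary completion).
An opening is the first crossing above the half-level one unitary amplitude
above the pre-pulse level, sustained ≥ 1 ms (suppressing filtered-noise
excursions); a closing mirrors this downward. Samples inside the transient
mask are ignored, which censors lags shorter than the mask end; for an
exponential lag distribution this inflates the mean by < 0.1 ms at the
default settings. Unitary conductance is an OLS line through per-voltage
unitary amplitudes (slope in pA/mV × 1000 → pS; x-intercept → reversal
potential, delta-method standard error without the slope–intercept
covariance term).

## Ensemble I/V (`photokv.ensemble`)

`extract_currents` subtracts the pre-step median baseline and reports
either the peak (default; taken on a 5 ms boxcar-smoothed segment so the
peak is the macroscopic current, not the largest noise excursion) or the
trailing-window steady-state mean. The Boltzmann fit

    I(V) = (V − Vrev) · Gmax / (1 + exp((V1/2 − V)/Vs))

uses nonlinear least squares with σ = √variance per row and relative
weights (uniformly rescaling all variances changes nothing); zero or
missing variances are floored to the smallest positive variance in the
table. Start values: Vrev from the minimum-|I| voltage, Gmax from the
steepest chord, V1/2 at half-maximal chord conductance, Vs = 15 mV; on
failure a multi-start over V1/2 ∈ {0, 40, …, 200} mV is tried. Vrev and
V1/2 are bounded to within a protocol-span margin of the sampled voltages:
unbounded, the linear prefactor can degenerate (Gmax → 0 with Vrev → −∞).
Normalization of I/V curves is a display transform only; fitting always
operates on unnormalized currents to avoid correlated-noise distortion.
The photostate comparison reports ΔV1/2 = V1/2(cis) − V1/2(trans) with
quadrature-propagated se, and the relative chord-conductance change at a
test voltage. The pipeline's cis/trans stage extracts steady-state currents
by default, since that comparison concerns currents recorded after the
tension has relaxed; peak extraction remains first-class for
activation-curve work.

## Problem sizes

Default study conditions: gating traces 2–3 s at dt = 0.04–0.1 ms with 1–4
channels; 10 replicate seeds per grid point for the activity study; 200
synthetic I/V tables per true V1/2 (11 voltages, 5 replicates each) for
the Boltzmann recovery study; 100 replicates for the capacitance recovery
study; 8–10 frame stacks of 256-pixel profiles for the torus bound. These
sizes give Monte-Carlo error comfortably below the tolerances they are
checked against while keeping any single study in the seconds-to-minutes
range.

## Known limitations

- The generators emulate statistical structure, not biophysics: no
  photochemistry kinetics, no membrane-voltage circuit, no inactivation,
  no 2-D imaging. Passing tests show the estimators recover what the
  generators encode, not that real recordings are this well behaved.
- The lag estimator requires a resolvable unitary amplitude (≥ 2 mixture
  components); on segments that never visit a second level it records
  nothing.
- The capacitance fit assumes a single exponential; genuinely biphasic
  relaxations will bias τ toward the dominant component.
- The ODE oracle is an internal consistency check for the closed form, not
  a hydrodynamic simulation of the torus.
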