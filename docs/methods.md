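# Methods

## Scope

`cavclamp` has two halves that check each other. The *analysis* half is the
procedure an electrophysiologist applies to step-step-ramp recordings of
CaV1.2 current: per-trace passive (linear-leak) subtraction or full-block
template subtraction, step/ramp peak measurement, fractional inhibition from
last-10-trace averages, and Hill concentration–inhibition fits with 95% CI
bands. The *simulator* half generates whole-cell recordings with the
artifacts that make that procedure necessary — rundown, temperature drift,
series-resistance error, leak, outward contamination, state-dependent block —
from known ground truth, so each analysis stage has an oracle.

## The voltage protocol

From a holding potential of −80 mV: −90 mV for 100 ms (leak probe), −80 mV
for 100 ms, 0 mV for 40 ms (step current), +30 mV for 200 ms (drives
channels into inactivation), then a 100 ms ramp back to −80 mV (−1.1 V/s,
ramp current), delivered at 0.2 Hz and sampled at 10 kHz. All voltages in
the package are membrane voltages; the liquid junction potential enters only
through `command_for_membrane` (V_pipette = V_membrane + LJP, e.g. −80 mV →
−63 mV at LJP 17 mV). A 10 ms pre-roll at holding is prepended to every
sampled sweep; the holding-current window needs somewhere to live, and the
standard protocol description does not say where it was measured — the
pre-roll is our convention. Segment durations must be integer multiples of
the sample interval so that windows and boundaries land exactly on samples;
step transitions belong to the first sample of the new segment.

## The cell model

Gating is Hodgkin–Huxley: activation `m` (current ∝ m², τ_act 0.8 ms,
V½ −18 mV), one voltage-dependent inactivation gate `h` (τ 400 ms, V½
−25 mV), and one Ca²⁺-dependent inactivation gate `f = 1/(1 + k·s)` where
`s` low-pass filters the instantaneous inward ionic current (τ 12 ms). A
Markov scheme would be more flexible, but HH gates with the occupancy
read-outs `p_open = m²hf`, `p_inact = m²(1−hf)`, `p_rest = 1−m²` generate
the full state-dependent phenomenology while keeping the binding oracle
closed-form. The driving force is ohmic, `g·(V−E_rev)`, with E_rev +46 mV in
Ca²⁺ and +35 mV in Ba²⁺ — the same linearization the I-V extrapolation of
the reversal potential assumes. Ba²⁺ recording means `cdi_gain = 0`.

Defaults were set once, against published whole-cell anchors for this
channel, and not revisited: C_m 35.2 pF, R_s 4.5 MΩ compensated 80% with a
156 µs lag (1.02 kHz bandwidth), step current ≈ −2 nA peaking ≈ 2 ms after
the 0 mV transition, ramp-to-step ratio ≈ 0.35 in Ca²⁺ and ≈ 0.59 in Ba²⁺,
ramp peak near −2 mV (Ca²⁺) / −6 mV (Ba²⁺). `tau_vdi = 400 ms` and
`cdi_gain = 2.5` are the two calibrated values that place those ratios;
everything else is standard for L-type channels.

**Rundown** is a deterministic conductance multiplier
`a_f·e^(−t/τ_f) + a_s·e^(−t/τ_s) + r_inf` of time since break-in (defaults
0.25/50 s, 0.40/400 s, plateau 0.35, ≈ 0.42 of initial current at trace
150). It scales conductance only — kinetics untouched — consistent with
rundown acting as a progressive loss of available channels (the constancy of
the ramp-to-step ratio under rundown is a test). The biexponential form is a
modeling choice; the mechanism of rundown is genuinely unresolved.

**Temperature** acts through standard Q10 factors: conductance ×
`q10_g^((T−37)/10)` (default 2.3, giving a 12–35%-per-3 °C amplitude swing),
all gating rates × `q10_rates^((T−37)/10)` (default 2.5). Drug binding rates
are *not* temperature-scaled: how potency moves with temperature is
drug-specific and is exactly the kind of question the pipeline is meant to
probe, so the generator does not hard-code an answer.

**Series resistance.** The pipette drives the membrane through R_s; the
compensation feedback boosts the command by `α·R_s·I_filt` where `I_filt` is
the pipette current low-passed with the lag time constant. Whole-cell
capacitance is assumed ideally neutralized, so the *recorded* current is the
pipette current minus `c_m·dV_m/dt` — i.e. the membrane ionic + leak +
outward current at the true, Rs-distorted V_m. Without this, every step edge
carries a multi-nanoamp charging spike that no real amplifier trace (with
neutralization engaged) shows, and the step-peak window would measure the
artifact instead of the channel. With `r_s = 0` the clamp is ideal and the
recording is exact.

**Drug block** is kinetic: `db/dt = c·(k_open·p_open + k_inact·p_inact +
k_rest·p_rest)(1−b) − k_off·b`, with on-rates in 1/(µM·s) per state. The
closed-form fixed point `k_off/(k_off + c·Σk·p)` is the oracle the
integrator must converge to at frozen occupancies. Between sweeps (5 s
interval) binding relaxes analytically at resting occupancy. Facilitation —
seen experimentally for methadone at tens of µM — is a phenomenological
open-conductance bonus `1 + gain·c/(c + EC50_f)`; it claims no mechanism.
Presets: an open+inactivated blocker (`k_off` 0.1/s, slow enough that block
accumulates over 0.2 Hz stimulation), a pure open blocker, a facilitating
blocker, and a saturating "template" blocker standing in for 100 µM
verapamil.

**Noise** is i.i.d. Gaussian per sample on the recorded current (default
4 pA); the pre-noise recording is retained on each simulated sweep so tests
can separate estimator error from irreducible noise.

## Numerics

Fixed-step RK4 at 20 µs, decimated to the 10 kHz sample grid; fixed step
keeps bit-level determinism, and 20 µs resolves the fastest gate (τ_act
0.8 ms) and the default clamp pole comfortably. When the partially
compensated Rs–membrane pole or the lag filter would be too fast for 20 µs,
the internal step is refined automatically (bound 2.0/|fastest pole| against
RK4's ≈ 2.78 stability limit); a diverged state is reported with the
offending time, never returned silently. The inner loop is numba-compiled;
the one-time JIT cost (~5 s) is paid per process.

Command voltages at stage points of each RK4 step use the segment-exact
value (midpoint average on ramps), so step edges stay sharp and ramps are
second-order accurate.

## Analysis conventions

* Measurement windows (not stated in the original procedure): I₋₉₀ and I₋₈₀
  are means over the final 50 ms of the −90 mV and second −80 mV segments,
  clear of settling transients. Configurable.
* R_input is recomputed for every trace; a denominator |I₋₉₀ − I₋₈₀| below
  1 pA is a hard error, not a silent skip.
* Step peak: minimum over the 0 mV segment excluding the first 0.5 ms (the
  "clear separation from the capacitive transient" criterion made
  operational); ties break earliest. Ramp peak: minimum over the whole ramp,
  reported with the *command* voltage at the minimizing sample — what an
  experimenter reports, not the simulator's hidden true V_m.
* Method selection: the step current always comes from passive-subtracted
  traces (a sizable step current survives full block, so the template would
  subtract real signal). The ramp uses the full-block template only when the
  passive-subtracted block trace shows > +50 pA sustained ≥ 5 ms in the
  +30 mV/ramp region *and* R_input and I₋₈₀ are stable (within 30% / 50 pA
  of their experiment medians); when both methods are viable, passive wins.
  The template averages the last 5 full-block sweeps by default; how many
  traces define "full inhibition" is not specified anywhere, so 5 is ours.
* Rundown correction (OLS slope vs trace index, loss added back) is used
  only for temperature/Rs analyses, never inside IC50 estimation.
* Hill fits run on individual cells' points, parameterized in log10(IC50)
  with n_H ∈ (0.05, 5], trust-region least squares from three deterministic
  starts spanning the tested range; maximal inhibition is fixed at 1, as in
  the printed Hill form. Fitting concentration means instead is available as
  an option (it shifts IC50s slightly). Concentrations whose mean inhibition
  is negative (facilitation) are excluded from the default fit but kept in
  the data; a flag re-includes them.
* CI bands: delta method (first-order propagation of the Gauss–Newton
  covariance, Student-t quantile). Because the curve's top and bottom are
  fixed, the half-width is ∝ f(1−f): bands are widest in the transition
  region and pinch to zero at both asymptotes. A seeded cell-level bootstrap
  is provided as an alternative. The original figures do not state their
  band construction, so band *widths* are not comparable across
  implementations — only the fits are.

## What the generator does and does not emulate

It emulates: biexponential rundown to a plateau; Q10 temperature scaling;
CDI vs no-CDI charge-carrier differences; partial, lagged Rs compensation
and its step/ramp asymmetry; passive leak and a nonlinear outward
contaminant; state-dependent block with cell-to-cell lognormal spread
(g_max, R_s, rundown taus) and 1–2 concentrations per cell.

It does not emulate: GHK rectification or ion accumulation, capacitive
transient remnants, perfusion/wash-in kinetics (solution changes are
instantaneous at epoch boundaries), temperature-dependent binding, seal
degradation, or recording-bandwidth filtering beyond the compensation lag.
A green pipeline test therefore establishes that the *analysis* is correct
for data with the stated structure — not that the simulator's absolute
potencies match wet-lab values, which is explicitly a non-goal.

One test-design note: the leak-subtraction exactness check bounds the
*estimator* error — the estimated passive current against the known
pre-noise recording — by 3 noise-sd. The raw corrected trace also carries
the irreducible per-sample recording noise, whose maximum over ~5,500
samples exceeds 3σ almost surely for any noise level; no subtraction method
can remove it, so it is excluded from the bound.

## Known limitations

* The HH + occupancy-read-out binding model cannot represent genuinely
  multi-site or allosteric schemes; shallow Hill slopes emerge here from
  state-mixing and use-dependence, not from the (unknown) true mechanism.
* The equilibrium-block oracle for end-to-end IC50s holds in the
  slow-binding limit (k_off ≪ cycle rate). Faster unbinding makes the bound
  fraction oscillate within the stimulus cycle and the measured peak samples
  its minimum — a real use-dependence effect that the closed form does not
  capture.
* Reversal-potential extrapolation inherits the activation curve's residual
  curvature on the fitted limb; with activation saturating below the fit
  range the error is < 2 mV, but cells with depolarized activation midpoints
  bias the extrapolation upward.
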