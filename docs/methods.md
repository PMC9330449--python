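# Methods

## The model

`hptsim` simulates the hypothalamic–pituitary–thyroid (HPT) axis as a
19-state compartmental ODE system in the THYROSIM family of physiologically
based models, with a personalized brain–pituitary TSH submodel. State
variables are amounts (µmol; TSH in internal mU-equivalent units):

* plasma, fast-tissue (liver/kidney) and slow-tissue pools for T4 and T3;
* a plasma/tissue TSH pool;
* a lumped "brain T3" variable `T3B` and a lagged copy `T3B_LAG` standing in
  for the pituitary/hypothalamic T3 signals that suppress TSH secretion —
  the lag is realized as a state with a T3-dependent rate (fast, ~2 h⁻¹,
  at normal brain T3; very slow, 0.0034 h⁻¹, when depleted), keeping the
  system a pure ODE rather than a delay equation;
* oral dosing chains (undissolved pill → absorbable gut pool) for LT4 and
  LT3 with 88% bioavailability;
* a six-stage delay chain carrying plasma TSH to the thyroid gland, whose
  output drives thyroidal T4 and T3 secretion.

Key nonlinearities: cubic free-hormone fractions for plasma T4 and T3
(protein binding), Michaelis–Menten deiodinase conversion of T4 to T3 in
fast and slow tissues, saturable TSH degradation, and the TSH secretion
function

    SR_TSH(t) = [B0 + A0 · f_CIRC · sin(π t/12 − φ)] · K^m / (K^m + T3B_LAG^m)

with `f_CIRC = T3B_LAG^n / (T3B_LAG^n + K_circ^n)`. Both factors are Hill
functions: secretion *saturates* at `B0 = 450` as brain T3 collapses
(giving an athyreotic TSH plateau near 1000 mU/L) instead of growing
exponentially, and the circadian amplitude gate makes TSH fluctuations
vanish in deep hypothyroidism. The brain T4→T3 conversion gain is a
decreasing Hill function bounded between `k3` and `6 k3`.

### Parameter provenance

The default parameter set combines the base-model kinetic constants of the
open-source THYROSIM lineage with the re-estimated personalized values
(`S4 = 0.00278`, `VmaxD1fast = 0.0121`, `k05 = 0.185`, `A0 = 220`,
`B0 = 450`, `k3 = 0.0589`, the Hill constants `K_circ = 3`,
`K_SR_TSH = 3.1`, `n = 5.68`, `m = 6.29`, `K_f4 = 8.5`, `l = 14.4`, the
anthropometric references `BMI_Mref = 21.8`, `BMI_Fref = 23`,
`H_Mref = 1.76`, `H_Fref = 1.67`, and the male clearance multiplier
`C_M = 1.05`; `VmaxTSH = 0.226`). The base constants were transcribed from
knowledge of the published model family rather than copied from a specific
source file; the transcription was validated by closing the euthyroid mass
balances by hand (plasma T4 ≈ 78–87 µg/L, T3 ≈ 1.3–1.7 µg/L,
TSH ≈ 1.4–1.8 mU/L at the fixed point) and by the athyreotic plateau.
Constants affecting only intra-day kinetics (pill dissolution rates
1.3/1.78 h⁻¹, circadian phase φ = −3.71) carry more uncertainty than the
steady-state-determining rates; none of the headline results depend on
them strongly.

## Personalization

A patient is (sex, height H, weight BW, optional hematocrit; defaults 0.45
male / 0.40 female). Three parameters are personalized:

1. **Plasma volume.** Ideal body weight is a sex-specific quadratic in H;
   blood volume follows the two-parameter power law
   `V_B = 1.27 (100 + Δ_iBW)^(0.373−1) BW` (liters) in the percent
   deviation from ideal weight, and `V_P = V_B (1 − HEM)`. Because the base
   model was calibrated at 3.2 L, raw volumes are rescaled by
   `V_Pnew = 3.2 V_P / V_Pref`, where `V_Pref = 2.774 L` is the average of
   the reference male (67.53 kg, 1.76 m) and female (64.14 kg, 1.67 m) —
   reference weights derived as BMI_ref · H_ref².
2. **TSH distribution volume**: `V_TSHnew = 5.2 + (V_Pnew − 3.2)` (the
   2.0 L non-vascular tissue space is held fixed).
3. **T3 clearance**: `k05_new = [C_M] · k05 · (BW/BW_ref)^(3/4)`, with the
   `C_M = 1.05` factor on the male branch only.

Inside the ODE, nonlinear terms calibrated at the reference volumes (the
free-hormone cubics, saturable TSH degradation, brain uptake normalizers)
receive *concentration-equivalent* amounts `q · V_ref / V_patient`; linear
fractional rates act on amounts directly. This choice makes simulated
*concentrations* nearly invariant under pure volume changes — which is what
the volume rescaling was constructed to achieve — and is the main place
where the reconstruction had genuine freedom; the alternative (raw amounts
in the nonlinearities) breaks that invariance and was rejected.

Residual thyroid function (RTF) multiplies both thyroidal secretion gains
(`S4`, `S3`) by a fraction in [0, 1]; `rtf = 0` is a complete
thyroidectomy.

## Simulation

LSODA with rtol 10⁻⁶ / atol 10⁻⁹ (TSH spans four orders of magnitude
across scenarios). Oral doses are bit-exact events: the integrator stops at
each dose time and the bolus (µg / 777 for T4, µg / 651 for T3) is added to
the pill compartment. Constant T3 infusion (an idealized slow-release
preparation) enters plasma through the RHS, bypassing absorption. The RHS
clips sub-tolerance negative states to zero; negativity beyond 10⁻⁵ µmol
aborts with an error. Time is phase-locked to the circadian clock (t mod
24 h), so 12 h and 24 h regimens stay aligned and end-of-day states are
phase-comparable across course lengths.

The euthyroid initial condition integrates the undosed system in 10-day
blocks until day-averaged hormones change < 10⁻⁵ (relative), starting from
a stored approximate fixed point. Steady states under dosing run up to 50
days (ample for this system: the slowest mode, the depleted brain-T3 lag,
has a ~12-day time constant) with early stopping once consecutive
day-averages agree to 2·10⁻⁴; runs whose last two day-averages differ by
more than 0.5% are flagged non-converged. Convergence denominators are
floored at ~1% of low-normal levels so hormones decaying to zero do not
block detection.

## Dose optimization

* **LT4 monotherapy**: exhaustive search over 62.5–325 µg in 12.5 µg steps
  (22 tablet doses); each candidate is a 42-day course of a completely
  thyroidectomized (`rtf = 0`) patient from the euthyroid state, mimicking
  the clinical titration protocol. The selected dose minimizes
  |TSH(day 42) − 1.8 mU/L|, the value read at end of course (the trough for
  once-daily dosing; the protocol does not fix the sampling time relative
  to the last dose, and trough sampling is the clinical convention). A
  joint objective |T4 − a|/60 + |TSH − b|/4 is also provided, with targets
  defaulting to range midpoints.
* **LT4+LT3 combination**: 2-D exhaustive search (LT3 0–20 µg in 2.5 µg
  steps) minimizing the symmetric normalized L1 distance of the steady
  state from the normal-range midpoints, Σ_h |h − mid_h| / halfwidth_h.
  The steady state is scored by the final-day dosing-cycle *average* (the
  clinically targeted quantity, and phase-consistent across once-daily,
  twice-daily and infusion schedules). Ties break toward the lower dose
  (clinical conservatism, determinism). Scenario set: male/female ×
  BMI {18.5, 23, 29} at the reference heights × {once-daily @ RTF 10%,
  twice-daily @ RTF 15%, LT4 + T3 infusion @ RTF 25%}.
* **Normal ranges** (configurable): TSH 0.5–4.5 mU/L (the titration
  protocol's interval), total T4 45–105 µg/L (105 is the printed
  normal-range maximum), total T3 0.8–2.0 µg/L — the standard clinical
  interval, adopted because no T3 bounds are fixed by the protocol. The
  combination optima, especially the LT3 component, are sensitive to the
  T3 interval: a narrower interval (e.g. 0.6–1.8) shifts several scenarios
  to LT3 = 0 because peripheral T4→T3 conversion alone reaches the lower
  midpoint.
* **Accuracy scoring**: a predicted dose is correct within 12.5 µg (one
  tablet step) of the clinically determined dose; cohort accuracies are
  reported per BMI bin (≤ 26, 26–32, ≥ 32) and overall. Validating against
  the original 554-patient clinical cohort is out of scope (the data are
  not public); the protocol is exercised on synthetic cohorts where, at
  zero dose jitter, self-consistency forces accuracy 1.0.

## RTF curves and inverse estimation

Steady-state T4/T3/TSH of the *untreated* patient are tabulated over an RTF
grid (default 0–0.5, step 0.01, 50-day runs). TSH decreases and T4/T3
increase strictly, so monotone piecewise-cubic (PCHIP) interpolation gives
a well-defined inverse; a hormone triple is reconciled by least squares
normalized by each channel's span, and out-of-range observations clamp to
the grid boundary with a warning.

**Known structural tension.** With the allometric k05 update active, the
untreated steady-state T3 concentration is proportional to 1/k05_new —
T3 exits the system only through the k05 pathway, so no feedback can pin
it — and T3-vs-RTF curves therefore spread ±25–30% across BMI 18.5–35.
The published finding for these curves, however, is that BMI has
essentially no effect. The package resolves this by default-personalizing
the curves through the volumes only (k05 held at the sex reference), which
reproduces near-universal per-sex charts; residual BMI effects of a few
percent (up to ~15% at extreme BMI contrasts, from imperfect cancellation
in the TSH pool) remain. `scale_k05=True` restores the fully personalized
model. Dose-prediction modules always use full personalization. The same
mechanism widens the spread of optimized LT3 doses across BMI classes in
the combination sweep relative to the published 5–7.5 µg/day band.

## Parameter estimation

Observations are independent Gaussians around the ODE solution with
per-channel SDs; the negative log-likelihood is the usual
`n log(2π)/2 + n log σ + Σ (y−µ)²/2σ²` summed over channels. Channel σs
are profiled analytically (their MLE is the weighted RMS residual, floored
at 10⁻⁹ so noise-free data keep the likelihood finite). Point estimation
uses Nelder–Mead with three seeded multiplicative restarts (local minima
insurance); simulation failures are penalized, not raised. Percent CVs are
`100 · sqrt(diag(H⁻¹)) / |θ̂|` with H a numerical Hessian
(statsmodels `approx_hess`); non-positive-definite Hessians yield missing
values with a warning. Four high-leverage TSH observations of the
euthyroid protocol (positions 9, 13, 24, 28) can be scaled by 100 —
implemented as observation *weights* by default (unit-coherent), with
value-scaling available, since either reading is possible. `calibrate_b0`
adjusts `B0` by damped fixed-point iteration until the simulated
thyroidectomy plateau hits a chosen maximum TSH (300–1000 mU/L are
plausible assay-limited choices).

## Synthetic data

Generators are pure functions of (config, seed):

* blood-volume scatter: percent deviations uniform on [−40, 100]%, per-kg
  volumes on the fitted power law plus Gaussian noise (default 5 ml/kg,
  ~Fig-level scatter); 80 patients per sex by default;
* thyroidectomized cohorts: sex Bernoulli(½), heights normal
  (1.76/1.63 ± 0.07 m), BMI log-normal (median 26, log-sd 0.2 — invented,
  as the source cohort's distributions are unpublished); "empirical" doses
  are the package's own optimizer output plus ±1 tablet-step jitter;
* hormone time courses: model trajectories at chosen times plus truncated
  Gaussian noise.

What passing tests on these data do and do not show: they verify
self-consistency (round trips, recovery, scoring logic) under the model's
own data-generating process. They cannot show calibration against real
patients — assay error structure, absorption variability, adherence, and
covariate correlations are all absent — so the published clinical accuracy
figures are not reproduced here.

## Problem sizes and numerical choices

Tests and the acceptance script use reduced problem sizes chosen to keep
the full suite comfortably interactive while preserving the protocols: the
combination sweep runs all 18 scenarios over the full 22 × 9 grid
(~3,500 fifty-day ODE courses, a few minutes with the numba-compiled RHS);
parameter-recovery fits free two well-identified parameters on one
protocol; cohort self-consistency uses 4 patients on a reduced grid.
Tie-breaks are always toward lower doses; all optimizers are deterministic
grid searches; the only randomness anywhere is seeded NumPy generators.

## Known limitations

* The base-model constants are a validated transcription, not a verbatim
  copy of a reference source; third-decimal differences in individual rate
  constants are possible and would shift euthyroid set points by a few
  percent.
* Total hormones only; free-T4 reporting would add the binding-polynomial
  conversion at the output stage.
* No meal/fasting absorption effects, adherence gaps, TRH dynamics, or
  drug interactions; RTF is static, not progressive.
* The athyreotic TSH plateau (~940 mU/L at B0 = 450) is assay-unverifiable
  territory; `calibrate_b0` exists precisely because the plateau is a
  modeling convention.
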