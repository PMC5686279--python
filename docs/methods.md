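# Methods

This note documents the modeling assumptions, parameter conventions,
numerical choices and limitations behind `resistpkpd`. It is the package's
own account of its science; every empirical statement here is computed by the
test suite or the shipped scripts.

## Models

### Pharmacokinetics

A one-compartment oral model with first-order absorption (`ka` [1/d]) and
elimination (`ke` [1/d]); plasma concentration is `Cp = Ap / (V − D·I)` in
µg/L. The `I` term [L per (mg/kg)] encodes a dose-dependent decrease of the
apparent volume observed for gefitinib; it is zero for erlotinib. When
`I > 0` each administered dose is scaled by its *own* effective volume
`V − D·I`, and simultaneous doses are summed before the correction. A
non-positive effective volume is rejected as a parameter error, naming the
offending dose.

Dose-to-amount convention: doses are weight-normalized (mg/kg) while amounts
are in µg, so a body weight is required to make the units close. The package
uses `amount = dose × body_weight × 1000` with a default body weight of
0.025 kg (a typical study mouse); it is a `PKParameters` field and can be
overridden. Clinical schedules given in absolute mg are converted with the
configured human body weight (default 70 kg).

Multi-dose profiles are analytic superpositions of per-dose
bilinear-exponential (Bateman) terms. The degenerate case `ka = ke` makes
that expression 0/0 and is rejected on the analytic path; the ODE path
(`solve_pk_ode`, used as an independent numerical check) has no such
restriction.

Threshold conversion: a free in-vitro molar threshold is converted to a total
plasma concentration via `C_th = c·MW / fu`. For 1 µM erlotinib
(MW 393.4 g/mol, fu 0.055) this gives ≈ 7152.7 µg/L. Dimensional analysis
fixes the unit as µg/L (1 µM × 393.4 g/mol = 393.4 µg/L free), even though
the value is sometimes quoted with a per-mL label; the package carries µg/L
throughout.

### Tumor growth and drug effect

Unperturbed growth follows the two-parameter switch
`dS/dt = 2λ0λ1S/(2λ0S + λ1)`: exponential at rate `2λ0` for small tumors,
saturating at the linear rate `λ1` [mm³/d] for large ones, with equal
contributions at `S = λ1/(2λ0)` (≈ 99 mm³ at the canonical values). Drug kill
is linear in exposure (`k2·Cp·S`) and delayed through three transit
compartments with rate `k1`; the mean transit time `τ = 3/k1` is the average
time for a damaged cell to die or (in the resistance model) convert, valid
while `kSR ≪ k1`.

The resistance extension routes terminally damaged cells into a resistant
pool at rate `kSR` [1/d]; resistant cells grow with the same law scaled by a
single ratio `β` applied to both `λ0` and `λ1` (no independent resistant
linear rate is exposed).

### Drug effect on resistant cells (DER)

The simulation-only threshold effect kills resistant cells while `Cp > C_th`.
The zeroth-order form `DER = k2R·Cp` carries no cell-mass factor and would
push `R` negative; the package's default is the mass-action form
`DER = k2R·Cp·R`, dimensionally symmetric with the kill on sensitive cells.
The printed form is available as `der_form="as_printed"`, clamped so it
cannot act on an empty pool. `k2R` has no identified value (no drug effect on
resistant cells was estimable from the study data), so it is a required
configuration input whenever the DER is enabled; the shipped
regimen-comparison experiment uses `k2R = 3.15e-4` L/µg/d — the magnitude of
the erlotinib high-dose kill slope — as a documented, replaceable choice.

## Canonical parameters

`resistpkpd.params` carries the canonical population estimates: PK per
compound (erlotinib ke 7.56/d, V 0.127 L; gefitinib ke 3.87/d, V 1.40 L,
I 0.00772; ka fixed at 55/d for both), shared growth/transit parameters
(λ0 0.217/d, λ1 42.8 mm³/d, k1 1.52/d), compound-specific kill slopes with a
high-dose (100 mg/kg) covariate for erlotinib (9.21e-5 mid/low vs 3.15e-4
high; gefitinib 6.19e-4 L/µg/d), the conversion rate with a high-dose
covariate (7.4e-3 mid/low vs 1.7e-3 high [1/d]) and β = 0.869. Log-normal
inter-individual SDs accompany each parameter (0.2–0.74).

The initial tumor volume at randomization is not part of that estimate set;
the package convention is `TV0 = 100 mm³` (typical xenograft enrollment
volume), overridable everywhere.

Human PK for the hybrid clinical simulation is a configuration default
(ka 24/d, ke 0.46/d — a ~36 h half-life — V/F 232 L, 70 kg), chosen as
representative adult erlotinib kinetics. With it, 150 mg daily stays well
below `C_th` while 1050 mg pulses peak only marginally above it, matching the
qualitative regime the hybrid experiment explores.

## Estimation

Fitting is deterministic maximum likelihood, not nonlinear mixed effects:

* **PK**: proportional error (`SD = b·f`). With BLQ rows dropped, the ML
  proportional SD has a closed form and is profiled out, removing an
  ill-conditioned direction from the search. Pooled and per-subject
  ("two-stage", geometric-mean summary) modes; `ka` is fixed by default
  (sparse sampling cannot identify it). Individual PK estimates are then
  fixed as inputs to the PD fit (sequential fitting).
* **PD**: combined error (`SD = a + b·f`), naive-pooled across subjects with
  shared growth/transit (and `β`, `kSR`) parameters, compound-specific `k2`,
  and optional categorical high-dose covariate splits. Per-subject `TV0` is
  anchored at the first tumor observation (excluded from the likelihood);
  alternatively a known common `TV0` can be fixed, keeping all rows.
* **Optimizer**: bound-constrained L-BFGS-B on log-transformed parameters
  with seeded multi-start, followed by a Nelder-Mead polish (the quasi-Newton
  line search can stall on the steep error-parameter ravine, e.g. when
  noise-free data drive the residual SD to its bound). Nested fits are
  warm-started from the simpler model's optimum so the nesting inequality
  `logL(resistance) ≥ logL(base)` holds in practice.
* **AIC**: `2k − 2·logL` with `k` counting structural fixed effects only
  (5 base / 7 resistance in the two-compound no-covariate configuration,
  +1 per covariate split). Residual-error parameters are estimated but held
  common in kind across compared models, so they cancel in AIC differences;
  the counting convention is recorded on every fit.
* **BLQ**: dropped by default; optionally treated as left-censored with a
  `Φ((LOQ − f)/SD)` likelihood contribution.
* **Two-stage PD** (`two_stage_fit`): per-subject fits summarized by
  geometric means; vehicle subjects inform only the growth parameters (with
  no drug there is no flux through the transit cascade). Unlike naive
  pooling, this is consistent under log-normal heterogeneity: with the full
  canonical variability the pooled fit's λ1 is pulled toward the arithmetic
  mean of a log-normal (≈ +24% at ω = 0.65) and its k1 absorbs
  population-average delay distortion, whereas the two-stage estimate stays
  within the tested 30% band. Recovery checks therefore use naive pooling on
  homogeneous populations (where it is the ML estimator) and the two-stage
  route under full variability.

The likelihood evaluates the tumor ODE for every subject at every objective
call. To keep pooled fits tractable on one CPU, predictions come from a
compiled fixed-step RK4 kernel (numba) over a plasma-concentration table
precomputed per subject (PK is fixed during PD fitting); subjects with
identical profiles share one integration. The step (0.01 d) divides the
design's dose and observation days, so concentration kinks fall on step
boundaries; the kernel is validated against the adaptive reference solver
(LSODA, rtol 1e-8/atol 1e-10 defaults) to ≲ 1e-4 relative in the tests. The
reference solver restarts integration at dose events and at
threshold-crossing times of `Cp` (located by bisection on the analytic
profile) so it never steps across a derivative discontinuity.

## Synthetic studies

The generator emulates the xenograft study design the models assume: 7 arms
(vehicle; erlotinib and gefitinib at 5/25/100 mg/kg) × 8 animals, once-daily
oral dosing for 14 days from day 3, caliper tumor volumes on a
2–3×/week schedule over 30 days (LOQ 5 mm³; a 6 mm³ figure also circulates —
the default is 5 with an override), sparse PK sampling (1 h, 6 h, 24 h after
the first and last dose — the true sampling times are not public; this is a
documented default), log-normal IIV on all PD parameters and on ke/V, and
residual noise (proportional b = 0.15 for PK; combined a = 1 mm³,
b = 0.136 for tumor volumes, the proportional magnitude matching the
resistance-model residual estimate).

Missingness arises mechanistically: subjects are truncated after the first
observation day on which true volume exceeds a sacrifice cap, and
observations below the detection limit are flagged BLQ (negative noisy
values are floored at zero and flagged). The cap default (2200 mm³) was
calibrated once, at design time, so the default study loses ≈ 7% of planned
tumor observations (measured 5.6–9.3% over seeds), the magnitude the
emulated study reports.

What the generator does *not* emulate: caliper measurement geometry,
informative dropout beyond the volume cap, adverse-event processes,
correlated random effects, or model misspecification of any kind — passing
recovery and discrimination tests therefore demonstrates internal
consistency of estimator and generator, not fidelity to any particular
animal dataset.

Seeding: every study derives per-subject generators as
`default_rng([seed, subject_index])`, so enlarging a study never perturbs
earlier subjects' draws; truth bundles record the generating parameters per
subject for recovery assertions.

## Simulation studies

Regimen comparisons simulate n = 250 virtual subjects by default (tests use
fewer), with the *same* subject-level draws in both arms — the paired design
makes identical regimens give per-subject deltas of exactly zero and removes
between-subject variance from the contrast. Metrics: minimal tumor volume
from treatment start; time to progression; AUCE (trapezoidal tumor-burden
integral) at 30 and 60 days, with arm-wise deltas.

Time to progression is implemented as the first upward re-crossing of the
baseline volume after the trajectory has dipped below baseline. Taken
literally ("first time TV exceeds its value at treatment start") the metric
is identically ≈ 0 under any delayed drug effect, because the tumor always
grows for the first day or two before the transit cascade delivers the kill;
published uses of the metric report ~15-day values, which only the
re-crossing reading produces. Monotone (never-responding) trajectories still
progress immediately, and trajectories that never re-exceed baseline within
the horizon return `inf` (reported as censored).

Confidence intervals of the mean default to `µ ± 1.96·σ/n` — the convention
of the tables this layout mirrors — with the standard `σ/√n` form available
as `ci_formula="standard"`; the as-printed form is the narrower of the two
for n > 1.

The mouse experiment compares 100 mg/kg daily against a pulsed cycle of
420 mg/kg then 4 × 20 mg/kg (equal 500 mg/kg per 5-day cycle); the clinical
hybrid experiment compares 150 mg daily against two 1050 mg pulses followed
by five 50 mg doses per 7-day cycle, with human PK driving the
mouse-estimated tumor model. The hybrid simulation supports *relative*
regimen comparison only: tumor growth and kill rates are mouse-scale, so
absolute clinical trajectories are explicitly out of scope, and the reported
quantity is the difference in regrowth delay between arms.

## Numerical conventions

* Reference integration: LSODA, rtol 1e-8, atol 1e-10 mm³ (simulation
  studies use 1e-6/1e-8 for speed), grid augmented with dose-event and
  threshold-crossing times, states clipped at zero at tolerance level.
* Likelihood kernel: RK4, dt = 0.01 d, stability margin ≥ 2× at the stiffest
  rates reachable within the optimizer bounds; non-finite states abort the
  evaluation and the objective returns a large penalty.
* Optimizer bounds (log-space): λ0 ∈ [1e-3, 5], λ1 ∈ [1, 500] mm³/d,
  k1 ∈ [0.05, 20]/d, k2 ∈ [1e-7, 5e-3] L/µg/d, kSR ∈ [1e-6, 1]/d,
  β ∈ [0.05, 5], error a ∈ [1e-6, 100] mm³, b ∈ [1e-3, 2].
* Degenerate inputs: empty regimens are valid (vehicle); `ka = ke` rejected
  analytically; zero tumors give growth 0 and resistant fraction 0; BLQ
  baselines fall back to the LOQ when anchoring `TV0`.
* Problem sizes in the shipped tests: discrimination uses 10 + 5 seeded
  7×8-subject studies; recovery uses 5 seeds at study size, one 10×-replicated
  study, and 5 seeds for the two-stage route; population comparisons use
  4–20 virtual subjects. These sizes were chosen to keep the default test
  run fast while leaving each check's statistics meaningful; all scale up
  through the public interfaces.

## Design choices on open points

* The `C_p2` symbol appearing in the threshold-effect definition is treated
  as the same plasma concentration that drives the kill on sensitive cells;
  no second PK model exists.
* Model-comparison studies generate from — and fit — the no-covariate
  configuration (single kSR and per-compound k2), the same configuration the
  5-vs-7 parameter count refers to; generating with covariate structure
  while fitting without it measures misspecification robustness rather than
  discrimination.
* Discrimination studies run on homogeneous populations with the censored
  BLQ likelihood and known TV0. Two artifacts otherwise contaminate the AIC
  direction, both measured during development and worth knowing about when
  applying pooled fits to real data: (i) unmodeled log-normal variability in
  drug potency makes the pooled mean of a purely sensitive population look
  biphasic — partial response then regrowth — which the resistance model
  absorbs, preferring it by large AIC margins even though no resistant cells
  exist (only a random-effects likelihood, out of scope here, separates the
  two); (ii) dropping below-limit observations censors the downward noise
  at the response nadir, leaving an apparent late-treatment plateau that
  again mimics resistance — the left-censored likelihood removes that bias.
* β scales both growth phases; β = 0.869 follows the canonical estimate
  table (a rounded 0.85 also circulates in prose).
* Literal fold-over-threshold statements about continuous/pulsed mouse
  exposure cannot be reconciled with any single body-weight convention from
  the printed parameters; the package documents its convention rather than
  calibrating to those statements, and treats them as out of numerical
  scope.

## Limitations

* Estimators are naive-pooled / two-stage, not SAEM/FOCE mixed-effects:
  standard errors, random-effect estimates and Wald tests of the original
  analyses are out of scope, as are their numeric AIC values (the original
  animal data are not public).
* Naive pooling is biased under strong log-normal heterogeneity (see
  Estimation); use the two-stage route when IIV matters.
* Sigmoid-Emax exposure-response and a pre-existing resistant pool are not
  modeled (both were unidentifiable in the source setting).
* The DER magnitude `k2R` is unidentified; every DER result is conditional
  on the configured value.
* Absolute human tumor dynamics are not predicted; hybrid results are
  relative regimen contrasts under mouse growth kinetics.
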