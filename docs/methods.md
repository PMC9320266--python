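# Methods

## Scope and model

`vancomipd` implements Bayesian forecasting of vancomycin exposure and
target-driven dose optimization over a configurable panel of population-PK
models, together with a synthetic hospital-wide TDM cohort generator and an
evaluation pipeline, so the complete model-based versus rule-based dosing
comparison runs without any external data.

**Structural PK.** Linear one- or two-compartment disposition with
zero-order infusion input. A course is a list of infusion events; a
continuous infusion with rate changes is encoded as back-to-back long
infusions and a loading dose as a short infusion, so a single evaluation
path covers both administration modes. Between rate change-points the
state equation `dA/dt = K A + u` is solved exactly,
`A(t0+dt) = A_ss + e^{K dt} (A(t0) − A_ss)` with `A_ss = −K⁻¹u`, using the
analytic scalar/2×2 matrix exponential. The closed form is the production
path; a stiff ODE integration of the same schedule serves as the
independent oracle in the test suite (agreement to 1e-6 relative). The
steady-state trough of a periodic regimen is the fixed point of the
one-interval affine map (geometric-series accumulation), cross-checked
against long-run simulation.

**Individual parameters.** `θ_k,i = TV_k · Π(covariate factors) · e^{η_k}`
with covariate forms power, proportional, linear, and flag factors
(dialysis). `η ~ N(0, Ω)` log-normal. Covariates outside a model's declared
support produce a logged warning, not an error — extrapolation is an
auditable event. Time-varying creatinine/weight series are carried as
last-observation-carried-forward step functions; for a given prediction the
engine uses parameters fixed at a reference time (the informing
observation), i.e. piecewise-constant-parameter propagation *within* one
prediction is not performed. This matches routine TDM granularity, where
covariates are charted once per sampling occasion.

**Residual error and MAP objective.** `g² = a² + (b·f)²` (additive sd `a`
mg/L, proportional sd `b`). The MAP estimate minimizes
`OFV(η) = Σ_j[(y_j − f_j)²/g_j² + ln g_j²] + ηᵀΩ⁻¹η`
(L-BFGS-B from `η = 0`, bounds |η_k| ≤ 6, OFV tolerance 1e-8, five seeded
restarts as a non-convergence fallback). By default only the most recent
previous concentration informs the fit (`n_informing = 1`, configurable):
forecasting from the latest sample alone has been found adequate, and it
keeps the informing/evaluation split clean.

A property worth knowing: with a prediction-dependent variance (`b > 0`),
the `ln g²` term makes the exact-interpolation point non-stationary — the
objective is an extended-least-squares criterion that will trade a small
misfit for a smaller predicted (hence smaller-variance) concentration.
Consequently "noiseless data are reproduced exactly" holds in the
constant-variance case (`b = 0`), which is how the exact-fit limit is
tested; with `b > 0` a small systematic downward pull of order `b²` exists
even for perfect data. This is a property of the standard objective, not an
implementation artifact.

**Model selection and averaging.** Weights from the fits to the informing
concentration: OFV scheme `w_i ∝ exp(−(OFV_i − min OFV)/2)` (Akaike-weight
form), SSE scheme `w_i ∝ 1/SSE_i` with SSE floored at 1e-12 (mg/L)². MSA
predicts with the maximal-weight model (ties broken by registry order,
logged); MAA with the weighted sum. SSE uses MAP-fit predictions (a flag
could switch to population predictions; MAP is the default because the
selection criterion should reflect the individualized model actually used
downstream).

**Dose optimization.** Linearity makes every predicted concentration
affine in a prospective dose, `pred = legacy + dose · unit response`, so
targets are attained in closed form and clamped at zero with a flag when
unreachable. Intermittent: the first dose targets the trough at the end of
the next dosing interval ("as soon as possible"); the second dose is the
steady-state dose whose periodic trough equals the target. Continuous: the
first rate segment corrects over a 12 h horizon; the second rate is
`target / Σ_i w_i/CL_i` (the rate whose weighted plateau equals the
target; for one model, `target · CL`). Targets default to 15 mg/L
(intermittent trough) and 22.5 mg/L (continuous). Doses are not rounded to
a formulary grid; differences are compared as mg per 12 h, and |Δ| ≥ 125 mg
is flagged clinically relevant (boundary inclusive).

**Evaluation.** rBias/rRMSE on relative errors against the observed second
concentration; 95% t-intervals for mean (relative) bias; individual
acceptability (|error| ≤ 2 mg/L when the observed concentration is below
20 mg/L, ≤ 10% relative at ≥ 20 mg/L — the threshold conditions on the
*observed* value, which is the measurement-quality anchor); exposure
classification with inclusive therapeutic bounds 12.5–17.5 / 20–25 mg/L;
ICC fixed to the two-way absolute-agreement single-measure variant
ICC(A,1), computed from mean squares and cross-checked against an
independent implementation in the tests; Wilcoxon signed-rank (two-sided,
zero differences dropped; degenerate all-zero case reported as p = 1)
delegated to scipy. The best approach is the lowest combined rank of
|rBias| and rRMSE; the worst approach drives a sensitivity re-run of the
dose comparison.

## Synthetic cohort

The generator emulates a hospital-wide adult TDM evaluation design:

- 154 patients, 95 intermittent / 59 continuous infusion;
- independent log-normal covariate marginals calibrated to the study
  population (median [IQR]: age 63 [53; 72] y, weight 76 [64; 94] kg, serum
  creatinine 0.83 [0.64; 1.22] mg/dL; `σ = ln(q3/q1)/(2·0.6745)`), Bernoulli
  flags (66.9% male, 39% ICU, 7.5% renal replacement). No correlation
  structure is imposed (none is reported for the population emulated); a
  hook for a correlated copula is left in the config design;
- initial dosing by a weight/renal-function heuristic (15 mg/kg rounded to
  250 mg; q12/q24/q48 h by Cockcroft–Gault thresholds 60/30 mL/min;
  continuous courses: loading dose then rate set from the population
  clearance estimate), infusion durations 1 h per 1000 mg;
- five routine samples per course (intermittent troughs immediately
  pre-dose at ~daily spacing, continuous samples every 24 h), observation
  noise `y = f(1 + b ε₁) + a ε₂` with the generating model's residual
  parameters (non-positive draws redrawn above a 0.05 mg/L floor);
- a rule-based standard-TDM emulator standing in for unobservable clinician
  behaviour: proportional correction `dose · target/observed`, a ±10%
  inertia band around the target, log-normal clinician noise (sd 0.2), and
  rounding to a 250 mg dose grid (100 mg/24 h for continuous rates) within
  formulary bounds. All constants live in `CohortConfig`;
- two non-overlapping pairs of consecutive samples per patient, selected
  uniformly among admissible combinations (within-pair gap ≤ 72 h), giving
  2 pairs × 154 patients = 308 pairs and 616 analysed concentrations.

Everything is a pure function of (config, seed); datasets round-trip
byte-identically through the NONMEM-style CSV layout (ID, TIME, AMT, RATE,
DUR, DV, EVID, MDV, covariate columns, PAIR).

**What the generator does not emulate.** Real TDM data contain model
misspecification (the fitted model is never the data-generating process),
assay batch effects, charting errors, irregular sampling, interacting
co-medication and non-stationary renal function. Passing the synthetic
recovery tests therefore demonstrates self-consistency of the pipeline
(fit, weighting, prediction and dose logic are mutually correct), not
real-world predictive performance. Two consequences are visible in the
synthetic results: precision (rRMSE) reflects the full residual magnitude
on both the informing and the evaluation sample, and the mean *relative*
bias carries a small positive offset because `E[1/obs] > 1/E[obs]` when the
denominator is noisy (of order `b²`), partially offset by the
extended-least-squares pull described above. The end-to-end recovery test
asserts the replicate-level behaviour of rBias and its CI as designed; the
CI-coverage clause is sensitive to exactly this ratio-denominator offset.
The emulated standard-TDM loop also attains the therapeutic range in fewer
than half of second samples — qualitatively matching routine care, though
its exact attainment rate depends on the emulator constants, which are
design choices, not fitted quantities.

## Numerical choices

- Engine: analytic eigendecomposition of the 2×2 rate matrix; the
  near-degenerate eigenvalue limit falls back to the `dt·e^{λdt}` form.
  Concentration is continuous across event boundaries (infusions change the
  state derivative, not the state), so no left/right convention is needed.
- Optimizer: L-BFGS-B with numerical gradients; η tolerance dominated by
  `ftol = 1e-8`. Multi-start seed fixed (a date constant) so refits are
  deterministic.
- SSE floor 1e-12 (mg/L)² keeps inverse-SSE weights finite for exact fits.
- Percentages in report tables rounded to one decimal; no other rounding.
- Creatinine-clearance capping is off by default and configurable per
  model (sources differ; capping is an explicit, logged choice).
- Below-quantification observations are excluded from fits with a logged
  warning (no likelihood-based LLOQ handling).

## Problem sizes

Default test and reproduction runs use the full 154-patient design; the
end-to-end recovery study uses 20 replicates with a single-model panel
(the generating model), and the oracle suites use 100 random engine cases,
50 grid-search MAP cases and 100 dose-closure cases. The full five-approach
study over the shipped three-model panel completes in a few seconds on one
core.

## Known limitations

- The shipped panel fillers are synthetic stand-ins, not published models;
  conclusions about multi-model gains on real data require registry files
  for the published panel.
- One informing sample is the default; richer informing windows are
  supported but untested against real multi-occasion data.
- No AUC/MIC targets, loading-dose logic for new continuous courses,
  pediatric dosing, nonlinear elimination, or absorption models.
- ICC variant is fixed (A,1); other agreement indices are out of scope.
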