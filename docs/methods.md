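# Methods

## The model

`mpndyn` implements a compartmental ODE model of haematopoiesis in
myeloproliferative neoplasms (MPN). Two cell lineages — healthy
wild-type and JAK2 V617F-mutant ("malignant") — each pass through three
maturity compartments: stem cells (x0 / y0), progenitor cells (x1 / y1)
and mature blood cells (x2 / y2). Two further state variables couple the
lineages: cellular debris `a`, fed by all dying cells, and a lumped
cytokine signal `s`, produced in proportion to the debris, degraded at
rate `e_s`, and driven by an external inflammatory load `I`.

Stem cells divide at rate `alpha_0`; a division self-renews with
probability `p0 * phi(x0, y0) * s/(s_half + s)` and differentiates
otherwise. The two feedbacks on self-renewal are

- **niche crowding** `phi = 1/(1 + c_·x x0 + c_·y y0)` — competition for
  stem-cell niche space, monotone decreasing in both stem-cell counts,
  with lineage-specific inhibition coefficients; and
- **cytokine saturation** `s/(s_half + s)` — a Michaelis-Menten
  up-regulation with lineage-specific half-saturation constants
  `s_x0`, `s_y0`.

Differentiating divisions feed the next compartment through lumped
amplification factors (`A_0`, `A_1`), standing in for the many unmodelled
intermediate divisions; progenitors self-renew with a constant fraction
and die at rate `d_1`, mature cells die at rate `d_2`; stem-cell death is
neglected. The mutant lineage obeys equations of the same form with its
own parameter values (higher proliferation and self-renewal — the
fitness advantage that drives clonal takeover).

The observable is the variant allele frequency (VAF). Under the
assumption that every mutant cell is homozygous, the model's VAF
estimate is `g(x2, y2) = y2/(x2 + y2)`. That assumption is motivated by
the high baseline allele burdens of well-responding trial patients
(cohort average ≈ 0.76): inverting `V = (1 + h)/2` shows that at
VAF 0.76 at least 52% of cells must carry the mutation homozygously
even in the extreme case that all cells are mutated
(`homozygous_fraction_bound`).

Time is measured in days internally (all default rates are per day);
user-facing summaries convert to years at 365 days/year.

### Parameters

The 26 constants live in `ModelParameters` (defaults = the published
calibration; YAML round-trip via `load_parameters`/`save_parameters`).
One default deviates from the headline parameter table in its last
digit: `s_y0 = 7.14e-2` rather than the rounded `7.1e-2`, because the
published per-patient results table carries the parameter to three
figures (patients with no stem-cell response print an effective
s_y0 of 0.0714, and every fold-change product in that table reproduces
the printed effective values only with 0.0714).

## Treatment

Ruxolitinib is modelled as two dose-dependent, patient-specific effects
with response strengths in (mg/day)^-1:

    s_y0_eff = (1 + c_R * rho_sy0) * s_y0      (blunted mutant stem-cell
                                                cytokine response)
    d_y1_eff = (1 + c_R * rho_dy1) * d_y1      (increased mutant
                                                progenitor death)

with constant daily dose `c_R` (35 mg/day for the myelofibrosis-trial-like
cohort, 20 mg/day for the polycythaemia-vera-trial-like cohort). Only
relative dose changes matter — a rescaling of `c_R` is absorbed by the
inverse rescaling of the rho's. The treated system is *identical* to the
untreated right-hand side evaluated at the effective parameters
(`effective_parameters`), which the code exploits everywhere.

The printed treated stem-cell equation in the source uses a crowding
argument `phi_y(y0, y0)` inconsistent with the untreated equation's
`phi_y(x0, y0)`; this is treated as a typo and `phi_y(x0, y0)` is used
throughout (simulating the printed variant produces scenario dynamics
qualitatively incompatible with the published figure — no return of the
malignant load at all).

## Steady states

At equilibrium each stem-cell equation factors into "no cells" or the
balance `2 p0 phi s/(s_half + s) = 1` (self-renewal probability exactly
1/2). On an active branch the influx into the progenitor compartment is
then simply `A_0 alpha_0 x0`, progenitor and mature counts are linear in
the stem count, and the cytokine balance fixes the debris level
`a = (e_s s - I)/r_s`. Substituting into the debris balance leaves a
single univariate polynomial in `s` per branch:

| branch              | polynomial degree | roots |
|---------------------|-------------------|-------|
| no cells            | 2 (a·s = 0 system)| 2     |
| healthy only        | 3                 | 3     |
| malignant only      | 3                 | 3     |
| both lineages       | 4                 | 4     |

giving 12 possible steady states in total, found deterministically by
companion-matrix root finding (no multi-start, no seed). Real roots are
polished by bisection on the branch residual; feasibility means all
components real and ≥ −1e−6 × the compartment scale (then clamped to 0);
duplicates are merged at relative distance 1e−4 on log1p-transformed
states. With the default parameters 5 states are feasible: the cell-free
state (s = I/e_s), two healthy and two malignant states.

Local stability comes from the eigenvalues of the 8×8 Jacobian computed
by central finite differences with component-relative steps (an
analytically derived Jacobian, cross-checked against symbolic
differentiation in the test suite, is supplied to the ODE solvers but
the classification deliberately uses the finite-difference route as an
independent path). Eigenvalue real parts within 1e−8/day of zero are
reported "marginal" rather than classified; the slow cell-kinetic modes
of this system are of order 1e−4 to 1e−2 per day, far outside that band.
`reduced_lineage_steady_states` repeats the analysis for the 5-variable
single-lineage subsystems, where removing the absent lineage's invasion
direction stabilises the calibration healthy state.

## Simulation

The system is stiff (debris/cytokine turnover is ~1e8 per day against
cell kinetics of ~1e-3 per day) and spans ~12 decades across
components. `simulate` uses LSODA with the analytic Jacobian, relative
tolerance 1e−8 and per-component absolute tolerances of 1e−12 × the
characteristic compartment magnitudes; output is sampled at least
weekly. Basin-of-attraction runs use BDF (LSODA refuses integration
from points at or extremely near an equilibrium), and the fitting
prediction path falls back to BDF when LSODA declines a start.

Scenario runs integrate 30 untreated years from the disease-onset state
(the calibrated healthy equilibrium seeded with one mutant stem cell,
`DISEASE_ONSET_STATE`), then continue with folded parameters (default
fold 6 on the targeted parameters): scenario a touches nothing, b folds
`s_y0` only, c folds `d_y1` only, d folds both.

`time_to_return` reports the first time a quantity crosses back down to
its value at treatment start, *after* an excursion strictly above that
reference — distinguishing the overshoot-and-return of scenario b from
the monotone declines of scenario d, which return `None`.

`basin_threshold` initialises a lineage's three compartments at a
fraction f of their stable single-lineage equilibrium (debris and
cytokine at equilibrium), integrates 200 years, and classifies the
endpoint as collapsed when fewer than one cell remains in total (counts
are continuous; one cell is the natural extinction cutoff). Geometric
bisection localises the critical f to relative width 1e−3. Defaults
reproduce collapse thresholds of ≈3.05% (healthy) and ≈0.086%
(malignant) of the respective stable states.

`local_sensitivity` ranks one-at-a-time elasticities
|d log(output)/d log(parameter)| by central differences (default ±1%).
The default output is the VAF after 30 untreated years; the stable
malignant equilibrium size is the alternative. The two self-renewal
fractions p_x0 and p_y0 dominate the ranking, followed by the crowding
coefficients c_xx and c_yx, the mutant stem-cell proliferation rate and
s_x0 — the parameters that set the lineages' competitive fitness.

### A known discrepancy

In scenario b the malignant mature-cell count peaks ≈0.9 years into
treatment at ≈1.23× its pre-treatment level and re-crosses that level
3.0–3.1 years after treatment start; the source text quotes
"approximately 2 years" for this return (while its "approximately
4 years" for the VAF return matches this implementation's 4.1 years,
and the within-first-year peak matches as well). Measured from the
excursion peak rather than from treatment start the value would be
≈2.2 years. The implementation reports the treatment-start convention
and the discrepancy is left standing rather than tuned away.

## Per-patient fitting

`TreatmentResponseModel(series, params, mode)` fits `(rho_sy0, rho_dy1)`
to one patient's VAF series by bounded ordinary least squares (the
source's explicit choice over weighted variants); `mode` restricts to a
single free parameter (`sy0_only`, `dy1_only`) with the other fixed at 0.

- **Anchoring.** The state at the first measurement (t = 0) is taken
  from the untreated progression: the first point along the
  disease-onset run whose model VAF equals the first observed VAF
  (event detection on a cached dense 100-year reference solution). This
  makes the t = 0 state patient-specific yet fully reproducible; the
  first residual is ≈0 by construction.
- **Optimisation.** `scipy.optimize.least_squares` (trust-region
  reflective, bounds rho ≥ 0) from the best 3 of a screened grid of
  starts (0 plus 5 log-spaced values over [1e−3, 1e1] per free
  parameter). Components that converge numerically onto the boundary
  (< 1e−6 (mg/day)^-1 — far below any resolvable effect) are snapped to
  exactly 0 when this does not worsen the objective. A per-solve RHS
  evaluation budget guards against pathological optimizer iterates; an
  exhausted solve just abandons that start. A boundary optimum is a
  valid result, not an error.
- **Uncertainty.** `approximate_ci` linearises at the optimum:
  covariance σ̂²(JᵀJ)⁻¹ with σ̂² = SSE/(m−p) (p = number of free
  parameters) and J the finite-difference residual Jacobian. 1000
  parameter pairs are drawn from the bivariate normal, negative draws
  resampled; parameter CIs are the 2.5/97.5 percentiles of the accepted
  draws (lower bound reported as max(·, 0)), and the VAF band is the
  pointwise middle 95% of the simulated trajectories over the
  observation window, summarised by its mean width. A near-singular
  JᵀJ (condition > 1e12, the flat direction of a saturated
  Michaelis-Menten term) is flagged `unbounded_ci` and inflated rather
  than silently pseudo-inverted — such fits have effectively unbounded
  stem-cell-response CIs.
- **Cohort summary.** Mean/sd of the fold changes s_y0_eff/s_y0 and
  d_y1_eff/d_y1 excluding folds above a threshold (default 100): beyond
  a point the cytokine term is insensitive to s_y0, so the magnitude of
  an astronomically large fitted fold carries no information. RMSE
  histogram counts at ≤0.02 and ≤0.04 complete the summary.

## Synthetic cohorts

The study's patient series were digitised from trial publications and
are not redistributable, so `synthetic.generate_cohort` emulates their
statistical shape; every downstream stage is exercised against known
ground truth. Per patient:

| quantity        | distribution (defaults)                               |
|-----------------|-------------------------------------------------------|
| baseline VAF    | Normal(0.76, 0.10) truncated to (0.3, 0.98)           |
| visits          | 3–8; first at 0, rest uniform over the window, ≥28-day gaps (count capped by the window) |
| window          | uniform 0.5–4 years                                   |
| rho_sy0         | 0 with probability 5/24, else log-uniform [0.05, 5]   |
| rho_dy1         | log-uniform [0.01, 1.1]                               |
| dose            | 35 mg/day (20 for a polycythaemia-vera-trial-like cohort)             |
| noise           | additive Gaussian, sd 0.02 VAF, clipped to [0, 1]     |

The noise default sits between the two reported qPCR assay standard
deviations (0.012 and 0.035); it is homoscedastic and Gaussian, matching
the OLS error model. The supports of the response strengths span the
published non-outlier fitted ranges, and the point mass at rho_sy0 = 0
reproduces the observed fraction of patients whose VAF declines only
transiently (5 of 24).

What the generator does *not* emulate: dose titration and interruptions,
heteroscedastic or VAF-dependent assay error, patient-to-patient
variation in the 26 haematopoiesis constants, multiple mutant clones,
and informative visit schedules. Passing recovery tests therefore
demonstrate that the estimation machinery is correct and well-behaved
under the model's own assumptions — not that those assumptions hold for
any real cohort.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the study's
own scale: full 24-patient cohorts for the three-mode RMSE comparison, a
20-patient cohort for noisy recovery, 1000-draw CI sampling, 200-year
basin horizons. All randomness flows through explicit seeds
(`numpy.random.default_rng`); the steady-state enumeration and all
simulations are deterministic. The CLI fans a single global seed out to
per-stage child seeds via `numpy.random.SeedSequence` spawn keys so that
a stage rerun in isolation reproduces its in-pipeline output.

## Limitations

- The homozygosity assumption overstates the mutant cell fraction for
  heterozygous-dominant patients (typical of essential thrombocythaemia).
- Response strengths are constant in time: acquired resistance would be
  mis-read as a small rho.
- The linearised CI is approximate; coverage is checked to be in a
  plausible range on synthetic replicates, not guaranteed.
- Anchoring assumes every patient sits on the default-parameter
  untreated progression at first measurement; real patients differ in
  their pre-treatment parameters.
- Fitting each patient independently ignores cohort-level information
  (no mixed-effects pooling).
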