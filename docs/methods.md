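# Methods

## Scope

`vancauc` evaluates two limited-sampling estimators of the first-dose
vancomycin AUC against a noncompartmental reference on synthetic
two-compartment cohorts. Everything is first-dose, single-infusion:
no accumulation, no covariate modelling, no Bayesian estimation, no dose
individualization.

## Simulation model

Drug disposition is a linear two-compartment model with elimination
clearance CL (L/h) from a central volume V1 (L), a peripheral volume V2
(L) and inter-compartmental clearance Q (L/h); micro constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2. The hybrid rate constants α > β > 0
are the roots of λ² − (k10+k12+k21)λ + k10·k21 = 0. A constant-rate
infusion of duration t_eoi is handled in closed form (the bolus
bi-exponential convolved with a square pulse), so simulated
concentrations are exact; the test suite verifies them against numerical
integration of the ODE system at rtol 1e-6. The analytic full AUC is
dose/CL and is stored per subject as ground truth.

### Population sampling

Each virtual subject is drawn deterministically from
`(cohort seed, subject index)` via numpy's seed-sequence mechanism:

* body weight — adults lognormal (mean 65 kg, CV 20%); children uniform
  10–40 kg. Weight scales the per-kg dose, and (pediatric convention)
  the per-kg CL and Vd.
* CL and terminal volume Vz — independent lognormals at the cohort means
  and CVs (adult 4.62 L/h CV 31%, 39.35 L CV 23%; pediatric 0.16 L/kg/h
  CV 25%, 0.55 L/kg CV 18%). The terminal rate is then β = CL/Vz, so the
  terminal half-life is a *derived* quantity with cohort mean within a few
  percent of the 6.28 h / 2.58 h targets (asserted within 10% in tests).
  Drawing CL, Vz and t½ independently is not an option: the three are
  algebraically linked (Vz = CL·t½/ln2), and independent draws put ~45% of
  subjects in kinetically impossible territory (terminal half-life longer
  than the Vss/CL turnover time, which admits no positive V1/V2/Q split).
* alpha-phase half-life — lognormal, mean 0.5 h (adults) / 0.3 h
  (children), CV 30%: typical vancomycin distribution kinetics; the source
  summaries report no alpha-phase values, so this is a modelling choice
  and is configurable for sensitivity analyses.
* Vss — fixed fraction of Vz, default `vss_fraction = 0.90`, taken from
  the adult vancomycin population model of Goti et al. (2018), whose
  V1/V2/Q imply Vss/Vz ≈ 0.90. This single number controls how deep the
  distribution phase is; estimator bias is sensitive to it (in the
  one-compartment limit Model 2 *over*estimates by (e^{Ke·t_eoi}−1)/(Ke·t_eoi)−1,
  while deep distribution phases pull it down), so it is set once from
  the literature and not fitted.

Given (CL, Vss, α, β) the compartment split is closed-form:
CL/V1 = α + β − αβ·Vss/CL, V2 = Vss − V1, Q = αβ·V1·V2/CL, feasible iff
β < CL/Vss < α. If the requested α is unattainable the generator falls
back to V1 = 0.35·Vss, preserves β and re-derives α (with a warning);
a split that is impossible outright raises a configuration error.

### Sampling schedules and noise

Schedules are given in minutes after the *end* of the infusion (the TDM
convention) and stored in hours since infusion start. The adult design
samples at 0, 10, 20, 40, 60, 90, 120, 240 min post-infusion plus a
pre-dose zero and one mid-infusion sample (10 records); the pediatric
design at 0, 15, 30, 60, 120, 180, 240, 300 min plus the pre-dose zero
(9 records). Measured concentrations are the exact model values times
exp(ε), ε ~ N(0, σ²) with σ = sqrt(ln(1+CV²)) and assay CV 7.5% by
default — proportional lognormal error, keeping values positive, with no
additive floor. The pre-dose zero stays exactly zero.

### What the generator does not emulate

Real assay error often has an additive component near the quantitation
limit; real CL and Vd are correlated through body size and renal
function (drawn independently here, which *widens* the β distribution
relative to the reported t½ spread); sampling times in practice deviate
from nominal; and real patients are not at kinetic steady state of their
own parameters during septic shock. Passing tests therefore demonstrate
internal correctness of the estimators and statistics under a plausible
synthetic population — not clinical performance on any real cohort.

## Reference NCA

AUC(0–t_last) uses the linear-up/log-down trapezoid: logarithmic
trapezoid (C_i − C_{i+1})Δt / ln(C_i/C_{i+1}) on strictly declining
segments with positive endpoints (exact for mono-exponential decline,
verified to machine precision), linear trapezoid otherwise (rising
segments and any segment touching zero). λz is the negated OLS slope of
ln C on t over the last three samples (configurable); a non-negative
slope raises an error, and in cohort evaluation such subjects are
excluded with a log line rather than aborting the run. The reference AUC
is AUC(0–∞) = AUC(0–t_last) + C_last/λz by default. The full-dose AUC is
interpreted as AUC to infinity because both two-point models integrate
their exponential tails to infinity and because dose/CL arithmetic on
the source summary means supports it; `mode="tlast"` is available for
sensitivity. Reported reference parameters are CL = dose/AUC,
Vz = CL/λz (the Vd = Cl/Ke convention) and t½ = ln2/λz.

## Agreement statistics

Differences are estimate − reference (positive bias = overestimation).
Percent bias divides the mean difference by the grand mean of all values
of both methods, which reproduces the published summary-row arithmetic
and keeps cohorts with different AUC scales comparable. Limits of
agreement are mean ± 1.96 SD (sample SD). Lin's CCC uses the original
1/n-moment definition ρc = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²) — no
small-sample bias correction — with inference by the z-transform and
Lin's 1989 asymptotic variance; |ρc| ≤ |r| always holds and is asserted
property-wide. Pearson and OLS come from scipy.

## Grid search and window intersection

Candidate C1 times are every scheduled post-infusion time before the C2
candidates (adult C2: 240 min; pediatric C2: 240 or 300 min), giving 14
adult and 26 pediatric cells over the two models. A cell is *acceptable*
when |percent bias| is strictly below the 5% threshold. Subjects whose
(C1, C2) pair fails to decline under noise (Ke would be ≤ 0) are dropped
from that cell and counted; a cell with fewer than three usable subjects
is an error.

Cross-cohort intersection works per model and axis: each cohort
contributes the [min, max] window of its acceptable times, opened to
±∞ at an end that coincides with the extreme of that cohort's candidate
set (a cohort cannot constrain a window beyond the times it tested —
e.g. a design whose only late sample is 240 min says nothing about
300 min); the per-cohort windows are intersected and clipped to the
union grid. Per-subject (reference, estimate) pairs from all cells
inside an intersection are pooled for a single OLS/Pearson fit.

The `report` CLI verb is evaluation-with-plots rather than a separate
stage: regenerating reports from a saved grid CSV would lose the
per-subject pairs the pooled regression needs.

## Evaluation defaults and observed behaviour

Cohorts of n=100 subjects per arm are the evaluation default — large
enough that Monte-Carlo error on a cell's mean percent difference is
~1–2 points while a full two-cohort grid still runs in about a second.
The acceptance script reports, at these defaults: the pediatric Model 2
60/300 absolute percent bias, and the across-cohort minima of Lin's CCC
and Pearson's r for Model 2 at 60/240.

Two structural findings from this synthetic evaluation are worth
flagging, because they differ from what small clinical validation
studies tend to report:

* **Two-point noise amplification.** Ke divides a noisy log-concentration
  difference by the inter-sample decline. For an adult-like half-life of
  ~6 h sampled at 60 and 240 min post-infusion the decline is only
  ln(C1/C2) ≈ 0.33, while 7.5% assay noise puts an SD of ≈0.106 on that
  difference; the AUC error inflates further through C0′/Ke. The
  reference is no refuge: with sampling truncated at 240 min
  post-infusion, roughly half the adult reference AUC is the C_last/λz
  tail, and a three-point λz carries ~35% relative noise at this assay
  CV. Correlations between estimator and reference of ~0.7–0.9, and
  Bland–Altman limits spanning hundreds of mg·h/L, are the *expected*
  behaviour under these conditions, not a defect.
* **Structural pediatric overestimation.** At C1 = 60 min the
  alpha phase (t½ 0.3 h) has decayed only ~3.3 half-lives, elevating C1
  ≈6% above the terminal line and inflating Ke and C0′; meanwhile the
  pediatric reference, which has no mid-infusion sample, under-integrates
  the concave infusion rise by ~2%. Together Model 2 sits ~+6–8% above
  the reference in children irrespective of assay noise. Sensitivity runs
  at assay CV 2% (see `CohortSpec.assay_cv`) confirm the bias is
  noise-independent while the correlations climb to 0.95–0.99.

## Numerical notes and edge cases

* All times are float hours; schedule lookups match sample times within
  1e-6 h.
* Lognormal draws use mean/CV parameterization (μ = ln m − σ²/2), so
  CV = 0 reproduces the mean exactly.
* The acceptability comparison is strict (|bias| = 5.0% is rejected).
* Degenerate agreement inputs (fewer than 3 pairs, zero variance,
  non-positive AUCs) raise `ValueError` rather than returning NaNs.
* `ConcProfile` enforces strictly increasing times and non-negative
  concentrations at construction.

## Known limitations

The window-intersection rule is a heuristic for reconciling designs with
different candidate grids; other conventions (e.g. requiring every shared
grid point to be acceptable everywhere) are defensible and would report
narrower windows. The pediatric per-kg parameters are reported in
absolute units in `pk_summary.csv` (weights are known only for synthetic
subjects, not for user-supplied profiles). CCC inference assumes
approximate bivariate normality, which lognormal AUCs violate in the
tails.
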