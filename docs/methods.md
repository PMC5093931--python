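# Methods

## The model

`previnc` implements a three-state illness-death model for a single,
non-remitting disease (the motivating application is first acute
myocardial infarction, AMI). A birth cohort moves between *disease-free*
(S), *alive with disease* (C) and *dead*, under four age-specific
transition hazards, each held constant within a one-year age interval
[a, a+1):

- incidence `i(a)` — first events per disease-free person-year;
- remission `r(a)` — return to the disease-free state (zero when
  prevalence means "ever diagnosed", as for AMI);
- case fatality `f(a)` — disease-attributable death rate among the
  diseased;
- other-cause mortality `m(a)` — acting equally on both living states.

The occupancy equations are

    dS/da = −(i + m) S + r C
    dC/da =  i S − (r + f + m) C

with the two death causes independent. Point prevalence among the
living is `p(a) = C/(S+C)` and the population disease-attributable
mortality rate is `M(a) = f(a) · p(a)` per living person-year.

Because `m` multiplies both living states equally, it cancels from
`p(a)`: prevalence depends only on `(i, r, f)`. This is both a model
property (asserted in tests on randomized schedules) and the key to the
inverse solver below.

### Forward integration

Within each year the hazards are constant, so the year-on-year update
is the matrix exponential of the 4-state generator (S, C, dead-disease,
dead-other). `integrate_cohort` applies `scipy.linalg.expm` per year —
exact for the stated model, no step-size error — and a fixed-step RK4
fallback (`method="rk4"`) is provided for cross-checks; the two agree
to better than 1e-8. Inside the inverse solver, where only prevalence
matters, a hand-written closed form of the 2×2 disease submodel
(Cayley–Hamilton: `exp(A) = e^μ [cosh(q) I + sinh(q)/q (A − μI)]` with
`μ = tr(A)/2`, `q² = μ² − det(A)`, always real for non-negative rates)
gives the same update at a fraction of the cost.

Conventions fixed for reproducibility: ages are exact-age grid points;
a hazard value attaches to the half-open year starting at its grid
point; the cohort starts disease-free (`C(0)=0`) unless an initial
state is given.

## The inverse problem

The study question runs the model backwards: given a cross-section of
single-year prevalence, remission (zero), disease-attributable
mortality `M(a)` and all-cause mortality, find `i(a)` and `f(a)` such
that the forward model reproduces the inputs.

- Case fatality comes from the identity `f(a) = M(a)/p(a)` (zero where
  `p = 0`; inputs with `M > 0` but `p = 0` are rejected as infeasible).
- Incidence is recovered year by year: given the cohort state at age
  `a`, the incidence over [a, a+1) that carries prevalence to the
  target `p(a+1)` is found by Brent root-finding against the exact
  within-year closed form. Predicted end-of-year prevalence is strictly
  increasing in the incidence hazard, so the solution is unique.
- A falling prevalence target that would need negative incidence is
  floored at zero and flagged (`floored_ages`); ages with `p ≥ 0.95`
  are flagged as ill-conditioned. The final grid age has no prevalence
  target and carries the previous year's estimate.

Every solve re-integrates the full forward model with the estimated
hazards and reports residuals; `converged` means max |p residual|
≤ 1e-4 and max |M residual| ≤ 1e-5. In practice residuals are ~1e-12:
the inversion is exact up to root-finding tolerance.

Two identifiability limits are inherent, not implementation artifacts:
at the single age where prevalence is still zero, `f` is unidentifiable
(set to 0), which biases the incidence estimate there when the true
case fatality is material; and the last grid year is unconstrained.
Recovery tests therefore use truth schedules with near-zero case
fatality at onset ages and assess all but the final grid age.

### Secular-trend adjustment

The steady-state solve assumes the cross-section equals one cohort's
history. With a secular trend this is false: prevalence at age `a`
accumulated under the rates of earlier calendar years. `solve_with_trend`
models an age-constant proportional annual change: the cohort aged `a`
at the index year experienced, at age `a′`, hazards

    i(a′) · (1 + τ_i)^(−min(a − a′, H)),
    f(a′) · (1 + τ_f)^(−min(a − a′, H)),

where `i, f` are the unknown index-year schedules, `τ` the annual
changes and `H` the horizon (rates held flat further back — "the
previous H years" implies no extrapolation beyond it). The scaling is
anchored to cohort time (years before the index year at which the
cohort had each age); period-time anchoring would differ only in how
the final fractional year is treated and is not supported. Each cohort
is re-simulated from birth with its own scalings; the unknowns enter
triangularly (`i(a)` first affects the cohort aged `a+1`), so the solve
is again a sequence of scalar root-finds, O(A²) submodel steps overall.
With `τ_i = τ_f = 0` the code path reduces exactly to the steady-state
solver. Age-varying trends are deliberately unsupported in the solver
(the modelled world can have them; the estimator cannot — that
asymmetry is part of the study design). A named preset
`SENSITIVITY_TREND` ships the larger-decline variant (−5 %/yr
incidence, −4 %/yr case fatality).

The default configuration for AMI-like runs is `τ_i = −0.04`,
`τ_f = −0.01`, `H = 28`, index year 2010.

## Input smoothing

Grouped tables (`GroupedRateTable`) carry bands with `age_low`,
`age_high` (inclusive completed years; NaN/`plus` marks one open-ended
top band), `rate`, `se`, and optional counts. Band midpoints are
`(age_low + age_high + 1)/2`; an open-ended band gets `age_low + 5`
(survivorship concentrates near its lower bound).

- **Mortality** (5-year bands): natural cubic spline through (midpoint,
  log rate), evaluated at single years; beyond the outer midpoints the
  expansion continues linearly in log rate with the end slopes (avoids
  cubic blow-up at ages 0 and 95+). Zero rates are replaced by half the
  smallest positive rate before the log transform, with a logged
  warning. At least 4 bands are required. On 5-year bands generated
  from a Gompertz hazard the expansion stays within 5 % of the
  generating curve on ages 30–84 (tested).
- **Prevalence** (10-year survey bands): weighted least squares fit of
  a three-parameter logistic `P(a) = L / (1 + e^{−k(a−a0)})` with
  `0 < L ≤ 1`, `k > 0` (so the curve is a valid, monotone ever-had
  prevalence), weights `1/se²` where standard errors are positive.
  Multi-start over `a0 ∈ {50, 65, 80}` plus a data-driven start; an
  analytic jacobian; non-convergence returns the best parameters with a
  degraded-fit flag. All-zero tables pin `L` at its lower bound. The
  WLS parameter covariance (from the weighted jacobian) is exposed and
  is well calibrated when the band standard errors are true sampling
  errors.

## Uncertainty propagation

`bootstrap_incidence` is a parametric bootstrap of the survey sampling
error only: each replicate redraws every band prevalence from
`Normal(rate, se)` truncated to [0, 1] (resampled up to 100 times, then
clipped), refits the sigmoid (warm-started from the point fit) and
re-solves. Mortality and remission are passed through untouched.
Intervals are percentile intervals whose endpoints are order statistics
of the replicate values (no interpolation), so they are monotone in the
interval level. Replicates failing the forward-consistency tolerance
are excluded and counted; a run with >20 % failures is flagged.
Defaults: B = 1000 (stable 95 % endpoints; experiments in the test
suite use B = 200), one seeded generator, bit-identical output for
identical seed and configuration. The trended solve can be
bootstrapped but is off by default.

## Registry comparator

`classify_events` applies the linked-registry first-event rules: a
qualifying admission is emergency + primary disease diagnosis + length
of stay strictly greater than 1 day for someone discharged alive
(in-hospital deaths qualify regardless of stay); a death with the
disease as underlying cause is an event in its own right; records
within 30 days (inclusive, measured from the event date) of an
existing event of the same person are absorbed into it, and any death
in that window marks the event fatal; a disease-coded death 31+ days
after the last event is a new fatal event. "First" means first since
the registry start date — events before it are unobservable, so
shortening the lookback can only inflate the first-event count (left
truncation; asserted on synthetic histories). Ages are completed years
at the event date from a birth-date mapping, falling back to the death
certificate's age.

`incidence_rates` reports band rates per 100,000 with, by default, the
Poisson normal approximation `rate · (1 ± z/√n)` truncated at zero
(an exact Garwood chi-square option is available); empty bands report
rate 0 with the rule-of-three upper bound.

## The synthetic world

`simulate_event_histories` generates person-level histories with known
truth: per birth cohort (anchored to 1 January birthdays so completed
age = calendar year − birth year), competing piecewise-constant hazards
for first disease events and other-cause death, with the disease hazard
scaled by `(1 + τ)^{y − y_index}` (flat beyond the horizon). On an
event, a Bernoulli 30-day fatality draw by age: survivors get an
emergency admission (LOS ≥ 2 days) and move to the diseased state with
a recurrence hazard (default 3× the first-event hazard) and elevated
other-cause mortality (default 2× — the certificate marks the disease
as contributory on their eventual deaths); fatal cases get a death
certificate with the disease as underlying cause, a configurable
fraction reaching hospital first (exercising the 30-day merge rule).
At most one transition is simulated per person-year; with annual
hazards of order 1e-2 the missed-transition probability is of order
1e-4. Event times within a year are truncated-exponential.

The default AMI-like scenario uses Gompertz first-event hazards
calibrated so band rates rise from ~10² per 100,000 in late middle age
to >10³ in the oldest band (men: `2.82e-3 · e^{0.056(a−60)}`, zero
below 25; women about half with a slightly steeper slope), 30-day case
fatality rising logistically from 0.25 towards 0.7, Gompertz all-cause
mortality of England-like magnitude, a 1998 registry start, index year
2010, and 4,000 persons per single year of age (a desk-scale population
of ~400,000 — large enough for stable band rates, small enough for the
full study to run in tens of seconds). Exact calibration to real
English demography is out of scope.

Survey emulation (`emulate_health_survey`) allocates a sample (default
n = 8610) to 10-year bands proportional to population, draws binomial
counts at the population-weighted band prevalence, and reports binomial
standard errors; an `exact` mode returns noise-free band averages, and
an optional under-report factor mimics self-report bias. Vital
statistics (`emulate_vital_statistics`) tabulate index-year deaths per
5-year band: disease-anywhere-on-certificate and all-cause.

### What the synthetic world does and does not show

The generator reproduces the *structure* of the study design — banded
self-report prevalence, certificate-based mortality, a left-truncated
linked registry, secular decline — not England's actual rates. Passing
tests show the pipeline's internal consistency and the direction and
rough size of the steady-state bias mechanism; they do not reproduce
the study's numerical England results, whose underlying inputs are not
published. Two deliberate simplifications matter when interpreting
results: deaths of everyone who ever had the disease count towards the
disease-anywhere mortality input (so the implied case fatality is
total, not excess — the same approximation the registry data source
makes), and hospital coding noise and transfers are not modelled.

The uncertainty-calibration experiments (`coverage_world`, and the
noise-free recovery test) use a truth world whose ever-had prevalence
is exactly logistic, so the survey smoothing model is correctly
specified and coverage measures the uncertainty propagation itself.
With a non-logistic (e.g. Gompertz-accumulated) truth, the sigmoid fit
carries a shape bias of order 5–20 % at younger ages that the bootstrap
does not see — the banding/smoothing analogue of the steady-state
critique, and a known limitation of the sigmoid configuration rather
than of the uncertainty machinery.

## Comparison report

`aggregate_to_bands` converts single-year modelled incidence to band
rates by population weighting (index-year person-years; rates are
population rates, not age-standardized), with a Total row equal by
construction through either aggregation route. `build_report` joins the
measured registry table and a modelled banded table into one row per
band: rates per 100,000, both intervals, the percentage difference with
the measured value as baseline (display-rounded to integers, halves
away from zero; full precision retained), and an interval-overlap flag.
`run_study` drives the whole synthetic study end to end. Report
generation is pure: identical inputs give byte-identical tables.

## Numerical choices and parameters at a glance

| parameter | default | meaning |
|---|---|---|
| `p_tol`, `csmr_tol` | 1e-4, 1e-5 | forward-consistency convergence tolerances |
| ill-conditioning threshold | p ≥ 0.95 | flagged; incidence never negative |
| trend preset | −0.04/yr incidence, −0.01/yr case fatality, H = 28 | AMI-like decline |
| `SENSITIVITY_TREND` | −0.05/yr, −0.04/yr | larger-decline sensitivity preset |
| bootstrap B | 1000 (200 in experiments) | percentile-interval resolution |
| interval level | 0.95 | percentile interval |
| merge window | 30 days, inclusive | registry event absorption / fatality |
| open-band midpoint | lower bound + 5 y | survivorship-weighted |
| survey n | 8610 | survey-scale sample |
| persons per age | 4000 | desk-scale simulated population |
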