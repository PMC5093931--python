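# previnc

Back-calculating disease incidence from prevalence and mortality with a
three-state illness-death model — and testing, against a synthetic
person-linked registry, whether that back-calculation can be trusted.

## The problem

For many diseases no routine incidence measurement exists, while
prevalence (from health surveys) and cause-specific mortality (from
death certificates) are collected continuously. Consistency models
exploit the fact that these quantities are linked: a cohort's
prevalence at age *a* is its prevalence at *a−1* plus incident cases
minus deaths. Given prevalence, remission and disease-attributable
mortality, the age-specific incidence schedule consistent with them can
be recovered — *if* age-specific rates are static over calendar time.
For a disease in rapid decline, such as myocardial infarction (AMI),
that steady-state assumption fails: today's prevalence accumulated
under yesterday's higher incidence, and the back-calculated "current"
incidence is biased upward. `previnc` implements the full workflow —
forward model, inverse solver with and without secular-trend
adjustment, parametric-bootstrap uncertainty, and an external
comparator built from linked hospital-admission and death-certificate
records — plus a synthetic-data generator so the entire validation
study design runs end to end with known ground truth and no data
access.

## The model

Three states (disease-free *S*, diseased *C*, dead) and four
age-specific hazards, constant within one-year age intervals:
incidence *i(a)*, remission *r(a)* (zero for ever-diagnosed
prevalence), case fatality *f(a)*, other-cause mortality *m(a)*:

    dS/da = −(i + m) S + r C
    dC/da =  i S − (r + f + m) C

with prevalence *p = C/(S+C)* and population disease-attributable
mortality *M = f·p*. Death causes are independent, so *m* cancels from
prevalence. The inverse solver recovers *f = M/p* and finds *i(a)* year
by year by exact root-finding against the closed-form within-year
solution; with a trend specification (τ_i, τ_f, horizon *H*), each
cohort's history is scaled by (1+τ)^(−min(years back, H)) and the
index-year schedule is recovered instead. Uncertainty comes from a
parametric bootstrap of the survey prevalence bands through the whole
smoothing + solving pipeline. The external comparator classifies first
events from linked records (emergency admission with primary diagnosis
and >1 day stay, or disease-coded death; 30-day merge window; first
event since the registry start).

## Worked example

Run the full synthetic validation study: a male-pattern AMI world with
a hidden 4 %/year incidence decline, a survey-style prevalence sample
(n = 8610), death-certificate tables, and a linked registry with a
1998 lookback; then back-calculate incidence with and without trend
adjustment and compare with the registry:

```python
from previnc import BootstrapConfig, TrendSpec, run_study
from previnc.synthetic import default_scenario

scenario = default_scenario("men", persons_per_age=4000, seed=20)
trend = TrendSpec(incidence_trend=-0.04, case_fatality_trend=-0.01,
                  horizon=28, index_year=2010)
result = run_study(scenario, trend=trend,
                   bootstrap_config=BootstrapConfig(replicates=200, seed=21))
print(result.summary)
```

```
all, untrended:
  0-29: measured 13, modelled 16 per 100,000 -> +24 %
  30-54: measured 114, modelled 155 per 100,000 -> +36 %
  55-64: measured 292, modelled 483 per 100,000 -> +65 %
  65-74: measured 577, modelled 755 per 100,000 -> +31 %
  75-84: measured 892, modelled 1379 per 100,000 -> +55 %
  85+: measured 1474, modelled 2880 per 100,000 -> +95 %
  Total: measured 274, modelled 436 per 100,000 -> +59 %
  non-overlapping intervals: 55-64, 75-84, 85+, Total
all, trended:
  0-29: measured 13, modelled 12 per 100,000 -> -3 %
  30-54: measured 114, modelled 107 per 100,000 -> -6 %
  55-64: measured 292, modelled 309 per 100,000 -> +6 %
  65-74: measured 577, modelled 470 per 100,000 -> -19 %
  75-84: measured 892, modelled 1015 per 100,000 -> +14 %
  85+: measured 1474, modelled 2433 per 100,000 -> +65 %
  Total: measured 274, modelled 321 per 100,000 -> +17 %
  all intervals overlap
```

Reading it: the *measured* column is registry first-event incidence per
100,000 with Poisson confidence intervals; *modelled* is the
back-calculated incidence aggregated to the same bands with bootstrap
credible intervals. Under the hidden decline, the steady-state
("untrended") solve over-estimates incidence in every working-age band
(+31 % to +65 % at ages 30–74) and several intervals fail to overlap;
supplying the correct trend pulls every band down and restores interval
overlap. The generating truth is known here, so the bias is
attributable to the steady-state assumption, not the data.

A command-line interface wraps the same pipeline:

```
previnc simulate --sex men --seed 1 --out scratch/sim
previnc validate registry --admissions scratch/sim/admissions.csv \
    --deaths scratch/sim/deaths.csv --population pop.csv \
    --birth-dates scratch/sim/birth_dates.csv --year 2010 --start 1998-01-01
previnc report --sex men --seed 1 --bootstrap-replicates 200 --out scratch/report
```

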