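"""Synthetic study world: event histories, survey and vital statistics.

Everything the validation pipeline consumes is generated here with known
ground truth: a population simulated person by person under competing
piecewise-constant hazards for first disease events and other-cause
death (with a secular trend in the disease hazard), from which the
module emulates

* a person-linked admissions/death-certificate registry with a fixed
  lookback start (events before it are invisible — left truncation);
* a self-report health-survey prevalence table in 10-year age bands
  with binomial sampling error;
* death-certificate tabulations in 5-year bands (disease anywhere on
  the certificate, and all causes).

Cohorts are anchored to 1 January birthdays so a person's completed age
equals calendar year minus birth year; hazards are constant within each
(age, calendar-year) cell, and event times within a year are drawn from
the matching truncated-exponential waiting time.  At most one
transition is simulated per person-year; with annual hazards of order
10^-2 the probability of a missed second transition is of order 10^-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import GroupedRateTable

__all__ = [
    "SimulationScenario",
    "default_scenario",
    "simulate_event_histories",
    "emulate_health_survey",
    "emulate_vital_statistics",
    "make_bands",
]

log = logging.getLogger(__name__)


@dataclass
class SimulationScenario:
    """Ground-truth world for the validation exercise.

    ``incidence`` is the first-event hazard per disease-free person-year
    at the index year; during calendar year ``y`` the simulation applies
    ``incidence * (1 + incidence_trend)^{max(y - index_year, -trend_horizon)}``,
    so with a negative trend past rates are higher, flattening beyond
    the horizon.  ``age_specific_trend`` optionally replaces the scalar
    trend with a per-age annual change (the model under test cannot
    represent this; the world can).
    """

    incidence: np.ndarray
    case_fatality_30d: np.ndarray
    other_mortality: np.ndarray
    index_year: int = 2010
    registry_start_year: int = 1998
    persons_per_age: int = 4000
    incidence_trend: float = 0.0
    age_specific_trend: np.ndarray | None = None
    trend_horizon: int = 28
    recurrence_factor: float = 3.0
    excess_mortality_factor: float = 2.0
    fatal_admission_fraction: float = 0.6
    prevalence_underreport: float = 0.0
    seed: int = 0

    def __post_init__(self):
        n = len(self.incidence)
        for name in ("incidence", "case_fatality_30d", "other_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if (self.case_fatality_30d > 1).any():
            raise ValueError("case_fatality_30d is a probability")
        if self.registry_start_year > self.index_year:
            raise ValueError("registry must start on or before the index year")
        if self.incidence_trend <= -1:
            raise ValueError("incidence_trend must be > -1")

    @property
    def age_max(self) -> int:
        return len(self.incidence) - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.incidence))

    def incidence_in_year(self, year: int) -> np.ndarray:
        """Age schedule of the first-event hazard in a calendar year."""
        k = max(year - self.index_year, -self.trend_horizon)
        if self.age_specific_trend is not None:
            tau = np.asarray(self.age_specific_trend, float)
            return self.incidence * (1.0 + tau) ** k
        return self.incidence * (1.0 + self.incidence_trend) ** k


def default_scenario(sex: str = "men", **overrides) -> SimulationScenario:
    """AMI-like default world, magnitude-plausible for England-scale rates.

    The first-event hazard is Gompertz (log-linear in age) calibrated so
    that band rates rise from roughly 10^2 per 100,000 in late middle
    age to above 10^3 per 100,000 in the oldest band, with women about
    half the male hazard and a slightly steeper age slope; 30-day case
    fatality rises with age; other-cause mortality is Gompertz at
    all-cause-England-like magnitudes.
    """
    ages = np.arange(100, dtype=float)
    if sex == "men":
        inc = 2.82e-3 * np.exp(0.056 * (ages - 60.0))
    elif sex == "women":
        inc = 1.30e-3 * np.exp(0.065 * (ages - 60.0))
    else:
        raise ValueError(f"unknown sex {sex!r}")
    inc[ages < 25] = 0.0
    cf = 0.25 + 0.45 / (1.0 + np.exp(-(ages - 80.0) / 8.0))
    m = 1.8e-5 * np.exp(0.092 * ages) + 2e-4
    params = dict(
        incidence=inc,
        case_fatality_30d=cf,
        other_mortality=m,
        incidence_trend=-0.04,
    )
    params.update(overrides)
    return SimulationScenario(**params)


def _truncated_exp_frac(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Event-time fraction within the year given an event occurred."""
    u = rng.uniform(size=lam.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = -np.log1p(-u * (-np.expm1(-lam))) / lam
    return np.where(lam > 1e-12, frac, u)


class _RecordBuffer:
    def __init__(self):
        self.cols: dict[str, list] = {}

    def add(self, **arrays):
        for k, v in arrays.items():
            self.cols.setdefault(k, []).append(np.asarray(v))

    def frame(self, empty_cols) -> pd.DataFrame:
        if not self.cols:
            return pd.DataFrame({c: [] for c in empty_cols})
        return pd.DataFrame({k: np.concatenate(v) for k, v in self.cols.items()})


def _dates(year: np.ndarray, frac: np.ndarray) -> pd.Series:
    base = pd.to_datetime(pd.DataFrame({"year": year, "month": 1, "day": 1}))
    return base + pd.to_timedelta(np.floor(frac * 365.0).astype(int), unit="D")


def simulate_event_histories(scenario: SimulationScenario):
    """Simulate the linked registry world and return records plus truth.

    Returns ``(admissions, deaths, truth)`` where the record tables use
    the registry column conventions and ``truth`` is a dict with the
    index-year population, true prevalence, true index-year first-event
    hazard, realized first-event counts and birth dates for linkage.
    All simulated records since birth are returned; registry left
    truncation is applied downstream by the classifier.
    """
    rng = np.random.default_rng(scenario.seed)
    adm_buf = _RecordBuffer()
    dth_buf = _RecordBuffer()

    n_ages = scenario.age_max + 1
    pop_index = np.zeros(n_ages)         # alive at start of index year
    diseased_index = np.zeros(n_ages)    # of which ever-diseased
    first_events_index = np.zeros(n_ages)  # realized first-ever events during index year
    sus_py_index = np.zeros(n_ages)      # person-years disease-free in index year

    birth_ids: list[np.ndarray] = []
    birth_years: list[np.ndarray] = []
    next_id = 0

    for cohort_age in range(n_ages):
        birth_year = scenario.index_year - cohort_age
        N = scenario.persons_per_age
        ids = np.arange(next_id, next_id + N, dtype=np.int64)
        next_id += N
        birth_ids.append(ids)
        birth_years.append(np.full(N, birth_year))

        alive = np.ones(N, dtype=bool)
        diseased = np.zeros(N, dtype=bool)
        had_first = np.zeros(N, dtype=bool)

        for age in range(cohort_age + 1):
            year = birth_year + age
            i_y = scenario.incidence_in_year(year)[age]
            m = scenario.other_mortality[age]
            cf = scenario.case_fatality_30d[age]

            if year == scenario.index_year:
                pop_index[cohort_age] = alive.sum()
                diseased_index[cohort_age] = (alive & diseased).sum()
                sus_py_index[cohort_age] = (alive & ~diseased).sum()

            # --- disease-free persons: competing first event vs other-cause death
            sus = alive & ~diseased
            n_sus = int(sus.sum())
            if n_sus:
                lam = i_y + m
                p_event = -np.expm1(-lam) if lam > 0 else 0.0
                hit = np.zeros(N, dtype=bool)
                hit[sus] = rng.uniform(size=n_sus) < p_event
                n_hit = int(hit.sum())
                if n_hit:
                    is_ami = rng.uniform(size=n_hit) < (i_y / lam if lam > 0 else 0.0)
                    frac = _truncated_exp_frac(rng, np.full(n_hit, lam))
                    idx = np.flatnonzero(hit)
                    ami_idx = idx[is_ami]
                    oth_idx = idx[~is_ami]
                    if year == scenario.index_year and ami_idx.size:
                        first_events_index[cohort_age] += np.sum(~had_first[ami_idx])
                    had_first[ami_idx] = True
                    fatal_idx = _emit_ami_events(
                        rng, scenario, adm_buf, dth_buf, ids, ami_idx,
                        year, frac[is_ami], cf, birth_year,
                    )
                    diseased[ami_idx] = True
                    alive[fatal_idx] = False
                    if oth_idx.size:
                        _emit_plain_deaths(
                            dth_buf, ids, oth_idx, year, frac[~is_ami],
                            birth_year, ami_anywhere=False,
                        )
                        alive[oth_idx] = False

            # --- diseased survivors: recurrence vs (elevated) death
            dis = alive & diseased
            n_dis = int(dis.sum())
            if n_dis:
                rho = scenario.recurrence_factor * i_y
                mu = scenario.excess_mortality_factor * m
                lam_d = rho + mu
                p_event = -np.expm1(-lam_d) if lam_d > 0 else 0.0
                hit = np.zeros(N, dtype=bool)
                hit[dis] = rng.uniform(size=n_dis) < p_event
                n_hit = int(hit.sum())
                if n_hit:
                    is_rec = rng.uniform(size=n_hit) < (rho / lam_d if lam_d > 0 else 0.0)
                    frac = _truncated_exp_frac(rng, np.full(n_hit, lam_d))
                    idx = np.flatnonzero(hit)
                    rec_idx = idx[is_rec]
                    oth_idx = idx[~is_rec]
                    fatal_idx = _emit_ami_events(
                        rng, scenario, adm_buf, dth_buf, ids, rec_idx,
                        year, frac[is_rec], cf, birth_year,
                    )
                    alive[fatal_idx] = False
                    if oth_idx.size:
                        _emit_plain_deaths(
                            dth_buf, ids, oth_idx, year, frac[~is_rec],
                            birth_year, ami_anywhere=True,
                        )
                        alive[oth_idx] = False

    admissions = adm_buf.frame(
        ["person_id", "admission_date", "emergency", "primary_diagnosis_ami",
         "length_of_stay", "discharged_alive"]
    )
    deaths = dth_buf.frame(
        ["person_id", "death_date", "underlying_cause_ami", "ami_anywhere", "age_at_death"]
    )
    if len(admissions):
        admissions = admissions.sort_values(["person_id", "admission_date"]).reset_index(drop=True)
    if len(deaths):
        deaths = deaths.sort_values("person_id").reset_index(drop=True)

    all_ids = np.concatenate(birth_ids)
    all_by = np.concatenate(birth_years)
    birth_dates = pd.Series(
        pd.to_datetime(pd.DataFrame({"year": all_by, "month": 1, "day": 1})).values,
        index=all_ids,
    )
    ages = scenario.ages
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(pop_index > 0, diseased_index / np.maximum(pop_index, 1), 0.0)
    truth = {
        "ages": ages,
        "population": pop_index,
        "true_prevalence": prev,
        "true_incidence_hazard": scenario.incidence_in_year(scenario.index_year),
        "first_event_count": first_events_index,
        "susceptible_person_years": sus_py_index,
        "birth_dates": birth_dates,
    }
    return admissions, deaths, truth


def _emit_ami_events(rng, scenario, adm_buf, dth_buf, ids, idx, year, frac, cf, birth_year):
    """Emit admission/death records for disease events; return fatal indices."""
    if idx.size == 0:
        return np.array([], dtype=int)
    fatal = rng.uniform(size=idx.size) < cf
    day = np.floor(frac * 365.0).astype(int)

    # survivors: emergency admission, LOS >= 2 days, discharged alive
    sv = ~fatal
    if sv.any():
        los = 1 + rng.geometric(0.4, size=int(sv.sum()))
        adm_buf.add(
            person_id=ids[idx[sv]],
            admission_date=_dates(np.full(int(sv.sum()), year), frac[sv]).values,
            emergency=np.ones(int(sv.sum()), dtype=bool),
            primary_diagnosis_ami=np.ones(int(sv.sum()), dtype=bool),
            length_of_stay=los,
            discharged_alive=np.ones(int(sv.sum()), dtype=bool),
        )
    # fatal cases: death certificate with the disease as underlying cause;
    # a fraction reach hospital first and die there within the 30-day window
    if fatal.any():
        nf = int(fatal.sum())
        adm_first = rng.uniform(size=nf) < scenario.fatal_admission_fraction
        delay = rng.integers(0, 26, size=nf)  # days from admission to death
        adate = _dates(np.full(nf, year), frac[fatal])
        ddate = adate + pd.to_timedelta(np.where(adm_first, delay, 0), unit="D")
        if adm_first.any():
            na = int(adm_first.sum())
            adm_buf.add(
                person_id=ids[idx[fatal]][adm_first],
                admission_date=adate[adm_first].values,
                emergency=np.ones(na, dtype=bool),
                primary_diagnosis_ami=np.ones(na, dtype=bool),
                length_of_stay=delay[adm_first],
                discharged_alive=np.zeros(na, dtype=bool),
            )
        age_at_death = ddate.dt.year.to_numpy() - birth_year
        dth_buf.add(
            person_id=ids[idx[fatal]],
            death_date=ddate.values,
            underlying_cause_ami=np.ones(nf, dtype=bool),
            ami_anywhere=np.ones(nf, dtype=bool),
            age_at_death=age_at_death,
        )
    return idx[fatal]


def _emit_plain_deaths(dth_buf, ids, idx, year, frac, birth_year, ami_anywhere):
    n = idx.size
    ddate = _dates(np.full(n, year), frac)
    dth_buf.add(
        person_id=ids[idx],
        death_date=ddate.values,
        underlying_cause_ami=np.zeros(n, dtype=bool),
        ami_anywhere=np.full(n, bool(ami_anywhere)),
        age_at_death=np.full(n, year - birth_year),
    )


def make_bands(age_max: int, width: int, start: int = 0, open_from: int | None = None) -> pd.DataFrame:
    """Band scheme [start, start+width-1], ... with an open top band."""
    rows = []
    a = start
    top = open_from if open_from is not None else (age_max // width) * width
    while a + width - 1 < top:
        rows.append({"age_low": a, "age_high": a + width - 1})
        a += width
    rows.append({"age_low": a, "age_high": np.nan})
    return pd.DataFrame(rows)


def emulate_health_survey(
    true_prevalence: np.ndarray,
    population: np.ndarray,
    seed: int = 0,
    total_n: int = 8610,
    bands: pd.DataFrame | None = None,
    underreport: float = 0.0,
    exact: bool = False,
    ages: np.ndarray | None = None,
) -> GroupedRateTable:
    """Survey-style grouped prevalence with binomial sampling error.

    The sample of ``total_n`` persons is allocated to 10-year bands in
    proportion to the population age structure; each band's observed
    count is Binomial(n_band, band prevalence).  ``underreport``
    multiplies true prevalence by (1 - underreport) to mimic self-report
    bias.  With ``exact=True`` the band rates equal the truth band
    averages (the noise-free emulation limit) and ``se`` keeps the
    binomial formula value.
    """
    rng = np.random.default_rng(seed)
    if ages is None:
        ages = np.arange(len(true_prevalence))
    ages = np.asarray(ages)
    if bands is None:
        bands = make_bands(int(ages[-1]), 10, start=15, open_from=85)
    rows = []
    pop = np.asarray(population, float)
    p_report = np.asarray(true_prevalence, float) * (1.0 - underreport)
    total_pop = sum(
        pop[_band_mask(ages, b)].sum() for b in bands.itertuples(index=False)
    )
    for b in bands.itertuples(index=False):
        mask = _band_mask(ages, b)
        band_pop = pop[mask].sum()
        if band_pop == 0:
            log.warning("band starting at %s has no population; dropped", b.age_low)
            continue
        n_band = int(round(total_n * band_pop / total_pop))
        if n_band == 0:
            log.warning("band starting at %s drew a sample of 0; dropped", b.age_low)
            continue
        p_true = float(np.average(p_report[mask], weights=pop[mask]))
        if exact:
            p_hat = p_true
        else:
            p_hat = rng.binomial(n_band, p_true) / n_band
        se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_band))
        rows.append(
            {
                "age_low": b.age_low,
                "age_high": b.age_high,
                "rate": p_hat,
                "se": se,
                "count": round(p_hat * n_band),
                "denominator": n_band,
            }
        )
    return GroupedRateTable(pd.DataFrame(rows))


def _band_mask(ages: np.ndarray, band) -> np.ndarray:
    hi = np.inf if pd.isna(band.age_high) else band.age_high + 1.0
    return (ages >= band.age_low) & (ages < hi)


def emulate_vital_statistics(
    deaths: pd.DataFrame,
    population: np.ndarray,
    year: int,
    bands: pd.DataFrame | None = None,
    ages: np.ndarray | None = None,
) -> tuple[GroupedRateTable, GroupedRateTable]:
    """Death-certificate tabulations in 5-year bands for one year.

    Returns ``(disease_table, all_cause_table)``: deaths with the
    disease anywhere on the certificate, and all deaths, per person-year
    of the banded population.  Standard errors use the Poisson
    sqrt(n)/denominator formula (vital registration is a complete count;
    the se column is carried for interface uniformity).
    """
    if ages is None:
        ages = np.arange(len(population))
    ages = np.asarray(ages)
    if bands is None:
        bands = make_bands(int(ages[-1]), 5, start=0, open_from=90)
    d = deaths.copy()
    if len(d):
        d["death_date"] = pd.to_datetime(d["death_date"])
        d = d[d["death_date"].dt.year == year]
    pop = np.asarray(population, float)
    rows_ami, rows_all = [], []
    for b in bands.itertuples(index=False):
        mask = _band_mask(ages, b)
        denom = pop[mask].sum()
        if denom == 0:
            continue
        if len(d):
            hi = np.inf if pd.isna(b.age_high) else b.age_high + 1.0
            in_band = (d["age_at_death"] >= b.age_low) & (d["age_at_death"] < hi)
            n_all = int(in_band.sum())
            n_ami = int((in_band & d["ami_anywhere"].astype(bool)).sum())
        else:
            n_all = n_ami = 0
        for rows, n in ((rows_ami, n_ami), (rows_all, n_all)):
            rows.append(
                {
                    "age_low": b.age_low,
                    "age_high": b.age_high,
                    "rate": n / denom,
                    "se": np.sqrt(n) / denom,
                    "count": n,
                    "denominator": denom,
                }
            )
    return GroupedRateTable(pd.DataFrame(rows_ami)), GroupedRateTable(pd.DataFrame(rows_all))


def coverage_world():
    """Logistic-prevalence truth world for uncertainty-calibration runs.

    Ever-diagnosed prevalence is exactly logistic, so the survey
    smoothing model is correctly specified and nested Monte-Carlo runs
    measure the calibration of the uncertainty propagation itself rather
    than curve misspecification.  The true incidence is the unique
    hazard schedule consistent with the prevalence and mortality inputs
    (forward-verified on construction).

    Returns ``(ages, remission, csmr, all_cause, i_true, p_true,
    population, survey_bands)``.
    """
    from .solver import solve_steady_state

    ages = np.arange(30, 96)
    p_true = 0.25 / (1.0 + np.exp(-0.11 * (ages.astype(float) - 78.0)))
    f = 0.15 / (1.0 + np.exp(-(ages - 80.0) / 8.0))
    csmr = f * p_true
    mall = csmr + 1.8e-5 * np.exp(0.092 * ages) + 2e-4
    r = np.zeros(len(ages))
    truth = solve_steady_state(p_true, r, csmr, mall, ages=ages)
    if not truth.converged:
        raise RuntimeError("coverage world construction failed forward verification")
    pop = np.exp(-0.02 * (ages - 30.0))
    pop = pop / pop.sum() * 500_000.0
    bands = make_bands(95, 10, start=30, open_from=90)
    return ages, r, csmr, mall, truth.incidence, p_true, pop, bands
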