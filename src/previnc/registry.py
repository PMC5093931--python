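"""First-event classification from linked admission and death records.

The external comparator for the modelled incidence: person-linked
hospital admissions and death certificates are combined into disease
events using the rules of the linked-registry literature:

* a qualifying admission is an emergency admission with the disease as
  primary diagnosis and, for someone discharged alive, a length of stay
  of more than 1 day (strictly);
* a death with the disease as underlying cause is an event in its own
  right;
* any death within 30 days (inclusive) after an event marks that event
  fatal and, for disease-coded deaths, is absorbed into it rather than
  counted again;
* qualifying records within 30 days of an existing event of the same
  person are absorbed into it (same clinical episode);
* an event is "first" if the person has no earlier qualifying event
  since the registry start — events before the registry window are
  unobservable, so a long pre-registry history is misread as disease-free
  (left truncation).

Because the registry only reaches back to its start date, "first event"
means first event *since the registry start*; shortening the lookback
can only inflate, never deflate, the first-event count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["classify_events", "incidence_rates", "MERGE_WINDOW_DAYS"]

MERGE_WINDOW_DAYS = 30

ADMISSION_COLUMNS = (
    "person_id",
    "admission_date",
    "emergency",
    "primary_diagnosis_ami",
    "length_of_stay",
    "discharged_alive",
)
DEATH_COLUMNS = (
    "person_id",
    "death_date",
    "underlying_cause_ami",
    "ami_anywhere",
    "age_at_death",
)
EVENT_COLUMNS = (
    "person_id",
    "event_date",
    "age_at_event",
    "fatal",
    "first_event",
)


def _completed_years(event_date: pd.Timestamp, birth_date: pd.Timestamp) -> int:
    years = event_date.year - birth_date.year
    if (event_date.month, event_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


@dataclass
class ClassificationDiagnostics:
    rejected_records: pd.DataFrame
    n_admissions: int
    n_deaths: int


def classify_events(
    admissions: pd.DataFrame,
    deaths: pd.DataFrame,
    registry_start_date,
    birth_dates: pd.Series | dict | None = None,
    return_diagnostics: bool = False,
):
    """Classify disease events from linked admission and death records.

    Parameters
    ----------
    admissions, deaths:
        Record tables with the columns of :data:`ADMISSION_COLUMNS` and
        :data:`DEATH_COLUMNS`; dates anything ``pd.to_datetime`` accepts.
    registry_start_date:
        Left edge of the observation window; earlier records are dropped
        (they are what a real registry cannot see).
    birth_dates:
        Optional person_id -> birth date mapping used to compute
        ``age_at_event`` in completed years; death events fall back to
        the certificate's ``age_at_death``.

    Returns
    -------
    DataFrame of events (columns :data:`EVENT_COLUMNS`), sorted by
    person and date; with ``return_diagnostics=True`` also a
    :class:`ClassificationDiagnostics` carrying rejected records.
    """
    start = pd.Timestamp(registry_start_date)
    adm = admissions.copy()
    dth = deaths.copy()
    for df, col in ((adm, "admission_date"), (dth, "death_date")):
        df[col] = pd.to_datetime(df[col])
    adm = adm[adm["admission_date"] >= start]
    dth = dth[dth["death_date"] >= start]

    dup = dth["person_id"].duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"multiple death records for person(s) {sorted(dth.loc[dup, 'person_id'].unique())[:5]}"
        )

    death_date_by_person = dict(zip(dth["person_id"], dth["death_date"]))
    # an admission after the person's recorded death is inconsistent linkage
    adm_death = pd.to_datetime(adm["person_id"].map(death_date_by_person))
    bad = adm_death.notna() & (adm["admission_date"] > adm_death)
    rejected = adm[bad].copy()
    adm = adm[~bad]

    if birth_dates is not None:
        if isinstance(birth_dates, dict):
            birth_dates = pd.Series(birth_dates)
        birth_dates = pd.to_datetime(birth_dates)

    qual_adm = adm[
        adm["emergency"].astype(bool)
        & adm["primary_diagnosis_ami"].astype(bool)
        & (~adm["discharged_alive"].astype(bool) | (adm["length_of_stay"] > 1))
    ]

    window = pd.Timedelta(days=MERGE_WINDOW_DAYS)
    records = pd.concat(
        [
            pd.DataFrame(
                {
                    "person_id": qual_adm["person_id"],
                    "date": qual_adm["admission_date"],
                    "is_death": False,
                }
            ),
            pd.DataFrame(
                {
                    "person_id": dth.loc[dth["underlying_cause_ami"].astype(bool), "person_id"],
                    "date": dth.loc[dth["underlying_cause_ami"].astype(bool), "death_date"],
                    "is_death": True,
                }
            ),
        ],
        ignore_index=True,
    ).sort_values(["person_id", "date", "is_death"], kind="stable")

    rows = []
    for person, grp in records.groupby("person_id", sort=True):
        events: list[dict] = []
        for rec in grp.itertuples(index=False):
            if events and rec.date <= events[-1]["event_date"] + window:
                if rec.is_death:
                    events[-1]["fatal"] = True
            else:
                events.append(
                    {
                        "person_id": person,
                        "event_date": rec.date,
                        "fatal": bool(rec.is_death),
                    }
                )
        # any death (disease-coded or not) within 30 days of an event is fatal
        ddate = death_date_by_person.get(person)
        if ddate is not None and events:
            for ev in events:
                if ev["event_date"] <= ddate <= ev["event_date"] + window:
                    ev["fatal"] = True
        for j, ev in enumerate(events):
            ev["first_event"] = j == 0
        rows.extend(events)

    if rows:
        events_df = pd.DataFrame(rows)
    else:
        events_df = pd.DataFrame(columns=list(EVENT_COLUMNS)).astype(
            {"fatal": bool, "first_event": bool}
        )

    ages = np.full(len(events_df), np.nan)
    if len(events_df):
        age_at_death = dict(zip(dth["person_id"], dth["age_at_death"]))
        for idx, ev in enumerate(events_df.itertuples(index=False)):
            if birth_dates is not None and ev.person_id in birth_dates.index:
                ages[idx] = _completed_years(ev.event_date, birth_dates[ev.person_id])
            elif ev.fatal and ev.person_id in age_at_death:
                ages[idx] = age_at_death[ev.person_id]
        events_df["age_at_event"] = ages
        events_df = events_df[list(EVENT_COLUMNS)].reset_index(drop=True)

    if return_diagnostics:
        return events_df, ClassificationDiagnostics(
            rejected_records=rejected, n_admissions=len(adm), n_deaths=len(dth)
        )
    return events_df


def incidence_rates(
    events: pd.DataFrame,
    population: pd.DataFrame,
    year: int,
    ci_method: str = "normal",
    level: float = 0.95,
    per: float = 1e5,
) -> pd.DataFrame:
    """Age-banded first-event incidence rates with confidence intervals.

    Parameters
    ----------
    events:
        Event table from :func:`classify_events`; only rows with
        ``first_event`` and an event date in ``year`` are counted.
    population:
        Bands with columns ``age_low``, ``age_high`` (NaN = open-ended)
        and ``population`` (person-years at risk in ``year``).
    ci_method:
        ``"normal"`` — Poisson normal approximation on the count,
        ``rate * (1 +/- z / sqrt(n))`` truncated below at 0;
        ``"exact"`` — chi-square (Garwood) Poisson interval.
        Empty bands report rate 0 with an upper bound from the rule of
        three (n = 3).

    Returns
    -------
    DataFrame with columns age_low, age_high, count, denominator, rate,
    lo, hi (rates per ``per`` person-years).
    """
    from scipy.stats import norm

    ev = events[events["first_event"].astype(bool)].copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev = ev[ev["event_date"].dt.year == year]
    if ev["age_at_event"].isna().any():
        raise ValueError("events with unknown age cannot be assigned to a band")

    pop = population.copy()
    pop["age_high"] = pd.to_numeric(pop["age_high"], errors="coerce")
    if (pop["population"] <= 0).any():
        bad = pop.loc[pop["population"] <= 0].iloc[0]
        raise ValueError(f"non-positive population in band starting at age {bad['age_low']}")

    z = norm.ppf(0.5 + level / 2.0)
    alpha = 1.0 - level
    out = []
    assigned = np.zeros(len(ev), dtype=bool)
    ev_ages = ev["age_at_event"].to_numpy(float)
    for row in pop.itertuples(index=False):
        hi_edge = np.inf if np.isnan(row.age_high) else row.age_high + 1.0
        in_band = (ev_ages >= row.age_low) & (ev_ages < hi_edge)
        assigned |= in_band
        n = int(in_band.sum())
        denom = float(row.population)
        rate = per * n / denom
        if n > 0:
            if ci_method == "normal":
                lo = max(0.0, rate * (1.0 - z / np.sqrt(n)))
                hi = rate * (1.0 + z / np.sqrt(n))
            elif ci_method == "exact":
                lo = per * chi2.ppf(alpha / 2.0, 2 * n) / 2.0 / denom
                hi = per * chi2.ppf(1.0 - alpha / 2.0, 2 * n + 2) / 2.0 / denom
            else:
                raise ValueError(f"unknown ci_method {ci_method!r}")
        else:
            lo, hi = 0.0, per * 3.0 / denom  # rule of three
        out.append(
            {
                "age_low": row.age_low,
                "age_high": row.age_high,
                "count": n,
                "denominator": denom,
                "rate": rate,
                "lo": lo,
                "hi": hi,
            }
        )
    if not assigned.all():
        missing_age = ev_ages[~assigned][0]
        raise ValueError(f"no population band covers event age {missing_age}")
    return pd.DataFrame(out)
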