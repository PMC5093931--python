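"""Event classification rules and rate/interval arithmetic."""

import numpy as np
import pandas as pd
import pytest

from previnc import classify_events, incidence_rates

START = "1998-01-01"


def admission(person_id, date, emergency=True, primary=True, los=3, alive=True):
    return dict(
        person_id=person_id,
        admission_date=date,
        emergency=emergency,
        primary_diagnosis_ami=primary,
        length_of_stay=los,
        discharged_alive=alive,
    )


def death(person_id, date, underlying=True, anywhere=None, age=70):
    return dict(
        person_id=person_id,
        death_date=date,
        underlying_cause_ami=underlying,
        ami_anywhere=underlying if anywhere is None else anywhere,
        age_at_death=age,
    )


def classify(adms, dths, start=START, **kw):
    adm = pd.DataFrame(adms or [], columns=list(admission(0, "2000-01-01").keys()))
    dth = pd.DataFrame(dths or [], columns=list(death(0, "2000-01-01").keys()))
    return classify_events(adm, dth, start, **kw)


class TestClassifyEvents:
    def test_single_qualifying_admission_is_nonfatal_first_event(self):
        ev = classify([admission(1, "2010-03-01", los=3)], [])
        assert len(ev) == 1
        assert not ev.fatal.iloc[0]
        assert ev.first_event.iloc[0]

    def test_death_within_30_days_merges_into_admission(self):
        ev = classify(
            [admission(1, "2010-03-01")], [death(1, "2010-03-21")]
        )
        assert len(ev) == 1
        assert ev.fatal.iloc[0]

    def test_day_30_is_inside_the_merge_window(self):
        ev = classify([admission(1, "2010-03-01")], [death(1, "2010-03-31")])
        assert len(ev) == 1 and ev.fatal.iloc[0]
        ev = classify([admission(1, "2010-03-01")], [death(1, "2010-04-01")])
        assert len(ev) == 2  # day 31: separate fatal event

    def test_second_admission_years_later_is_not_first(self):
        ev = classify(
            [admission(3, "2005-06-01"), admission(3, "2010-06-01")], []
        )
        assert list(ev.first_event) == [True, False]

    def test_length_of_stay_of_one_day_does_not_qualify(self):
        ev = classify([admission(1, "2010-03-01", los=1)], [])
        assert len(ev) == 0

    def test_in_hospital_death_admission_qualifies_regardless_of_stay(self):
        # length-of-stay rule applies only to those discharged alive
        ev = classify(
            [admission(1, "2010-03-01", los=1, alive=False)],
            [death(1, "2010-03-02")],
        )
        assert len(ev) == 1 and ev.fatal.iloc[0]

    def test_non_emergency_or_secondary_diagnosis_excluded(self):
        ev = classify(
            [
                admission(1, "2010-03-01", emergency=False),
                admission(2, "2010-03-01", primary=False),
            ],
            [],
        )
        assert len(ev) == 0

    def test_standalone_disease_death_is_an_event(self):
        ev = classify([], [death(9, "2010-05-05", age=81)])
        assert len(ev) == 1
        assert ev.fatal.iloc[0] and ev.first_event.iloc[0]
        assert ev.age_at_event.iloc[0] == 81

    def test_non_disease_death_within_window_marks_event_fatal(self):
        ev = classify(
            [admission(1, "2010-03-01")],
            [death(1, "2010-03-20", underlying=False, anywhere=True)],
        )
        assert len(ev) == 1 and ev.fatal.iloc[0]

    def test_disease_death_after_31_days_is_new_fatal_event(self):
        ev = classify([admission(1, "2010-03-01")], [death(1, "2010-05-01")])
        assert len(ev) == 2
        assert list(ev.fatal) == [False, True]
        assert list(ev.first_event) == [True, False]

    def test_events_before_registry_start_invisible(self):
        ev = classify(
            [admission(3, "1995-06-01"), admission(3, "2010-06-01")], []
        )
        # the 1995 event cannot be seen: 2010 is misread as a first event
        assert len(ev) == 1 and ev.first_event.iloc[0]

    def test_shorter_lookback_never_decreases_first_event_count(self):
        rng = np.random.default_rng(7)
        adms = []
        for pid in range(300):
            n = rng.integers(1, 4)
            days = np.sort(rng.integers(0, 6000, n))
            for d in days:
                adms.append(
                    admission(pid, str(pd.Timestamp("1994-01-01") + pd.Timedelta(int(d), "D")))
                )
        ev_long = classify(adms, [], start="1994-01-01")
        ev_short = classify(adms, [], start="2002-01-01")
        year_first = lambda ev: (
            (ev.first_event) & (pd.to_datetime(ev.event_date).dt.year == 2009)
        ).sum()
        assert year_first(ev_short) >= year_first(ev_long)

    def test_record_order_invariance(self):
        recs = [
            admission(1, "2010-03-01"),
            admission(1, "2010-06-01"),
            admission(2, "2010-04-01"),
        ]
        a = classify(recs, [])
        b = classify(recs[::-1], [])
        pd.testing.assert_frame_equal(a, b)

    def test_admission_after_death_rejected_with_diagnostic(self):
        ev, diag = classify(
            [admission(1, "2010-06-01")],
            [death(1, "2010-01-01")],
            return_diagnostics=True,
        )
        assert len(diag.rejected_records) == 1
        assert len(ev) == 1  # the death still stands as an event

    def test_age_from_birth_dates_in_completed_years(self):
        bd = pd.Series({1: pd.Timestamp("1950-06-15")})
        ev = classify([admission(1, "2010-06-14")], [], birth_dates=bd)
        assert ev.age_at_event.iloc[0] == 59
        ev = classify([admission(1, "2010-06-15")], [], birth_dates=bd)
        assert ev.age_at_event.iloc[0] == 60


def pop_bands(rows):
    return pd.DataFrame(rows)


class TestIncidenceRates:
    def test_formula_at_table_scale(self):
        # 41,689 events at a rate of 162 per 100,000:
        # the normal-approximation CI is rate*(1 +/- 1.96/sqrt(n))
        n = 41689
        denom = n / 162.0 * 1e5
        ev = pd.DataFrame(
            {
                "person_id": np.arange(n),
                "event_date": "2010-06-01",
                "age_at_event": 60,
                "fatal": False,
                "first_event": True,
            }
        )
        pop = pop_bands([{"age_low": 0, "age_high": np.nan, "population": denom}])
        out = incidence_rates(ev, pop, 2010)
        assert out.rate.iloc[0] == pytest.approx(162.0)
        assert out.lo.iloc[0] == pytest.approx(162 * (1 - 1.96 / np.sqrt(n)), rel=1e-4)
        assert out.hi.iloc[0] == pytest.approx(162 * (1 + 1.96 / np.sqrt(n)), rel=1e-4)
        assert out.hi.iloc[0] - out.lo.iloc[0] == pytest.approx(2 * 1.555, abs=0.01)

    def test_hand_computed_interval(self):
        ev = pd.DataFrame(
            {
                "person_id": np.arange(100),
                "event_date": "2010-06-01",
                "age_at_event": 50,
                "fatal": False,
                "first_event": True,
            }
        )
        pop = pop_bands([{"age_low": 0, "age_high": np.nan, "population": 1_000_000}])
        out = incidence_rates(ev, pop, 2010)
        assert out.rate.iloc[0] == pytest.approx(10.0)
        assert out.lo.iloc[0] == pytest.approx(8.04, abs=0.01)
        assert out.hi.iloc[0] == pytest.approx(11.96, abs=0.01)

    def test_empty_band_uses_rule_of_three(self):
        ev = pd.DataFrame(
            {"person_id": [], "event_date": [], "age_at_event": [],
             "fatal": [], "first_event": []}
        )
        pop = pop_bands([{"age_low": 0, "age_high": 49, "population": 100000}])
        out = incidence_rates(ev, pop, 2010)
        assert out.rate.iloc[0] == 0
        assert out.lo.iloc[0] == 0
        assert out.hi.iloc[0] == pytest.approx(1e5 * 3 / 100000)

    def test_exact_interval_narrower_asymptotically_consistent(self):
        ev = pd.DataFrame(
            {
                "person_id": np.arange(400),
                "event_date": "2010-06-01",
                "age_at_event": 60,
                "fatal": False,
                "first_event": True,
            }
        )
        pop = pop_bands([{"age_low": 0, "age_high": np.nan, "population": 1e6}])
        a = incidence_rates(ev, pop, 2010, ci_method="normal")
        b = incidence_rates(ev, pop, 2010, ci_method="exact")
        assert b.lo.iloc[0] == pytest.approx(a.lo.iloc[0], rel=0.02)
        assert b.hi.iloc[0] == pytest.approx(a.hi.iloc[0], rel=0.02)

    def test_missing_population_band_rejected(self):
        ev = pd.DataFrame(
            {
                "person_id": [1],
                "event_date": ["2010-06-01"],
                "age_at_event": [95],
                "fatal": [False],
                "first_event": [True],
            }
        )
        pop = pop_bands([{"age_low": 0, "age_high": 49, "population": 1000}])
        with pytest.raises(ValueError, match="95"):
            incidence_rates(ev, pop, 2010)

    def test_band_counts_sum_to_total_first_events(self):
        rng = np.random.default_rng(11)
        ages = rng.integers(30, 90, 500)
        ev = pd.DataFrame(
            {
                "person_id": np.arange(500),
                "event_date": "2010-06-01",
                "age_at_event": ages,
                "fatal": False,
                "first_event": rng.uniform(size=500) < 0.8,
            }
        )
        pop = pop_bands(
            [{"age_low": a, "age_high": a + 29 if a < 60 else np.nan, "population": 1e5}
             for a in (30, 60)]
        )
        out = incidence_rates(ev, pop, 2010)
        assert out["count"].sum() == ev.first_event.sum()
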