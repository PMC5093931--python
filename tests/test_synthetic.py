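"""Synthetic world: event histories, survey and vital-statistics emulation."""

import numpy as np
import pandas as pd
import pytest

from previnc import (
    GroupedRateTable,
    HazardSchedule,
    SimulationScenario,
    classify_events,
    default_scenario,
    emulate_health_survey,
    emulate_vital_statistics,
    incidence_rates,
    integrate_cohort,
    simulate_event_histories,
    solve_steady_state,
)
from previnc.preprocess import expand_mortality, fit_sigmoid_prevalence
from previnc.synthetic import make_bands


def small_scenario(**overrides):
    params = dict(persons_per_age=300, seed=42)
    params.update(overrides)
    return default_scenario("men", **params)


class TestSimulateEventHistories:
    def test_zero_incidence_world_has_no_disease_records(self):
        sc = small_scenario(incidence=np.zeros(100), persons_per_age=150)
        adm, dth, truth = simulate_event_histories(sc)
        assert len(adm) == 0
        if len(dth):
            assert not dth.ami_anywhere.any()
        assert truth["first_event_count"].sum() == 0
        assert np.all(truth["true_prevalence"] == 0)

    def test_registry_estimate_matches_flat_hazard_band(self):
        # constant hazard 0.002 only at ages 60-69, no trend: the
        # registry rate in that band must sit within 3 Monte-Carlo
        # standard errors of 200 per 100,000
        inc = np.zeros(100)
        inc[60:70] = 0.002
        sc = small_scenario(
            incidence=inc, incidence_trend=0.0, persons_per_age=4000, seed=9,
            other_mortality=np.full(100, 1e-4), case_fatality_30d=np.zeros(100),
        )
        adm, dth, truth = simulate_event_histories(sc)
        events = classify_events(
            adm, dth, f"{sc.registry_start_year}-01-01", birth_dates=truth["birth_dates"]
        )
        pop = pd.DataFrame(
            [{"age_low": 60, "age_high": 69,
              "population": truth["population"][60:70].sum()}]
        )
        first_in_band = events[
            (events.first_event)
            & (pd.to_datetime(events.event_date).dt.year == sc.index_year)
            & (events.age_at_event.between(60, 69))
        ]
        out = incidence_rates(first_in_band, pop, sc.index_year)
        n = out["count"].iloc[0]
        mc_se = 200.0 / np.sqrt(max(n, 1))
        assert abs(out.rate.iloc[0] - 200.0) < 3 * mc_se

    def test_shorter_lookback_inflates_first_events(self):
        sc = small_scenario(persons_per_age=500, seed=3)
        adm, dth, truth = simulate_event_histories(sc)

        def first_events_in_index_year(start):
            ev = classify_events(adm, dth, start, birth_dates=truth["birth_dates"])
            return (
                (ev.first_event)
                & (pd.to_datetime(ev.event_date).dt.year == sc.index_year)
            ).sum()

        assert first_events_in_index_year("2005-01-01") >= first_events_in_index_year(
            "1990-01-01"
        )

    def test_trend_scaling_of_hazards(self):
        sc = small_scenario(incidence_trend=-0.04, trend_horizon=28)
        i0 = sc.incidence_in_year(sc.index_year)
        i10 = sc.incidence_in_year(sc.index_year - 10)
        np.testing.assert_allclose(i10, i0 * 0.96**-10)
        # flat beyond the horizon
        np.testing.assert_allclose(
            sc.incidence_in_year(sc.index_year - 40),
            sc.incidence_in_year(sc.index_year - 28),
        )

    def test_non_finite_hazard_rejected(self):
        inc = np.zeros(100)
        inc[50] = np.inf
        with pytest.raises(ValueError, match="finite"):
            small_scenario(incidence=inc)


class TestHealthSurvey:
    POP = np.full(100, 5000.0)

    def test_zero_prevalence_gives_zero_bands(self):
        tab = emulate_health_survey(np.zeros(100), self.POP, seed=0)
        assert np.all(tab.data.rate == 0)
        assert np.all(tab.data.se == 0)

    def test_large_sample_recovers_band_averages(self):
        ages = np.arange(100)
        p = 0.3 / (1 + np.exp(-0.1 * (ages - 70)))
        tab = emulate_health_survey(p, self.POP, seed=1, total_n=10_000_000)
        bands = make_bands(99, 10, start=15, open_from=85)
        for row, b in zip(tab.data.itertuples(index=False), bands.itertuples(index=False)):
            hi = 100 if pd.isna(b.age_high) else int(b.age_high) + 1
            truth = p[int(b.age_low):hi].mean()
            # within 4 binomial standard errors, and never worse than
            # a 0.1 % absolute deviation at this sample size
            tol = max(4 * np.sqrt(truth * (1 - truth) / row.denominator), 1e-5)
            assert abs(row.rate - truth) < tol

    def test_se_matches_binomial_formula(self):
        ages = np.arange(100)
        p = 0.2 / (1 + np.exp(-0.12 * (ages - 68)))
        tab = emulate_health_survey(p, self.POP, seed=5, total_n=8610)
        for row in tab.data.itertuples(index=False):
            expected = np.sqrt(row.rate * (1 - row.rate) / row.denominator)
            assert row.se == pytest.approx(expected, rel=1e-12)

    def test_sample_allocation_proportional_to_population(self):
        tab = emulate_health_survey(np.full(100, 0.1), self.POP, seed=2, total_n=8610)
        n_by_band = tab.data.denominator.to_numpy(float)
        # equal population per age: allocation proportional to band width
        widths = np.array([10] * 7 + [15])  # 15-24 ... 75-84, then 85+
        expected = 8610 * widths / widths.sum()
        np.testing.assert_allclose(n_by_band, expected, atol=1.0)


class TestVitalStatistics:
    def test_no_deaths_gives_zero_tables(self):
        deaths = pd.DataFrame(
            {"person_id": [], "death_date": [], "underlying_cause_ami": [],
             "ami_anywhere": [], "age_at_death": []}
        )
        ami, allc = emulate_vital_statistics(deaths, np.full(100, 1000.0), 2010)
        assert np.all(ami.data.rate == 0)
        assert np.all(allc.data.rate == 0)

    def test_all_disease_flagged_deaths_make_tables_equal(self):
        rng = np.random.default_rng(8)
        deaths = pd.DataFrame(
            {
                "person_id": np.arange(200),
                "death_date": "2010-06-01",
                "underlying_cause_ami": True,
                "ami_anywhere": True,
                "age_at_death": rng.integers(40, 99, 200),
            }
        )
        ami, allc = emulate_vital_statistics(deaths, np.full(100, 1000.0), 2010)
        np.testing.assert_allclose(ami.data.rate, allc.data.rate)

    def test_band_rates_match_analytic_hazards(self):
        # other-cause-only world: banded all-cause death rates must sit
        # within 3 MC standard errors of 1 - exp(-m) per person-year
        m = np.full(100, 0.01)
        sc = small_scenario(
            incidence=np.zeros(100), other_mortality=m, persons_per_age=2000, seed=17
        )
        adm, dth, truth = simulate_event_histories(sc)
        _, allc = emulate_vital_statistics(dth, truth["population"], sc.index_year)
        expected = -np.expm1(-0.01)
        for row in allc.data.itertuples(index=False):
            if row.denominator < 5000:
                continue
            se = np.sqrt(expected / row.denominator)
            assert abs(row.rate - expected) < 3.5 * se


class TestEndToEndRecovery:
    def test_steady_world_recovered_through_banded_pipeline(self):
        # no trend, noise-free survey/vital emulation: banding, sigmoid
        # smoothing, log-spline expansion and the steady-state solve
        # recover the true incidence within 5 % relative on ages 40-84.
        # The truth world has logistic ever-had prevalence, so this
        # measures the banding/expansion pipeline error rather than
        # sigmoid misspecification (examined separately).
        ages = np.arange(100)
        p_true = 0.22 / (1.0 + np.exp(-0.085 * (ages - 82.0)))
        f = 0.02 + 0.13 / (1.0 + np.exp(-(ages - 80.0) / 8.0))
        m = 1.8e-5 * np.exp(0.092 * ages) + 2e-4
        csmr = f * p_true
        truth_res = solve_steady_state(p_true, np.zeros(100), csmr, csmr + m, ages=ages)
        assert truth_res.converged  # i_true is forward-verified
        i_true = truth_res.incidence
        pop = integrate_cohort(truth_res.hazards).alive * 1e5

        survey = emulate_health_survey(p_true, pop, exact=True, total_n=8610)
        prev_fit, _ = fit_sigmoid_prevalence(survey, ages)
        mort_rows = []
        bands5 = make_bands(99, 5, start=0, open_from=90)
        for b in bands5.itertuples(index=False):
            hi = 100 if pd.isna(b.age_high) else int(b.age_high) + 1
            sel = slice(int(b.age_low), hi)
            mort_rows.append(
                {
                    "age_low": b.age_low,
                    "age_high": b.age_high,
                    "rate": float(np.average(csmr[sel], weights=pop[sel])),
                    "se": 0.0,
                }
            )
        csmr_fit = expand_mortality(GroupedRateTable(pd.DataFrame(mort_rows)), ages)
        res = solve_steady_state(
            np.minimum(prev_fit, 1 - 1e-9),
            np.zeros(len(ages)),
            csmr_fit,
            csmr_fit + m,
            ages=ages,
        )
        sel = (ages >= 40) & (ages <= 84)
        rel = np.abs(res.incidence[sel] - i_true[sel]) / i_true[sel]
        assert rel.max() < 0.05
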