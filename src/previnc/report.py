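"""Modelled-vs-measured comparison tables and the full study pipeline.

Produces the banded comparison the validation exercise reports: measured
registry incidence with confidence intervals, modelled incidence (with
bootstrap credible intervals where run), percentage differences with the
measured value as baseline, and interval-overlap flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, BootstrapResult, bootstrap_incidence
from .preprocess import GroupedRateTable, expand_mortality, fit_sigmoid_prevalence
from .registry import classify_events, incidence_rates
from .solver import SolverResult, TrendSpec, solve_steady_state, solve_with_trend
from .synthetic import (
    SimulationScenario,
    emulate_health_survey,
    emulate_vital_statistics,
    simulate_event_histories,
)

__all__ = [
    "percent_difference",
    "aggregate_to_bands",
    "build_report",
    "run_study",
    "StudyResult",
]

#: sentinel used when the measured baseline is zero
UNDEFINED_PCT = float("nan")


def percent_difference(modelled: float, measured: float) -> float:
    """Signed percentage difference with the measured value as baseline.

    Returns ``100 * (modelled - measured) / measured``; display rounding
    (nearest integer, half away from zero) is applied by the report
    builder, not here.
    """
    if measured <= 0:
        raise ValueError("measured baseline must be positive")
    return 100.0 * (modelled - measured) / measured


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def aggregate_to_bands(
    rates: np.ndarray,
    weights: np.ndarray,
    bands: pd.DataFrame,
    ages: np.ndarray | None = None,
    with_total: bool = True,
) -> pd.DataFrame:
    """Population-weighted band means of a single-year rate schedule.

    The overall row (age_low = NaN) is the weighted mean over all ages,
    which equals the band rates re-weighted by band population — the
    two-route consistency every banded table must satisfy.
    """
    rates = np.asarray(rates, float)
    weights = np.asarray(weights, float)
    if ages is None:
        ages = np.arange(len(rates))
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    covered = np.zeros(len(ages), dtype=bool)
    rows = []
    for b in bands.itertuples(index=False):
        hi = np.inf if pd.isna(b.age_high) else b.age_high + 1.0
        mask = (ages >= b.age_low) & (ages < hi)
        covered |= mask
        w = weights[mask]
        if w.sum() <= 0:
            raise ValueError(f"band starting at {b.age_low} has zero weight")
        rows.append(
            {
                "age_low": b.age_low,
                "age_high": b.age_high,
                "rate": float(np.average(rates[mask], weights=w)),
                "weight": float(w.sum()),
            }
        )
    if not covered.all():
        raise ValueError(f"bands do not cover age {ages[~covered][0]}")
    out = pd.DataFrame(rows)
    if with_total:
        total = float(np.average([r["rate"] for r in rows], weights=[r["weight"] for r in rows]))
        out = pd.concat(
            [out, pd.DataFrame([{"age_low": np.nan, "age_high": np.nan,
                                 "rate": total, "weight": weights.sum()}])],
            ignore_index=True,
        )
    return out


def _band_label(age_low, age_high) -> str:
    if pd.isna(age_low):
        return "Total"
    if pd.isna(age_high):
        return f"{int(age_low)}+"
    return f"{int(age_low)}-{int(age_high)}"


def build_report(
    measured: pd.DataFrame,
    modelled: pd.DataFrame,
    variant: str = "untrended",
    sex: str = "all",
) -> pd.DataFrame:
    """One comparison row per band: rates, intervals, percent difference.

    ``measured`` is a registry rate table (columns age_low, age_high,
    count, rate, lo, hi per 100,000); ``modelled`` a banded table with
    columns age_low, age_high, rate and optionally lo, hi (credible
    interval).  Band schemes must match row for row.
    """
    mism = []
    if len(measured) != len(modelled):
        raise ValueError(
            f"band schemes differ: {len(measured)} measured vs {len(modelled)} modelled bands"
        )
    for a, b in zip(measured.itertuples(index=False), modelled.itertuples(index=False)):
        same_low = (pd.isna(a.age_low) and pd.isna(b.age_low)) or a.age_low == b.age_low
        same_high = (pd.isna(a.age_high) and pd.isna(b.age_high)) or a.age_high == b.age_high
        if not (same_low and same_high):
            mism.append((_band_label(a.age_low, a.age_high), _band_label(b.age_low, b.age_high)))
    if mism:
        raise ValueError(f"band schemes differ at: {mism}")

    has_cred = {"lo", "hi"}.issubset(modelled.columns)
    rows = []
    for a, b in zip(measured.itertuples(index=False), modelled.itertuples(index=False)):
        if a.rate > 0:
            pct = percent_difference(b.rate, a.rate)
            pct_disp = round_half_away(pct)
        else:
            pct = UNDEFINED_PCT
            pct_disp = None
        overlap = None
        if has_cred and hasattr(a, "lo"):
            overlap = bool(a.lo <= b.hi and b.lo <= a.hi)
        rows.append(
            {
                "sex": sex,
                "variant": variant,
                "band": _band_label(a.age_low, a.age_high),
                "age_low": a.age_low,
                "age_high": a.age_high,
                "measured_events": getattr(a, "count", np.nan),
                "measured_rate": a.rate,
                "measured_lo": getattr(a, "lo", np.nan),
                "measured_hi": getattr(a, "hi", np.nan),
                "modelled_rate": b.rate,
                "modelled_lo": b.lo if has_cred else np.nan,
                "modelled_hi": b.hi if has_cred else np.nan,
                "percent_difference": pct,
                "percent_difference_display": pct_disp,
                "interval_overlap": overlap,
            }
        )
    return pd.DataFrame(rows)


def summarize_report(report: pd.DataFrame) -> str:
    """Plain-text summary naming bands where intervals fail to overlap."""
    lines = []
    for (sex, variant), grp in report.groupby(["sex", "variant"], sort=False):
        lines.append(f"{sex}, {variant}:")
        for row in grp.itertuples(index=False):
            disp = row.percent_difference_display
            pct = (
                "undefined (measured rate 0)"
                if pd.isna(disp)
                else f"{int(disp):+d} %"
            )
            lines.append(
                f"  {row.band}: measured {row.measured_rate:.0f}, "
                f"modelled {row.modelled_rate:.0f} per 100,000 -> {pct}"
            )
        bad = [
            row.band
            for row in grp.itertuples(index=False)
            if row.interval_overlap is False
        ]
        if bad:
            lines.append(f"  non-overlapping intervals: {', '.join(bad)}")
        else:
            lines.append("  all intervals overlap")
    return "\n".join(lines)


@dataclass
class StudyResult:
    """Everything the end-to-end synthetic validation study produces."""

    report: pd.DataFrame
    summary: str
    measured: pd.DataFrame
    untrended: SolverResult
    trended: SolverResult | None
    bootstrap: BootstrapResult | None
    truth: dict
    survey: GroupedRateTable
    age_grid: np.ndarray


REPORT_BANDS = pd.DataFrame(
    [
        {"age_low": 0, "age_high": 29},
        {"age_low": 30, "age_high": 54},
        {"age_low": 55, "age_high": 64},
        {"age_low": 65, "age_high": 74},
        {"age_low": 75, "age_high": 84},
        {"age_low": 85, "age_high": np.nan},
    ]
)


def run_study(
    scenario: SimulationScenario,
    trend: TrendSpec | None = None,
    bootstrap_config: BootstrapConfig | None = None,
    bands: pd.DataFrame = REPORT_BANDS,
    survey_seed: int | None = None,
    exact_survey: bool = False,
) -> StudyResult:
    """Run the full synthetic external-validity study for one sex.

    Simulates event histories, emulates the survey and death-certificate
    inputs, back-calculates incidence (untrended, and trended when a
    :class:`~previnc.solver.TrendSpec` is given), estimates registry
    first-event rates, and assembles the banded comparison report.
    """
    admissions, deaths, truth = simulate_event_histories(scenario)
    age_grid = scenario.ages
    population = truth["population"]

    survey = emulate_health_survey(
        truth["true_prevalence"],
        population,
        seed=scenario.seed + 1 if survey_seed is None else survey_seed,
        underreport=scenario.prevalence_underreport,
        exact=exact_survey,
    )
    ami_tab, all_tab = emulate_vital_statistics(deaths, population, scenario.index_year)

    prev, _ = fit_sigmoid_prevalence(survey, age_grid)
    prev = np.minimum(prev, 1.0 - 1e-9)
    csmr = expand_mortality(ami_tab, age_grid)
    all_cause = np.maximum(expand_mortality(all_tab, age_grid), csmr)
    remission = np.zeros_like(prev)

    untrended = solve_steady_state(prev, remission, csmr, all_cause, ages=age_grid)
    trended = (
        solve_with_trend(prev, remission, csmr, all_cause, trend, ages=age_grid)
        if trend is not None
        else None
    )
    boot = (
        bootstrap_incidence(survey, remission, csmr, all_cause, age_grid, bootstrap_config)
        if bootstrap_config is not None
        else None
    )

    events = classify_events(
        admissions,
        deaths,
        registry_start_date=f"{scenario.registry_start_year}-01-01",
        birth_dates=truth["birth_dates"],
    )
    pop_bands = bands.copy()
    pop_bands["population"] = [
        population[_band_ages(age_grid, b)].sum() for b in bands.itertuples(index=False)
    ]
    measured = incidence_rates(events, pop_bands, scenario.index_year)
    measured_tot = _with_total_measured(measured)

    per = 1e5
    mod_banded = aggregate_to_bands(untrended.incidence * per, population, bands, ages=age_grid)
    if boot is not None:
        lo_b = aggregate_to_bands(boot.lo * per, population, bands, ages=age_grid)
        hi_b = aggregate_to_bands(boot.hi * per, population, bands, ages=age_grid)
        mod_banded["lo"] = lo_b["rate"]
        mod_banded["hi"] = hi_b["rate"]
    parts = [build_report(measured_tot, mod_banded, variant="untrended", sex="all")]
    if trended is not None:
        tr_banded = aggregate_to_bands(trended.incidence * per, population, bands, ages=age_grid)
        parts.append(build_report(measured_tot, tr_banded, variant="trended", sex="all"))
    report = pd.concat(parts, ignore_index=True)
    return StudyResult(
        report=report,
        summary=summarize_report(report),
        measured=measured_tot,
        untrended=untrended,
        trended=trended,
        bootstrap=boot,
        truth=truth,
        survey=survey,
        age_grid=age_grid,
    )


def _band_ages(ages: np.ndarray, band) -> np.ndarray:
    hi = np.inf if pd.isna(band.age_high) else band.age_high + 1.0
    return (ages >= band.age_low) & (ages < hi)


def _with_total_measured(measured: pd.DataFrame) -> pd.DataFrame:
    n = measured["count"].sum()
    denom = measured["denominator"].sum()
    rate = 1e5 * n / denom
    z = 1.959963984540054
    if n > 0:
        lo = max(0.0, rate * (1 - z / np.sqrt(n)))
        hi = rate * (1 + z / np.sqrt(n))
    else:
        lo, hi = 0.0, 1e5 * 3.0 / denom
    total = pd.DataFrame(
        [{"age_low": np.nan, "age_high": np.nan, "count": n,
          "denominator": denom, "rate": rate, "lo": lo, "hi": hi}]
    )
    return pd.concat([measured, total], ignore_index=True)
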