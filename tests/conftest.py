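"""Shared fixtures: smooth disease-like truth schedules and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from previnc import HazardSchedule, TrendSpec, integrate_cohort
from previnc.hazards import disease_submodel_step


@pytest.fixture(scope="session")
def ami_like_truth():
    """Smooth heart-attack-like hazard schedules on ages 0..100.

    Incidence is Gompertz, positive everywhere (tiny at young ages);
    case fatality rises logistically from near zero, so the onset ages
    where prevalence is still ~0 carry essentially no case fatality and
    the inverse problem stays well-identified.
    """
    ages = np.arange(101)
    i = 2.82e-3 * np.exp(0.056 * (ages - 60.0))
    f = 0.15 / (1.0 + np.exp(-(ages - 80.0) / 8.0))
    m = 1.8e-5 * np.exp(0.092 * ages) + 2e-4
    return ages, i, f, m


@pytest.fixture(scope="session")
def ami_like_cross_section(ami_like_truth):
    """Steady-state cross-section (p, csmr, all-cause) from the truth."""
    ages, i, f, m = ami_like_truth
    hz = HazardSchedule(
        ages=ages, incidence=i, remission=0.0, case_fatality=f, other_mortality=m
    )
    traj = integrate_cohort(hz)
    csmr = f * traj.prevalence
    return ages, traj.prevalence, csmr, csmr + m


def trended_cross_section(ages, i_index, f_index, trend: TrendSpec):
    """Index-year prevalence when each cohort lived through scaled hazards.

    Oracle construction used by solver tests: cohort aged ``a`` at the
    index year experienced, at age ``j``, incidence
    ``i_index[j] * (1+tau_i)^{-min(a-j, H)}`` (likewise case fatality);
    the cohort is integrated through the 2x2 disease submodel year by
    year.  Remission is zero.
    """
    n = len(ages)
    p = np.zeros(n)
    for a in range(n):
        s, c = 1.0, 0.0
        for j in range(a):
            back = a - j
            gi = float(trend.incidence_scale(back))
            gf = float(trend.case_fatality_scale(back))
            s, c = disease_submodel_step(s, c, i_index[j] * gi, 0.0, f_index[j] * gf)
        p[a] = c / (s + c)
    return p
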