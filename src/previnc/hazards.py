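"""Three-state illness-death model with piecewise-constant hazards.

The model tracks a birth cohort through three states -- disease-free
("susceptible"), alive with the disease, and dead -- under four
age-specific transition hazards: incidence ``i``, remission ``r``,
case fatality ``f`` (mortality from the disease, acting on the diseased
only) and other-cause mortality ``m`` (acting equally on both living
states).  All hazards are per person-year and are held constant within
each one-year age interval ``[a, a+1)``; the two causes of death are
independent, so other-cause survival factors out of prevalence.

Within each year the occupancy equations

    dS/da = -(i + m) S + r C
    dC/da =  i S - (r + f + m) C

form a linear system with constant coefficients, so the year-on-year
update is a matrix exponential and is computed in closed form (no
step-size error).  A fixed-step Runge-Kutta fallback is provided for
cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "HazardSchedule",
    "StateTrajectory",
    "integrate_cohort",
    "csmr_from_trajectory",
]


def _as_rate_array(x, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} is not finite at age index {bad}")
    return arr


@dataclass(frozen=True)
class HazardSchedule:
    """Age-indexed transition hazards on a single-year grid.

    ``ages`` are exact-age grid points; each hazard value applies to the
    half-open year ``[a, a+1)`` starting at the grid point.
    """

    ages: np.ndarray
    incidence: np.ndarray
    remission: np.ndarray
    case_fatality: np.ndarray
    other_mortality: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        if ages.ndim != 1 or len(ages) < 2:
            raise ValueError("age grid must be a 1-D array with at least two ages")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("age grid must be consecutive single years")
        object.__setattr__(self, "ages", ages)
        n = len(ages)
        for name in ("incidence", "remission", "case_fatality", "other_mortality"):
            arr = _as_rate_array(getattr(self, name), n, name)
            neg = np.flatnonzero(arr < 0)
            if neg.size:
                a = ages[neg[0]]
                raise ValueError(f"negative {name} rate at age {a}: {arr[neg[0]]!r}")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.ages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "i": self.incidence,
                "r": self.remission,
                "f": self.case_fatality,
                "m": self.other_mortality,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HazardSchedule":
        return cls(
            ages=df["age"].to_numpy(),
            incidence=df["i"].to_numpy(float),
            remission=df["r"].to_numpy(float),
            case_fatality=df["f"].to_numpy(float),
            other_mortality=df["m"].to_numpy(float),
        )


@dataclass(frozen=True)
class StateTrajectory:
    """Cohort state occupancy at exact grid ages.

    ``S`` and ``C`` are proportions of the birth cohort alive without and
    with the disease; ``dead_disease`` and ``dead_other`` accumulate the
    two death causes.  ``prevalence`` is ``C/(S+C)`` among the living and
    ``csmr`` is the disease-attributable death rate per living
    person-year, ``f * prevalence``.
    """

    ages: np.ndarray
    S: np.ndarray
    C: np.ndarray
    dead_disease: np.ndarray
    dead_other: np.ndarray
    prevalence: np.ndarray = field(init=False)

    def __post_init__(self):
        alive = self.S + self.C
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(alive > 0, self.C / alive, 0.0)
        object.__setattr__(self, "prevalence", p)

    @property
    def alive(self) -> np.ndarray:
        return self.S + self.C

    def to_frame(self, hazards: HazardSchedule | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"age": self.ages, "S": self.S, "C": self.C, "p": self.prevalence}
        )
        if hazards is not None:
            df["M"] = csmr_from_trajectory(self, hazards)
            for col, arr in zip(
                ("i", "r", "f", "m"),
                (
                    hazards.incidence,
                    hazards.remission,
                    hazards.case_fatality,
                    hazards.other_mortality,
                ),
            ):
                df[col] = arr
        return df


def _year_step_matrix(i: float, r: float, f: float, m: float) -> np.ndarray:
    """Exact one-year transition matrix for states (S, C, D_dis, D_oth)."""
    gen = np.array(
        [
            [-(i + m), r, 0.0, 0.0],
            [i, -(r + f + m), 0.0, 0.0],
            [0.0, f, 0.0, 0.0],
            [m, m, 0.0, 0.0],
        ]
    )
    return expm(gen)


def disease_submodel_step(
    s: float, c: float, i: float, r: float, f: float, dt: float = 1.0
) -> tuple[float, float]:
    """Advance (S~, C~) one interval under the 2x2 disease submodel.

    Other-cause mortality is omitted: it multiplies both states by the
    same survival factor and therefore cancels from prevalence.  The
    update is the closed-form matrix exponential of
    ``[[-i, r], [i, -(r+f)]]`` obtained from the Cayley-Hamilton
    identity, valid for all non-negative rates (the eigenvalues of this
    generator are always real).
    """
    mu = -0.5 * (i + r + f)
    # det = i*f; discriminant mu^2 - det >= 0 for non-negative rates
    q2 = mu * mu - i * f
    q = math.sqrt(q2) if q2 > 0.0 else 0.0
    qt = q * dt
    ch = math.cosh(qt)
    shc = math.sinh(qt) / qt if qt > 1e-8 else 1.0 + qt * qt / 6.0
    e = math.exp(mu * dt)
    # B = A - mu*I
    b11 = -i - mu
    b22 = -(r + f) - mu
    s1 = e * (ch * s + shc * dt * (b11 * s + r * c))
    c1 = e * (ch * c + shc * dt * (i * s + b22 * c))
    return s1, c1


def integrate_cohort(
    hazards: HazardSchedule,
    initial_state: tuple[float, float] = (1.0, 0.0),
    method: str = "closed_form",
    substeps: int = 64,
) -> StateTrajectory:
    """Solve the occupancy equations over the age grid.

    Parameters
    ----------
    hazards:
        Piecewise-constant transition hazards; the value at the last grid
        age describes the year beyond the grid and does not affect the
        returned states.
    initial_state:
        ``(S0, C0)`` at the first grid age; must sum to 1.  The default
        starts the cohort disease-free.
    method:
        ``"closed_form"`` (exact per-year matrix exponential, default) or
        ``"rk4"`` (fixed-step Runge-Kutta with ``substeps`` per year, for
        cross-checks).
    """
    s0, c0 = float(initial_state[0]), float(initial_state[1])
    if s0 < 0 or c0 < 0 or abs(s0 + c0 - 1.0) > 1e-12:
        raise ValueError(
            f"initial state must be non-negative and sum to 1, got {initial_state!r}"
        )
    n = len(hazards)
    S = np.empty(n)
    C = np.empty(n)
    Dd = np.empty(n)
    Do = np.empty(n)
    x = np.array([s0, c0, 0.0, 0.0])
    S[0], C[0], Dd[0], Do[0] = x
    for k in range(n - 1):
        rates = (
            hazards.incidence[k],
            hazards.remission[k],
            hazards.case_fatality[k],
            hazards.other_mortality[k],
        )
        if method == "closed_form":
            x = _year_step_matrix(*rates) @ x
        elif method == "rk4":
            x = _rk4_year(x, rates, substeps)
        else:
            raise ValueError(f"unknown method {method!r}")
        S[k + 1], C[k + 1], Dd[k + 1], Do[k + 1] = x
    return StateTrajectory(ages=hazards.ages.copy(), S=S, C=C, dead_disease=Dd, dead_other=Do)


def _rk4_year(x: np.ndarray, rates: tuple[float, float, float, float], substeps: int) -> np.ndarray:
    i, r, f, m = rates
    gen = np.array(
        [
            [-(i + m), r, 0.0, 0.0],
            [i, -(r + f + m), 0.0, 0.0],
            [0.0, f, 0.0, 0.0],
            [m, m, 0.0, 0.0],
        ]
    )
    h = 1.0 / substeps
    for _ in range(substeps):
        k1 = gen @ x
        k2 = gen @ (x + 0.5 * h * k1)
        k3 = gen @ (x + 0.5 * h * k2)
        k4 = gen @ (x + h * k3)
        x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return x


def csmr_from_trajectory(traj: StateTrajectory, hazards: HazardSchedule) -> np.ndarray:
    """Disease-attributable death rate per living person-year, M = f * p."""
    if len(traj.ages) != len(hazards):
        raise ValueError(
            f"trajectory has {len(traj.ages)} ages but hazards have {len(hazards)}"
        )
    return hazards.case_fatality * traj.prevalence
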