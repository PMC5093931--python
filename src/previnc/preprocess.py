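"""Smoothing of grouped rate tables into single-year-of-age curves.

Survey prevalence arrives in 10-year age bands and vital-statistics
mortality in 5-year bands; the consistency model needs smooth
single-year inputs.  Mortality is expanded with a natural cubic spline
through (band midpoint, log rate) — log-linear extrapolation beyond the
outer midpoints — and ever-diagnosed prevalence is fitted with a
three-parameter logistic, the canonical "sigmoid" for a cumulative
quantity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

__all__ = [
    "GroupedRateTable",
    "SigmoidFit",
    "expand_mortality",
    "fit_sigmoid_prevalence",
    "sigmoid",
]

log = logging.getLogger(__name__)


@dataclass
class GroupedRateTable:
    """Age-band rates with sampling uncertainty.

    Wraps a DataFrame with columns ``age_low``, ``age_high`` (NaN for an
    open-ended top band), ``rate``, ``se`` and optionally ``count`` and
    ``denominator``.  ``age_high`` is inclusive in completed years, so a
    band [55, 64] covers exact ages [55, 65).
    """

    data: pd.DataFrame

    REQUIRED = ("age_low", "age_high", "rate", "se")

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"grouped rate table is missing column {col!r}")
        df["age_low"] = df["age_low"].astype(float)
        df["age_high"] = pd.to_numeric(df["age_high"], errors="coerce")
        open_mask = df["age_high"].isna()
        if open_mask.sum() > 1:
            raise ValueError("at most one open-ended top band is allowed")
        if open_mask.any() and not open_mask.iloc[-1]:
            raise ValueError("the open-ended band must be the top band")
        if (df["rate"] < 0).any():
            raise ValueError("rates must be non-negative")
        if (df["se"] < 0).any():
            raise ValueError("standard errors must be non-negative")
        lows = df["age_low"].to_numpy()
        highs = df["age_high"].to_numpy()
        if not np.all(np.diff(lows) > 0):
            raise ValueError("bands must be ascending in age_low")
        for k in range(len(df)):
            if not np.isnan(highs[k]):
                if highs[k] < lows[k]:
                    raise ValueError("age_high must be >= age_low")
                if k + 1 < len(df) and highs[k] >= lows[k + 1]:
                    raise ValueError("bands must not overlap")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def midpoints(self, open_band_offset: float = 5.0) -> np.ndarray:
        """Band midpoints treating ages as completed years.

        A closed band [a_low, a_high] has midpoint (a_low + a_high + 1)/2;
        an open-ended band gets a_low + ``open_band_offset`` because
        survivorship concentrates near the lower bound.
        """
        lows = self.data["age_low"].to_numpy()
        highs = self.data["age_high"].to_numpy()
        mids = (lows + highs + 1.0) / 2.0
        mids = np.where(np.isnan(highs), lows + open_band_offset, mids)
        return mids

    def band_of(self, age: float) -> int:
        """Index of the band containing an exact age, or -1."""
        lows = self.data["age_low"].to_numpy()
        highs = self.data["age_high"].to_numpy()
        for k in range(len(lows)):
            hi = np.inf if np.isnan(highs[k]) else highs[k] + 1.0
            if lows[k] <= age < hi:
                return k
        return -1

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["age_high"] = out["age_high"].map(
            lambda v: "plus" if pd.isna(v) else f"{v:g}"
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupedRateTable":
        df = pd.read_csv(path)
        df["age_high"] = pd.to_numeric(
            df["age_high"].replace({"plus": np.nan, "": np.nan}), errors="coerce"
        )
        return cls(df)


def expand_mortality(
    table: GroupedRateTable,
    age_grid: np.ndarray,
    open_band_offset: float = 5.0,
) -> np.ndarray:
    """Expand banded mortality to single years of age.

    A natural cubic spline interpolates (band midpoint, log rate); beyond
    the outer midpoints the expansion continues linearly in log rate with
    the end slopes.  Zero rates are replaced by half the smallest
    positive rate in the table before taking logs (logged).
    """
    mids = table.midpoints(open_band_offset)
    rates = table.data["rate"].to_numpy(float).copy()
    if len(mids) < 4:
        raise ValueError(
            f"need at least 4 bands for a cubic spline, got {len(mids)}"
        )
    if (rates < 0).any():
        raise ValueError("mortality rates must be non-negative")
    zeros = rates == 0
    if zeros.any():
        positive = rates[~zeros]
        if positive.size == 0:
            raise ValueError("all rates are zero; log-spline expansion undefined")
        fill = positive.min() / 2.0
        log.warning(
            "replacing %d zero rate(s) with half the smallest positive rate (%g)",
            int(zeros.sum()),
            fill,
        )
        rates[zeros] = fill
    spline = CubicSpline(mids, np.log(rates), bc_type="natural")
    ages = np.asarray(age_grid, dtype=float)
    out = spline(np.clip(ages, mids[0], mids[-1]))
    # linear continuation in log rate outside the outer midpoints
    lo, hi = mids[0], mids[-1]
    slope_lo = spline(lo, 1)
    slope_hi = spline(hi, 1)
    below = ages < lo
    above = ages > hi
    out[below] = spline(lo) + slope_lo * (ages[below] - lo)
    out[above] = spline(hi) + slope_hi * (ages[above] - hi)
    return np.exp(out)


def sigmoid(a: np.ndarray, L: float, k: float, a0: float) -> np.ndarray:
    """Three-parameter logistic L / (1 + exp(-k (a - a0)))."""
    return L / (1.0 + np.exp(-k * (np.asarray(a, float) - a0)))


@dataclass(frozen=True)
class SigmoidFit:
    L: float
    k: float
    a0: float
    rss: float
    converged: bool
    #: WLS parameter covariance (L, k, a0) from the weighted jacobian,
    #: valid when the band standard errors are the true sampling errors
    param_cov: np.ndarray | None = None

    def __call__(self, a) -> np.ndarray:
        return sigmoid(a, self.L, self.k, self.a0)


_L_FLOOR = 1e-10
_K_FLOOR = 1e-6


def fit_sigmoid_prevalence(
    table: GroupedRateTable,
    age_grid: np.ndarray,
    starts_a0: tuple[float, ...] = (50.0, 65.0, 80.0),
    open_band_offset: float = 5.0,
    max_nfev: int = 2000,
    warm_start: tuple[float, float, float] | None = None,
) -> tuple[np.ndarray, SigmoidFit]:
    """Fit ever-had-disease prevalence with a monotone logistic curve.

    Weighted least squares on the band values at their midpoints, weights
    1/se^2 where standard errors are positive (equal weights otherwise),
    with constraints 0 < L <= 1 and k > 0 so the curve is a valid,
    non-decreasing prevalence.  Multi-start over ``starts_a0`` plus a
    data-driven midpoint start; the best residual sum of squares wins.
    ``warm_start`` replaces the multi-start with a single start at the
    given ``(L, k, a0)`` — used when refitting small perturbations of a
    table already fitted once.
    """
    mids = table.midpoints(open_band_offset)
    prev = table.data["rate"].to_numpy(float)
    se = table.data["se"].to_numpy(float)
    if len(mids) < 4:
        raise ValueError(f"need at least 4 bands to fit a sigmoid, got {len(mids)}")
    if (prev < 0).any() or (prev > 1).any():
        raise ValueError("prevalence must lie in [0, 1]")
    if (se > 0).all():
        w = 1.0 / se**2
    else:
        w = np.ones_like(prev)
    sw = np.sqrt(w)

    def resid(theta):
        L, k, a0 = theta
        return sw * (sigmoid(mids, L, k, a0) - prev)

    def jac(theta):
        L, k, a0 = theta
        z = np.exp(-k * (mids - a0))
        denom = 1.0 + z
        dL = 1.0 / denom
        dk = L * z * (mids - a0) / denom**2
        da0 = -L * z * k / denom**2
        return sw[:, None] * np.column_stack([dL, dk, da0])

    pmax = float(prev.max())
    if pmax <= 0.0:
        # no disease observed anywhere: curve pinned at the lower bound
        fit = SigmoidFit(L=_L_FLOOR, k=_K_FLOOR, a0=float(np.median(mids)), rss=0.0, converged=True)
        return fit(np.asarray(age_grid, float)), fit

    L0 = min(1.0, max(1.2 * pmax, 1e-6))
    # data-driven centre: age at which prevalence first exceeds half its max
    above = mids[prev >= pmax / 2.0]
    a0_data = float(above[0]) if above.size else float(np.median(mids))
    lo = np.array([_L_FLOOR, _K_FLOOR, mids[0] - 60.0])
    hi = np.array([1.0, 5.0, mids[-1] + 60.0])

    if warm_start is not None:
        start_points = [np.asarray(warm_start, float)]
    else:
        start_points = [
            np.array([L0, 0.1, a0_start]) for a0_start in (*starts_a0, a0_data)
        ]
    best = None
    ok = False
    for x0 in start_points:
        x0 = np.clip(x0, lo, hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = least_squares(
                resid, x0, jac=jac, bounds=(lo, hi), max_nfev=max_nfev, method="trf"
            )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.status > 0))
        if sol.status > 0:
            ok = True
    rss, theta, status_ok = best[0], best[1], best[2]
    if not (ok and status_ok):
        log.warning("sigmoid fit did not converge; returning best parameters so far")
    J = jac(theta)
    try:
        cov = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = None
    fit = SigmoidFit(
        L=float(theta[0]),
        k=float(theta[1]),
        a0=float(theta[2]),
        rss=rss,
        converged=bool(ok and status_ok),
        param_cov=cov,
    )
    return fit(np.asarray(age_grid, float)), fit
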