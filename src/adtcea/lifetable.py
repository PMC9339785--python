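"""Background mortality: life-table smoothing and per-cycle death risk.

An age-specific annual mortality table (age, qx) is smoothed with a
three-parameter logistic curve of age, q(a) = L / (1 + exp(-k (a - a0))),
and converted to per-cycle death probabilities at any attained age under a
constant-hazard-within-year assumption, scaled by a disease-state hazard
ratio.  A raw-table mode with linear interpolation is available as a
fallback when no smooth fit is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LifeTable",
    "LogisticMortalityModel",
    "InterpolatedMortalityModel",
    "MortalityHR",
    "fit_logistic_mortality",
    "interpolated_mortality",
    "cycle_death_prob",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx in [0, 1) by integer age."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=float)
        q = np.asarray(self.qx, dtype=float)
        if a.ndim != 1 or a.shape != q.shape:
            raise ValueError("ages and qx must be parallel 1-d sequences")
        if a.size == 0:
            raise ValueError("empty life table")
        if np.any(np.diff(a) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("qx must lie in [0, 1)")
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "qx", q)

    @classmethod
    def read_csv(cls, path: str) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages.astype(int), "qx": self.qx})


def _logistic(a, L, k, a0):
    return L / (1.0 + np.exp(-k * (a - a0)))


@dataclass(frozen=True)
class LogisticMortalityModel:
    """q(a) = L / (1 + exp(-k (a - a0))), clamped to the fitted age range."""

    asymptote: float   # L, probability scale
    steepness: float   # k, per year
    midpoint: float    # a0, years
    age_min: float = 0.0
    age_max: float = np.inf

    def annual_q(self, age) -> np.ndarray | float:
        a = np.clip(np.asarray(age, dtype=float), self.age_min, self.age_max)
        q = _logistic(a, self.asymptote, self.steepness, self.midpoint)
        q = np.clip(q, 0.0, 0.999999)
        return float(q) if np.ndim(age) == 0 else q


@dataclass(frozen=True)
class InterpolatedMortalityModel:
    """Raw-table fallback: linear interpolation, flat beyond either end."""

    table: LifeTable

    def annual_q(self, age) -> np.ndarray | float:
        q = np.interp(np.asarray(age, dtype=float),
                      self.table.ages, self.table.qx)
        return float(q) if np.ndim(age) == 0 else q


@dataclass(frozen=True)
class MortalityHR:
    """Multiplicative hazard ratio on background mortality (value > 0)."""

    value: float
    description: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError("mortality hazard ratio must be positive")


def fit_logistic_mortality(table: LifeTable) -> LogisticMortalityModel:
    """Least-squares fit of the logistic curve to (age, qx).

    Requires at least four distinct ages and at least one non-zero qx.
    Deterministic given the table.
    """
    if table.ages.size < 4:
        raise ValueError("need at least 4 ages to fit a 3-parameter curve")
    if np.all(table.qx == 0):
        raise ValueError("degenerate table: all qx are zero")
    qmax = float(table.qx.max())
    # midpoint guess: age at which qx first reaches half its maximum
    half_idx = int(np.searchsorted(table.qx, qmax / 2.0))
    half_idx = min(half_idx, table.ages.size - 1)
    p0 = (min(2.0 * qmax, 1.0), 0.1, float(table.ages[half_idx]))
    popt, _ = curve_fit(
        _logistic, table.ages, table.qx, p0=p0,
        bounds=([1e-12, 1e-6, table.ages.min() - 100.0],
                [1.0, 5.0, table.ages.max() + 200.0]),
        maxfev=20_000)
    return LogisticMortalityModel(
        asymptote=float(popt[0]), steepness=float(popt[1]),
        midpoint=float(popt[2]),
        age_min=float(table.ages.min()), age_max=float(table.ages.max()))


def interpolated_mortality(table: LifeTable) -> InterpolatedMortalityModel:
    return InterpolatedMortalityModel(table)


def cycle_death_prob(model, age, hr: MortalityHR | float = 1.0,
                     cycle_length: float = 28.0) -> np.ndarray | float:
    """Per-cycle death probability at an attained age.

    The annual probability q(age) is converted assuming a constant hazard
    within the year, with the hazard ratio applied on the hazard scale:

        p = 1 - exp(-hr * (-ln(1 - q)) * cycle_length / 365.25)

    Monotone in age (for a fitted logistic), hr and cycle_length; compounding
    365.25 / c cycles at hr = 1 recovers the annual probability exactly.
    """
    value = hr.value if isinstance(hr, MortalityHR) else float(hr)
    if value <= 0:
        raise ValueError("hazard ratio must be positive")
    if cycle_length <= 0:
        raise ValueError("cycle length must be positive")
    q = np.asarray(model.annual_q(age), dtype=float)
    if np.any(q >= 1.0):
        raise ValueError("annual death probability must be < 1")
    hazard = -np.log1p(-q)
    p = -np.expm1(-value * hazard * cycle_length / DAYS_PER_YEAR)
    return float(p) if np.ndim(age) == 0 else p
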