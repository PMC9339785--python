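"""Parametric survival fitting and per-cycle transition probabilities.

Fits right-censored time-to-event data (time to PSA progression, in days)
with five parametric families by maximum likelihood, selects the best family
by AIC, and converts the extrapolated curve into per-cycle progression
probabilities for the cohort engine — optionally under a proportional-hazards
treatment effect.

Parameterizations (t in days, scale lambda > 0):

========== ===========================================  ==========
family     survival function S(t)                       parameters
========== ===========================================  ==========
exponential  exp(-lambda t)                             lambda
weibull      exp(-lambda t**gamma)                      gamma, lambda
loglogistic  1 / (1 + lambda t**gamma)                  gamma, lambda
lognormal    1 - Phi((ln t - mu) / sigma)               sigma, mu
gompertz     exp(-(lambda/gamma) (e**(gamma t) - 1))    gamma, lambda
========== ===========================================  ==========

For the log-logistic, log-normal, Weibull and exponential families S(t) -> 0
as t -> infinity.  A Gompertz curve with negative shape plateaus at
exp(lambda/gamma) > 0 (a fraction never experiences the event); this is the
one family whose extrapolation does not vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "SurvivalDataset",
    "SurvivalFit",
    "HazardRatio",
    "survival_at",
    "fit_parametric",
    "fit_all_families",
    "select_best",
    "apply_hazard_ratio",
    "per_cycle_progression_prob",
    "per_cycle_progression_probs",
    "fit_report",
    "AllCensoredError",
    "FitConvergenceError",
]

#: Fixed family order, also the tie-break order in :func:`select_best`.
FAMILIES: tuple[str, ...] = (
    "exponential", "weibull", "loglogistic", "lognormal", "gompertz")

_N_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2,
             "lognormal": 2, "gompertz": 2}


class AllCensoredError(ValueError):
    """Dataset contains no observed events; the likelihood is degenerate."""


class FitConvergenceError(RuntimeError):
    """The likelihood optimizer failed to converge from every start."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored time-to-event data.

    ``times`` are event or censoring times in days (strictly positive);
    ``events`` are parallel indicators (1 = event observed, 0 = censored).
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=float)
        if t.ndim != 1 or e.ndim != 1 or t.shape != e.shape:
            raise ValueError("times and events must be parallel 1-d sequences")
        if t.size == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all times must be finite and strictly positive")
        if not np.all(np.isin(e, (0.0, 1.0))):
            raise ValueError("events must be 0/1 indicators")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e.astype(int))

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def exposure(self) -> float:
        """Total follow-up time (sum of all times), days."""
        return float(self.times.sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        return cls(df["time_days"].to_numpy(), df["event"].to_numpy())

    @classmethod
    def read_csv(cls, path: str) -> "SurvivalDataset":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "event": self.events})


@dataclass(frozen=True)
class SurvivalFit:
    """A fitted parametric survival curve.

    ``shape`` is gamma (sigma for the log-normal; unused and None for the
    exponential); ``scale`` is lambda (mu for the log-normal, any real).
    """

    family: str
    shape: float | None
    scale: float
    log_likelihood: float
    aic: float
    n_params: int

    def survival(self, t) -> np.ndarray | float:
        return survival_at(self, t)

    def __call__(self, t):
        return survival_at(self, t)


@dataclass(frozen=True)
class HazardRatio:
    """A multiplicative effect on the hazard (value > 0)."""

    value: float
    applies_to: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError("hazard ratio must be finite and positive")


# ---------------------------------------------------------------------------
# survival / hazard kernels
# ---------------------------------------------------------------------------

def _log_survival(family: str, t: np.ndarray, shape: float | None,
                  scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return -scale * t
    if family == "weibull":
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = -scale * t[pos] ** shape
        return out
    if family == "loglogistic":
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = -np.log1p(scale * t[pos] ** shape)
        return out
    if family == "lognormal":
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = stats.norm.logsf((np.log(t[pos]) - scale) / shape)
        return out
    if family == "gompertz":
        if abs(shape) < 1e-12:
            return -scale * t
        return -(scale / shape) * np.expm1(shape * t)
    raise ValueError(f"unknown family {family!r}")


def _log_hazard(family: str, t: np.ndarray, shape: float | None,
                scale: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if family == "exponential":
        return np.full_like(t, np.log(scale))
    if family == "weibull":
        return np.log(scale * shape) + (shape - 1.0) * np.log(t)
    if family == "loglogistic":
        return (np.log(scale * shape) + (shape - 1.0) * np.log(t)
                - np.log1p(scale * t ** shape))
    if family == "lognormal":
        z = (np.log(t) - scale) / shape
        return (stats.norm.logpdf(z) - np.log(shape * t)
                - stats.norm.logsf(z))
    if family == "gompertz":
        return np.log(scale) + shape * t
    raise ValueError(f"unknown family {family!r}")


def survival_at(fit: SurvivalFit, t) -> np.ndarray | float:
    """Evaluate S(t) for a fitted curve; S(0) = 1, non-increasing in t."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    if not np.isfinite(fit.scale) or (fit.shape is not None
                                      and not np.isfinite(fit.shape)):
        raise ValueError("non-finite survival parameters")
    out = np.exp(_log_survival(fit.family, arr, fit.shape, fit.scale))
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# maximum likelihood under right censoring
# ---------------------------------------------------------------------------

def _unpack(family: str, theta: np.ndarray) -> tuple[float | None, float]:
    if family == "exponential":
        return None, float(np.exp(theta[0]))
    if family == "lognormal":
        return float(np.exp(theta[1])), float(theta[0])  # sigma, mu
    if family == "gompertz":
        return float(theta[0]), float(np.exp(theta[1]))  # gamma free sign
    return float(np.exp(theta[0])), float(np.exp(theta[1]))  # gamma, lambda


def _neg_loglik(family: str, theta: np.ndarray,
                data: SurvivalDataset) -> float:
    shape, scale = _unpack(family, theta)
    if family == "gompertz" and abs(shape) > 1.0:
        return np.inf  # per-day shape of |1| is far outside plausibility
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ls = _log_survival(family, data.times, shape, scale)
        ev = data.events == 1
        lh = _log_hazard(family, data.times[ev], shape, scale)
        ll = float(ls.sum() + lh.sum())
    return np.inf if not np.isfinite(ll) else -ll


def _neg_loglik_grad(family: str, theta: np.ndarray,
                     data: SurvivalDataset) -> np.ndarray:
    """Analytic gradient of the negative log-likelihood in transformed
    coordinates (log-scale for positive parameters)."""
    shape, scale = _unpack(family, theta)
    t = data.times
    ev = data.events == 1
    d = float(ev.sum())
    if family == "exponential":
        dlam = d / scale - t.sum()
        return -np.array([dlam * scale])
    if family == "weibull":
        tg = t ** shape
        logt = np.log(t)
        dlam = d / scale - tg.sum()
        dgam = d / shape + logt[ev].sum() - scale * (tg * logt).sum()
        return -np.array([dgam * shape, dlam * scale])
    if family == "loglogistic":
        u = scale * t ** shape
        w = u / (1.0 + u)
        logt = np.log(t)
        dlam = (d - w.sum() - w[ev].sum()) / scale
        dgam = (d / shape + logt[ev].sum()
                - (w * logt).sum() - (w[ev] * logt[ev]).sum())
        return -np.array([dgam * shape, dlam * scale])
    if family == "lognormal":
        sigma, mu = shape, scale
        z = (np.log(t) - mu) / sigma
        dmu = z[ev].sum() / sigma
        dsig = ((z[ev] ** 2 - 1.0).sum()) / sigma
        zc = z[~ev]
        if zc.size:
            ratio = np.exp(stats.norm.logpdf(zc) - stats.norm.logsf(zc))
            dmu += ratio.sum() / sigma
            dsig += (zc * ratio).sum() / sigma
        return -np.array([dmu, dsig * sigma])
    if family == "gompertz":
        g = shape if abs(shape) > 1e-12 else 1e-12
        egt = np.exp(g * t)
        em1 = np.expm1(g * t)
        dlam = d / scale - em1.sum() / g
        dgam = (t[ev].sum() + (scale / g ** 2) * em1.sum()
                - (scale / g) * (t * egt).sum())
        return -np.array([dgam, dlam * scale])
    raise ValueError(f"unknown family {family!r}")


def _starting_values(data: SurvivalDataset, family: str) -> list[np.ndarray]:
    te = data.times[data.events == 1]
    rate = max(data.n_events / data.exposure, 1e-300)
    med = float(np.median(te))
    if family == "exponential":
        return [np.array([np.log(rate)]),
                np.array([np.log(rate) + 0.5]),
                np.array([np.log(rate) - 0.5])]
    if family == "lognormal":
        mu0 = float(np.mean(np.log(te)))
        s0 = float(np.std(np.log(te))) or 1.0
        return [np.array([mu0, np.log(s0)]),
                np.array([mu0, np.log(1.5 * s0)]),
                np.array([mu0 + 0.5, np.log(s0)])]
    if family == "gompertz":
        return [np.array([1e-4, np.log(rate)]),
                np.array([1e-3, np.log(rate)]),
                np.array([-1e-4, np.log(rate)])]
    # weibull / loglogistic: match the observed median event time
    starts = []
    for g in (0.8, 1.0, 1.5):
        lam = (np.log(2.0) if family == "weibull" else 1.0) / med ** g
        starts.append(np.array([np.log(g), np.log(lam)]))
    return starts


def fit_parametric(data: SurvivalDataset, family: str) -> SurvivalFit:
    """Maximum-likelihood fit of one family under right censoring.

    The log-likelihood is sum(events * log h(t)) + sum(log S(t)).  The
    optimizer runs Nelder-Mead from three starting points on log-transformed
    positive parameters; non-convergence from every start raises
    :class:`FitConvergenceError`.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    if data.n_events == 0:
        raise AllCensoredError("no observed events: cannot fit")
    objective = lambda th: _neg_loglik(family, th, data)
    best = None
    for theta0 in _starting_values(data, family):
        res = optimize.minimize(
            objective, theta0, method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-12, maxiter=10_000,
                         maxfev=20_000))
        if np.isfinite(res.fun) and res.success:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitConvergenceError(
            f"{family} fit failed to converge from all starting values")
    # polish by solving the score equation: likelihood differences near the
    # optimum fall below floating-point noise, but the analytic gradient
    # stays resolvable, so a root-find pushes the MLE to full precision
    best_x, best_fun = best.x, float(best.fun)
    grad = lambda th: _neg_loglik_grad(family, th, data)
    polished = optimize.minimize(objective, best_x, jac=grad, method="BFGS",
                                 options=dict(gtol=1e-10))
    if np.isfinite(polished.fun) and polished.fun <= best_fun:
        best_x, best_fun = polished.x, float(polished.fun)
    root = optimize.root(grad, best_x, method="hybr", tol=1e-13)
    solved = root.success or np.all(np.abs(np.atleast_1d(root.fun)) < 1e-6)
    if solved and np.all(np.abs(root.x - best_x) < 1e-2):
        cand = objective(root.x)
        if np.isfinite(cand) and cand <= best_fun + 1e-8 * (1 + abs(best_fun)):
            best_x, best_fun = root.x, float(cand)
    shape, scale = _unpack(family, best_x)
    ll = -best_fun
    k = _N_PARAMS[family]
    return SurvivalFit(family=family, shape=shape, scale=scale,
                       log_likelihood=ll, aic=2.0 * k - 2.0 * ll, n_params=k)


def fit_all_families(data: SurvivalDataset,
                     families: Sequence[str] = FAMILIES) -> list[SurvivalFit]:
    """Fit every requested family on the same dataset."""
    return [fit_parametric(data, fam) for fam in families]


def select_best(fits: Sequence[SurvivalFit]) -> SurvivalFit:
    """Pick the minimal-AIC fit; ties break to fewer parameters, then the
    fixed family order (exponential, weibull, loglogistic, lognormal,
    gompertz)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits supplied")
    return min(fits, key=lambda f: (f.aic, f.n_params,
                                    FAMILIES.index(f.family)))


# ---------------------------------------------------------------------------
# derived survival functions and per-cycle probabilities
# ---------------------------------------------------------------------------

def apply_hazard_ratio(fit: SurvivalFit | Callable,
                       hr: HazardRatio | float) -> Callable:
    """Proportional hazards on the cumulative-hazard scale: S_hr = S**hr.

    hr = 1 returns the identity; composing hr = a then hr = b equals
    hr = a * b.  Accepts either a :class:`SurvivalFit` or any survival
    callable.
    """
    value = hr.value if isinstance(hr, HazardRatio) else float(hr)
    if not np.isfinite(value) or value <= 0:
        raise ValueError("hazard ratio must be finite and positive")
    base = fit.survival if isinstance(fit, SurvivalFit) else fit

    def s_hr(t):
        return np.power(base(t), value)

    return s_hr


def per_cycle_progression_prob(surv: Callable, cycle_index: int,
                               cycle_length: float) -> float:
    """Conditional probability of progressing during one cycle.

    p_i = 1 - S((i+1) c) / S(i c); the product of (1 - p_i) over i < k
    telescopes back to S(k c) / S(0).
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    s0 = float(surv(cycle_index * cycle_length))
    if s0 <= 0.0:
        raise ZeroDivisionError(
            "survival is zero at the cycle start: cohort fully progressed")
    s1 = float(surv((cycle_index + 1) * cycle_length))
    return float(np.clip(1.0 - s1 / s0, 0.0, 1.0))


def per_cycle_progression_probs(surv: Callable, n_cycles: int,
                                cycle_length: float) -> np.ndarray:
    """Vectorized per-cycle progression probabilities for cycles 0..n-1."""
    grid = np.arange(n_cycles + 1, dtype=float) * cycle_length
    s = np.asarray(surv(grid), dtype=float)
    if np.any(s[:-1] <= 0.0):
        raise ZeroDivisionError("survival reaches zero inside the horizon")
    return np.clip(1.0 - s[1:] / s[:-1], 0.0, 1.0)


def fit_report(fits: Sequence[SurvivalFit],
               selected: SurvivalFit | None = None) -> pd.DataFrame:
    """Tabular fit report: family, params, loglik, aic, selected flag."""
    if selected is None:
        selected = select_best(fits)
    rows = []
    for f in fits:
        if f.family == "lognormal":
            ptxt = f"mu={f.scale:.6g};sigma={f.shape:.6g}"
        elif f.family == "exponential":
            ptxt = f"lambda={f.scale:.6g}"
        else:
            ptxt = f"lambda={f.scale:.6g};gamma={f.shape:.6g}"
        rows.append({"family": f.family, "params": ptxt,
                     "loglik": f.log_likelihood, "aic": f.aic,
                     "selected": int(f is selected or f == selected)})
    return pd.DataFrame(rows)
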