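"""Scenario, one-way (tornado), threshold-price and probabilistic analyses.

Every analysis here is a perturbation of a base
:class:`~adtcea.params.ParameterSet` addressed through dot paths, followed by
a full re-evaluation of the model (both arms, full horizon).  The
probabilistic analysis draws each uncertain parameter from a standard
distribution family — gamma for costs, beta for utilities and probabilities,
log-normal for hazard ratios — with hyper-parameters moment-matched to the
base value and a relative standard error (default 20%), and summarises the
Monte-Carlo cloud as a cost-effectiveness plane and an acceptability curve
CEAC(wtp) = P(wtp * dE - dC > 0).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .economics import EconomicResult, evaluate
from .params import ParameterSet

__all__ = [
    "ParamPerturbation",
    "PsaDistribution",
    "ThresholdResult",
    "PsaResult",
    "one_way",
    "default_one_way_perturbations",
    "scenario_run",
    "threshold_price",
    "psa",
    "default_psa_distributions",
    "ceac_curve",
]


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamPerturbation:
    """One tornado bar: a parameter path with low/high inputs.

    ``pclass`` records the convention that produced the range: cost
    parameters vary by -20%/+20%, efficacy parameters by -10%/+10%;
    utilities and the discount rate take explicitly configured bounds.
    """

    path: str
    low: float
    high: float
    pclass: str = "cost"


def one_way(base: ParameterSet,
            perturbations: Sequence[ParamPerturbation],
            intervention: str = "degarelix",
            comparator: str = "leuprorelin") -> pd.DataFrame:
    """Tornado table: two full model evaluations per parameter.

    Returns columns (parameter, pclass, low_input, high_input, icer_low,
    icer_high, range), stable-sorted by descending range.  Listing a
    parameter twice simply yields two identical rows.
    """
    rows = []
    for pert in perturbations:
        base.get(pert.path)  # raises KeyError for unknown paths
        lo = evaluate(base.with_edits({pert.path: pert.low}),
                      intervention, comparator)
        hi = evaluate(base.with_edits({pert.path: pert.high}),
                      intervention, comparator)
        rows.append({
            "parameter": pert.path, "pclass": pert.pclass,
            "low_input": pert.low, "high_input": pert.high,
            "icer_low": lo.icer, "icer_high": hi.icer,
            "range": abs(hi.icer - lo.icer),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("range", ascending=False,
                            kind="mergesort").reset_index(drop=True)
    return df


def default_one_way_perturbations(base: ParameterSet) -> list[ParamPerturbation]:
    """Standard tornado battery: cost paths at +/-20%, efficacy at +/-10%,
    utilities at +/-10% (capped at 1), cost discount rate 0 to 8%."""
    cost_paths = [
        "drug_costs.degarelix_maintenance",
        "drug_costs.degarelix_first_cycle",
        "drug_costs.leuprorelin_per_cycle",
        "drug_costs.flare_cover_daily",
        "drug_costs.docetaxel_daily",
        "drug_costs.abiraterone_daily",
        "management_costs.post_abiraterone_cycle",
        "management_costs.supportive_cycle",
        "management_costs.palliative_cycle",
    ]
    efficacy_paths = [
        "survival.hr_psa_recurrence",
        "second_line.response_rates.aa_addition",
        "second_line.response_rates.aa_withdrawal",
        "second_line.response_rates.docetaxel",
        "second_line.response_rates.abiraterone",
        "mortality.hr_post_progression",
    ]
    utility_paths = [
        "utilities.first_line",
        "utilities.aa_addition",
        "utilities.docetaxel",
        "utilities.supportive_care",
    ]
    perts = [ParamPerturbation(p, 0.8 * base.get(p), 1.2 * base.get(p), "cost")
             for p in cost_paths]
    perts += [ParamPerturbation(
        p, 0.9 * base.get(p),
        min(1.1 * base.get(p), 1.0) if "response_rates" in p
        else 1.1 * base.get(p), "efficacy")
        for p in efficacy_paths]
    perts += [ParamPerturbation(p, 0.9 * base.get(p),
                                min(1.1 * base.get(p), 1.0), "utility")
              for p in utility_paths]
    perts.append(ParamPerturbation("settings.discount_rate_cost",
                                   0.0, 0.08, "rate"))
    return perts


# ---------------------------------------------------------------------------
# scenario and threshold-price analyses
# ---------------------------------------------------------------------------

def scenario_run(base: ParameterSet, edits: dict[str, Any],
                 intervention: str = "degarelix",
                 comparator: str = "leuprorelin") -> EconomicResult:
    """Evaluate the model under path edits; the base set is never mutated."""
    return evaluate(base.with_edits(edits), intervention, comparator)


@dataclass(frozen=True)
class ThresholdResult:
    """Solution of a threshold-price search."""

    price: float
    pct_change: float        # percent change from the base price
    icer: float
    base_price: float
    target_icer: float


def threshold_price(base: ParameterSet, price_path: str, target_icer: float,
                    bracket: tuple[float, float] | None = None,
                    icer_tol: float = 1.0, price_tol: float = 0.01,
                    intervention: str = "degarelix",
                    comparator: str = "leuprorelin") -> ThresholdResult:
    """Bisection for the price at which the ICER meets a target.

    Requires the ICER to be monotone in the addressed price over the search
    bracket (default: 0 to twice the base price).  Stops when the ICER is
    within ``icer_tol`` yuan/QALY of the target or the bracket is narrower
    than ``price_tol`` yuan.
    """
    base_price = float(base.get(price_path))

    def icer_at(price: float) -> float:
        res = scenario_run(base, {price_path: price}, intervention, comparator)
        if math.isnan(res.icer):
            raise ValueError("ICER undefined along the search bracket")
        return res.icer

    lo, hi = bracket if bracket is not None else (0.0, 2.0 * base_price)
    if lo >= hi:
        raise ValueError("invalid bracket")
    f_lo = icer_at(lo) - target_icer
    f_hi = icer_at(hi) - target_icer
    if abs(f_lo) <= icer_tol:
        price, f_mid = lo, f_lo
    elif abs(f_hi) <= icer_tol:
        price, f_mid = hi, f_hi
    elif f_lo * f_hi > 0:
        raise ValueError("target ICER not bracketed by the price bracket")
    else:
        price = 0.5 * (lo + hi)
        f_mid = icer_at(price) - target_icer
        while hi - lo > price_tol and abs(f_mid) > icer_tol:
            if f_lo * f_mid <= 0:
                hi = price
            else:
                lo, f_lo = price, f_mid
            price = 0.5 * (lo + hi)
            f_mid = icer_at(price) - target_icer
    pct = 100.0 * (price - base_price) / base_price
    return ThresholdResult(price=price, pct_change=pct,
                           icer=f_mid + target_icer,
                           base_price=base_price, target_icer=target_icer)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaDistribution:
    """Sampling distribution of one parameter.

    Hyper-parameters are moment-matched to the base value and a relative
    standard error: gamma (costs, support >= 0), beta (utilities and
    probabilities, support [0, 1]), log-normal (hazard ratios, support > 0).
    ``rse = 0`` degenerates to the base value.
    """

    path: str
    family: str          # gamma | beta | lognormal
    rse: float = 0.2

    def draw(self, base_value: float, rng: np.random.Generator,
             max_rejects: int = 100) -> float:
        if self.rse == 0.0 or base_value == 0.0:
            return base_value
        sd = self.rse * abs(base_value)
        for _ in range(max_rejects):
            if self.family == "gamma":
                shape = 1.0 / self.rse ** 2
                scale = base_value * self.rse ** 2
                x = float(rng.gamma(shape, scale))
                if x >= 0:
                    return x
            elif self.family == "beta":
                m = base_value
                if not 0.0 < m < 1.0:
                    raise ValueError(
                        f"beta base value for {self.path} must lie in (0,1)")
                var = min(sd ** 2, 0.99 * m * (1.0 - m))
                nu = m * (1.0 - m) / var - 1.0
                x = float(rng.beta(m * nu, (1.0 - m) * nu))
                if 0.0 <= x <= 1.0:
                    return x
            elif self.family == "lognormal":
                sigma2 = math.log1p(self.rse ** 2)
                mu = math.log(base_value) - sigma2 / 2.0
                x = float(rng.lognormal(mu, math.sqrt(sigma2)))
                if x > 0:
                    return x
            else:
                raise ValueError(f"unknown distribution family {self.family!r}")
        raise RuntimeError(
            f"draw for {self.path} rejected {max_rejects} times")


def default_psa_distributions(base: ParameterSet,
                              rse: float = 0.2) -> list[PsaDistribution]:
    """Standard distribution battery over the fixture's uncertain parameters."""
    dists = [PsaDistribution(p, "gamma", rse) for p in (
        "drug_costs.degarelix_maintenance",
        "drug_costs.degarelix_first_cycle",
        "drug_costs.leuprorelin_per_cycle",
        "drug_costs.flare_cover_daily",
        "drug_costs.docetaxel_daily",
        "drug_costs.abiraterone_daily",
        "management_costs.post_abiraterone_cycle",
        "management_costs.supportive_cycle",
        "management_costs.palliative_cycle",
        "management_costs.gp_visit",
        "management_costs.blood_test",
    )]
    dists += [PsaDistribution(p, "beta", rse) for p in (
        "utilities.first_line",
        "utilities.aa_addition",
        "utilities.aa_withdrawal",
        "utilities.docetaxel",
        "utilities.abiraterone",
        "utilities.supportive_care",
        "second_line.response_rates.aa_addition",
        "second_line.response_rates.aa_withdrawal",
        "second_line.response_rates.docetaxel",
        "second_line.response_rates.abiraterone",
        "second_line.chemo_skip_fraction",
    )]
    dists += [PsaDistribution(p, "lognormal", rse) for p in (
        "survival.hr_psa_recurrence",
        "mortality.hr_post_progression",
    )]
    return dists


def _path_key(path: str) -> int:
    # Stable 31-bit stream key per parameter path, independent of list order.
    return int.from_bytes(hashlib.sha256(path.encode()).digest()[:4],
                          "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo cloud plus acceptability summaries."""

    samples: pd.DataFrame    # iteration, delta_cost, delta_qaly, icer
    draws: pd.DataFrame      # drawn parameter values, one column per path
    ceac: pd.DataFrame       # wtp, probability
    n_iter: int
    seed: int

    def prob_cost_effective(self, wtp: float) -> float:
        inb = wtp * self.samples["delta_qaly"] - self.samples["delta_cost"]
        return float((inb > 0).mean())

    def quadrant_counts(self) -> dict[str, int]:
        dc = self.samples["delta_cost"].to_numpy()
        de = self.samples["delta_qaly"].to_numpy()
        return {
            "ne": int(np.sum((de > 0) & (dc > 0))),
            "nw": int(np.sum((de <= 0) & (dc > 0))),
            "sw": int(np.sum((de <= 0) & (dc <= 0))),
            "se": int(np.sum((de > 0) & (dc <= 0))),
        }


def ceac_curve(samples: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """CEAC(wtp) = fraction of iterations with positive incremental net
    benefit at that willingness-to-pay."""
    dc = samples["delta_cost"].to_numpy()
    de = samples["delta_qaly"].to_numpy()
    probs = [(float(np.mean(w * de - dc > 0))) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def psa(base: ParameterSet, dists: Sequence[PsaDistribution],
        n_iter: int = 5000, seed: int = 0,
        wtp_grid: np.ndarray | None = None,
        intervention: str = "degarelix",
        comparator: str = "leuprorelin") -> PsaResult:
    """Probabilistic sensitivity analysis.

    Each iteration independently redraws every listed parameter, re-runs both
    arms and records (dC, dE).  The random-number contract: one root seed;
    the stream for (iteration, parameter) is derived from the seed, the
    iteration index and a hash of the parameter path, so adding or reordering
    parameters does not scramble the other draws.  The default WTP grid runs
    0 to 300,000 yuan in 1,000-yuan steps (covering one to three times GDP
    per capita).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 300_001.0, 1000.0)
    base_values = {d.path: float(base.get(d.path)) for d in dists}
    rows = []
    draw_rows = []
    for it in range(n_iter):
        edits = {}
        for d in dists:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, it, _path_key(d.path)]))
            edits[d.path] = d.draw(base_values[d.path], rng)
        res = evaluate(base.with_edits(edits), intervention, comparator)
        rows.append({"iteration": it, "delta_cost": res.delta_cost,
                     "delta_qaly": res.delta_qalys, "icer": res.icer})
        draw_rows.append(dict(edits))
    samples = pd.DataFrame(rows)
    draws = pd.DataFrame(draw_rows)
    return PsaResult(samples=samples, draws=draws,
                     ceac=ceac_curve(samples, np.asarray(wtp_grid, float)),
                     n_iter=n_iter, seed=seed)
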