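"""Discounted cost and QALY accounting, ICER and net-benefit statistics.

Converts a pair of cohort traces into discounted per-arm totals and the
incremental comparison: delta cost, delta QALYs, the incremental
cost-effectiveness ratio ICER = (C_deg - C_leu) / (E_deg - E_leu), the
incremental net benefit INB = wtp * dE - dC, and the ICER expressed as a
multiple of GDP per capita (the willingness-to-pay convention of one to
three times GDP per capita per QALY).

Cost components per state and cycle: drug acquisition (arm-specific in the
castration states), bundled management costs, per-item administration costs
via a configurable frequency map, and expected adverse-event treatment costs
(incidence x mix-weighted event cost).  Effects: state utility plus the
expected adverse-event decrement, accrued as 28/365.25 years per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import CohortTrace, run_cohort
from .params import ARMS, DAYS_PER_YEAR, STATES, ParameterSet

__all__ = [
    "DiscountSpec",
    "ArmTotals",
    "EconomicResult",
    "discount_factor",
    "discount_factors",
    "mean_price",
    "state_cost_matrix",
    "state_utility_vector",
    "accumulate",
    "incremental",
    "evaluate",
    "result_table",
]


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rates for costs and effects, plus the cycle length."""

    rate_cost: float = 0.05
    rate_effect: float = 0.05
    cycle_length_days: float = 28.0

    @classmethod
    def from_params(cls, params: ParameterSet) -> "DiscountSpec":
        s = params.settings
        return cls(rate_cost=s.discount_rate_cost,
                   rate_effect=s.discount_rate_effect,
                   cycle_length_days=s.cycle_length_days)


def discount_factor(spec: DiscountSpec, cycle: int, which: str) -> float:
    """(1 + r)^(-cycle * cycle_length / 365.25); cycle 0 -> 1."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if which not in ("cost", "effect"):
        raise ValueError("which must be 'cost' or 'effect'")
    r = spec.rate_cost if which == "cost" else spec.rate_effect
    years = cycle * spec.cycle_length_days / DAYS_PER_YEAR
    return float((1.0 + r) ** (-years))


def discount_factors(rate: float, n_cycles: int,
                     cycle_length_days: float) -> np.ndarray:
    years = np.arange(n_cycles, dtype=float) * cycle_length_days / DAYS_PER_YEAR
    return (1.0 + rate) ** (-years)


def mean_price(prices: Sequence[float]) -> float:
    """Arithmetic mean of listed prices, rounded to 2 decimals for reporting.

    Used where a drug's unit price is the average of the originator and
    generic list prices.
    """
    prices = list(prices)
    if not prices:
        raise ValueError("no prices supplied")
    return round(float(np.mean(prices)), 2)


# ---------------------------------------------------------------------------
# per-state cost and utility ingredients
# ---------------------------------------------------------------------------

def _admin_cost(params: ParameterSet, state: str) -> float:
    freqs = params.admin_frequencies.get(state, {})
    return sum(f * getattr(params.management_costs, item)
               for item, f in freqs.items())


def _ae_expected(params: ParameterSet, arm: str,
                 state: str) -> tuple[float, float]:
    """(expected AE cost, expected AE utility decrement) per cycle in a state."""
    cost = 0.0
    dec = 0.0
    for ae in params.adverse_events:
        if state not in ae.states:
            continue
        inc = ae.incidence.get(arm, 0.0)
        cost += inc * ae.expected_cost(params.ae_costs)
        dec += inc * ae.disutility
    return cost, dec


def _base_state_costs(params: ParameterSet, arm: str) -> np.ndarray:
    """Steady-state per-cycle cost of each state (cycle >= 1), yuan."""
    dc = params.drug_costs
    mc = params.management_costs
    c = params.settings.cycle_length_days
    adt = (dc.degarelix_maintenance if arm == "degarelix"
           else dc.leuprorelin_per_cycle)
    drug = {
        "first_line": adt,
        "aa_addition": (adt if dc.adt_during_aa_states else 0.0)
        + dc.flare_cover_daily * c,
        "aa_withdrawal": adt if dc.adt_during_aa_states else 0.0,
        "docetaxel": dc.docetaxel_daily * c,
        "abiraterone": (dc.abiraterone_daily + dc.dexamethasone_daily) * c,
        "post_abiraterone": mc.post_abiraterone_cycle,
        "supportive_care": mc.supportive_cycle,
        "palliative_care": mc.palliative_cycle,
        "death": 0.0,
    }
    out = np.zeros(len(STATES))
    for j, state in enumerate(STATES):
        if state == "death":
            continue
        ae_cost, _ = _ae_expected(params, arm, state)
        out[j] = drug[state] + _admin_cost(params, state) + ae_cost
    return out


def state_cost_matrix(params: ParameterSet, arm: str,
                      n_cycles: int | None = None) -> np.ndarray:
    """(n_cycles, n_states) accrual costs; cycle 0 carries the starting-dose
    adjustments (degarelix 240 mg loading dose; leuprorelin 28-day
    anti-androgen flare cover)."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    n = (params.n_cycles if n_cycles is None else n_cycles)
    base = _base_state_costs(params, arm)
    mat = np.tile(base, (n, 1))
    dc = params.drug_costs
    fl = STATES.index("first_line")
    if arm == "degarelix":
        mat[0, fl] += dc.degarelix_first_cycle - dc.degarelix_maintenance
    else:
        mat[0, fl] += dc.flare_cover_daily * params.settings.cycle_length_days
    return mat


def state_utility_vector(params: ParameterSet, arm: str) -> np.ndarray:
    """Per-state utility including the expected adverse-event decrement."""
    out = np.array(params.utilities.as_vector(), dtype=float)
    for j, state in enumerate(STATES):
        if state == "death":
            continue
        _, dec = _ae_expected(params, arm, state)
        out[j] += dec
    return out


# ---------------------------------------------------------------------------
# accumulation and incremental statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmTotals:
    """Discounted totals for one arm."""

    arm: str
    cost: float
    qalys: float
    life_years: float


def accumulate(trace: CohortTrace, params: ParameterSet,
               spec: DiscountSpec | None = None) -> ArmTotals:
    """Discounted total cost and QALYs for one arm's trace.

    Each trace row is the occupancy during one cycle; the terminal row is a
    snapshot and accrues nothing (with half-cycle correction enabled, rows
    get trapezoid weights 0.5, 1, ..., 1, 0.5 instead).  QALYs accrue at
    utility x cycle_length/365.25 years per occupied cycle.
    """
    if spec is None:
        spec = DiscountSpec.from_params(params)
    occ = trace.occupancy
    n_rows = occ.shape[0]
    if params.settings.half_cycle_correction:
        rows = occ
        w = np.ones(n_rows)
        w[0] = w[-1] = 0.5
        n = n_rows
    else:
        rows = occ[:-1]
        w = np.ones(n_rows - 1)
        n = n_rows - 1
    costs = state_cost_matrix(params, trace.arm, n)
    util = state_utility_vector(params, trace.arm)
    alive = np.array([s != "death" for s in STATES], dtype=float)
    dfc = discount_factors(spec.rate_cost, n, spec.cycle_length_days)
    dfe = discount_factors(spec.rate_effect, n, spec.cycle_length_days)
    cycle_years = spec.cycle_length_days / DAYS_PER_YEAR
    cost = float(np.sum(w * dfc * np.sum(rows * costs, axis=1)))
    qalys = float(np.sum(w * dfe * (rows @ util)) * cycle_years)
    ly = float(np.sum(w * dfe * (rows @ alive)) * cycle_years)
    return ArmTotals(arm=trace.arm, cost=cost, qalys=qalys, life_years=ly)


@dataclass(frozen=True)
class EconomicResult:
    """Incremental comparison of intervention vs. comparator arm.

    ``classification`` is "defined" for an ordinary positive trade-off,
    "dominant" (cheaper and more effective), "dominated" (dearer and less
    effective) or "undefined" (no QALY difference; ICER is not a number).
    """

    intervention: ArmTotals
    comparator: ArmTotals
    delta_cost: float
    delta_qalys: float
    icer: float
    classification: str
    wtp: float
    inb: float
    gdp_per_capita: float
    gdp_multiple: float

    @property
    def icer_defined(self) -> bool:
        return self.classification != "undefined"


def incremental(intervention: ArmTotals, comparator: ArmTotals,
                wtp: float, gdp_per_capita: float) -> EconomicResult:
    """Incremental statistics; degenerate cases are labelled, never raised."""
    dc = intervention.cost - comparator.cost
    de = intervention.qalys - comparator.qalys
    if de == 0.0:
        icer = math.nan
        label = "undefined"
    else:
        icer = dc / de
        if dc < 0 and de > 0:
            label = "dominant"
        elif dc > 0 and de < 0:
            label = "dominated"
        else:
            label = "defined"
    inb = wtp * de - dc
    gdp_mult = icer / gdp_per_capita if not math.isnan(icer) else math.nan
    return EconomicResult(
        intervention=intervention, comparator=comparator,
        delta_cost=dc, delta_qalys=de, icer=icer, classification=label,
        wtp=wtp, inb=inb, gdp_per_capita=gdp_per_capita,
        gdp_multiple=gdp_mult)


def evaluate(params: ParameterSet, intervention: str = "degarelix",
             comparator: str = "leuprorelin",
             wtp: float | None = None) -> EconomicResult:
    """Run both arms through the cohort engine and compare them.

    The full base-case pipeline: cohort traces, discounted accumulation and
    the incremental comparison at the configured willingness-to-pay.
    """
    if wtp is None:
        wtp = params.willingness.wtp
    a = accumulate(run_cohort(params, intervention), params)
    b = accumulate(run_cohort(params, comparator), params)
    return incremental(a, b, wtp=wtp,
                       gdp_per_capita=params.willingness.gdp_per_capita)


def result_table(res: EconomicResult) -> pd.DataFrame:
    """One row per arm: total cost, QALYs, incremental QALYs, ICER, INB.

    Yuan rounded to the nearest integer, QALYs to 3 decimals (reporting
    convention)."""
    icer_txt = ("Dominant" if res.classification == "dominant"
                else "Undefined" if res.classification == "undefined"
                else f"{res.icer:.0f}")
    return pd.DataFrame([
        {"treatment": res.intervention.arm,
         "total_cost_yuan": round(res.intervention.cost),
         "qalys": round(res.intervention.qalys, 3),
         "incremental_qalys": round(res.delta_qalys, 3),
         "icer_yuan_per_qaly": icer_txt,
         "inb_yuan": round(res.inb)},
        {"treatment": res.comparator.arm,
         "total_cost_yuan": round(res.comparator.cost),
         "qalys": round(res.comparator.qalys, 3),
         "incremental_qalys": "", "icer_yuan_per_qaly": "", "inb_yuan": ""},
    ])


def result_text(res: EconomicResult) -> str:
    """Key-value text record of an incremental result."""
    lines = [
        f"intervention = {res.intervention.arm}",
        f"comparator = {res.comparator.arm}",
        f"cost_intervention_yuan = {res.intervention.cost:.2f}",
        f"cost_comparator_yuan = {res.comparator.cost:.2f}",
        f"qalys_intervention = {res.intervention.qalys:.4f}",
        f"qalys_comparator = {res.comparator.qalys:.4f}",
        f"delta_cost_yuan = {res.delta_cost:.2f}",
        f"delta_qalys = {res.delta_qalys:.4f}",
        f"icer_yuan_per_qaly = {res.icer:.2f}",
        f"classification = {res.classification}",
        f"wtp_yuan_per_qaly = {res.wtp:.2f}",
        f"inb_yuan = {res.inb:.2f}",
        f"gdp_multiple = {res.gdp_multiple:.4f}",
    ]
    return "\n".join(lines) + "\n"
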