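"""Cohort propagation through the adapted treatment-pathway state graph.

Moves a treatment-arm cohort through nine health states on 28-day cycles
over a 30-year horizon.  Transition probabilities are time-varying: first-line
PSA progression follows the extrapolated parametric survival curve (the
treated arm through a proportional-hazards effect), second-line states
persist at the per-cycle response rates, and every living state carries an
age-specific background death risk scaled by a disease-state hazard ratio.
Death competes with all other exits: non-death destinations are scaled by
(1 - p_death) so each row remains a probability distribution.

The default chain (configurable through :class:`~adtcea.params.ParameterSet`):

    first_line -> aa_addition -> aa_withdrawal -> {abiraterone (35%),
    docetaxel (65%)}; docetaxel -> abiraterone -> post_abiraterone ->
    supportive_care -> palliative_care; every state -> death (absorbing;
    palliative care exits only through background mortality x HR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .lifetable import LogisticMortalityModel, cycle_death_prob
from .params import ARMS, DAYS_PER_YEAR, STATES, ParameterSet
from .survival import (SurvivalFit, apply_hazard_ratio,
                       per_cycle_progression_probs)

__all__ = [
    "CohortTrace",
    "TransitionError",
    "arm_survival",
    "progression_probs",
    "death_probs",
    "transition_matrices",
    "build_transition_matrix",
    "run_cohort",
    "microsimulate",
]

N_STATES = len(STATES)
IDX = {s: i for i, s in enumerate(STATES)}
DEATH = IDX["death"]

_ROW_TOL = 1e-9


class TransitionError(ValueError):
    """A transition matrix row is not a probability distribution."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state-occupancy fractions for one arm.

    ``occupancy`` has one row per cycle 0..N (N maintenance cycles plus the
    initial row) and one column per state; each row sums to 1 and the death
    column is non-decreasing.
    """

    occupancy: np.ndarray
    arm: str
    cycle_length_days: float
    start_age: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        return (self.start_age + np.arange(self.occupancy.shape[0])
                * self.cycle_length_days / DAYS_PER_YEAR)

    def validate(self) -> None:
        occ = self.occupancy
        if np.any(occ < -_ROW_TOL) or np.any(occ > 1 + _ROW_TOL):
            raise TransitionError("occupancy outside [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > _ROW_TOL):
            raise TransitionError("cohort mass not conserved")
        if np.any(np.diff(occ[:, DEATH]) < -_ROW_TOL):
            raise TransitionError("death occupancy decreased")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


# ---------------------------------------------------------------------------
# per-cycle probability ingredients
# ---------------------------------------------------------------------------

def arm_survival(params: ParameterSet, arm: str) -> Callable:
    """PSA-progression-free survival function for one arm.

    The reference arm follows the configured parametric curve; the other arm
    is derived through S**HR on the cumulative-hazard scale.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; choose from {ARMS}")
    sv = params.survival
    fit = SurvivalFit(family=sv.family, shape=sv.shape, scale=sv.scale,
                      log_likelihood=np.nan, aic=np.nan, n_params=2)
    if arm == sv.reference_arm:
        return fit.survival
    return apply_hazard_ratio(fit, sv.hr_psa_recurrence)


def progression_probs(params: ParameterSet, arm: str,
                      n_cycles: int | None = None) -> np.ndarray:
    """Per-cycle first-line progression probabilities for cycles 0..N-1."""
    n = params.n_cycles if n_cycles is None else n_cycles
    return per_cycle_progression_probs(
        arm_survival(params, arm), n, params.settings.cycle_length_days)


def _mortality_model(params: ParameterSet) -> LogisticMortalityModel:
    m = params.mortality
    return LogisticMortalityModel(
        asymptote=m.logistic_asymptote, steepness=m.logistic_steepness,
        midpoint=m.logistic_midpoint, age_min=m.age_min, age_max=m.age_max)


def death_probs(params: ParameterSet,
                n_cycles: int | None = None) -> np.ndarray:
    """(n_cycles, n_states) per-cycle death probabilities by attained age."""
    n = params.n_cycles if n_cycles is None else n_cycles
    model = _mortality_model(params)
    ages = params.age_at(np.arange(n, dtype=float))
    c = params.settings.cycle_length_days
    out = np.zeros((n, N_STATES))
    for j, state in enumerate(STATES):
        if state == "death":
            continue
        hr = params.mortality.hazard_ratio_for(state)
        out[:, j] = cycle_death_prob(model, ages, hr, c)
    return out


def _exit_schedule(params: ParameterSet, arm: str,
                   n_cycles: int) -> list[tuple[int, np.ndarray, dict[int, float]]]:
    """(state index, per-cycle exit probability, destination split) triples."""
    sl = params.second_line
    rr = sl.response_rates
    const = lambda p: np.full(n_cycles, float(p))
    skip = sl.chemo_skip_fraction
    return [
        (IDX["first_line"], progression_probs(params, arm, n_cycles),
         {IDX["aa_addition"]: 1.0}),
        (IDX["aa_addition"], const(1.0 - rr["aa_addition"]),
         {IDX["aa_withdrawal"]: 1.0}),
        (IDX["aa_withdrawal"], const(1.0 - rr["aa_withdrawal"]),
         {IDX["abiraterone"]: skip, IDX["docetaxel"]: 1.0 - skip}),
        (IDX["docetaxel"], const(1.0 - rr["docetaxel"]),
         {IDX["abiraterone"]: 1.0}),
        (IDX["abiraterone"], const(1.0 - rr["abiraterone"]),
         {IDX["post_abiraterone"]: 1.0}),
        (IDX["post_abiraterone"], const(sl.post_abiraterone_exit),
         {IDX["supportive_care"]: 1.0}),
        (IDX["supportive_care"], const(sl.supportive_exit),
         {IDX["palliative_care"]: 1.0}),
        (IDX["palliative_care"], const(0.0), {}),
    ]


def transition_matrices(params: ParameterSet, arm: str,
                        n_cycles: int | None = None) -> np.ndarray:
    """Stacked (n_cycles, 9, 9) transition matrices, validated row-stochastic."""
    n = params.n_cycles if n_cycles is None else n_cycles
    pd_mat = death_probs(params, n)
    P = np.zeros((n, N_STATES, N_STATES))
    for s, exit_p, dests in _exit_schedule(params, arm, n):
        if np.any(exit_p < -_ROW_TOL) or np.any(exit_p > 1 + _ROW_TOL):
            raise TransitionError(f"exit probability out of [0,1] for {STATES[s]}")
        alive = 1.0 - pd_mat[:, s]
        P[:, s, s] = (1.0 - exit_p) * alive
        for d, frac in dests.items():
            if not 0.0 <= frac <= 1.0:
                raise TransitionError("destination fraction out of [0,1]")
            P[:, s, d] += exit_p * frac * alive
        P[:, s, DEATH] += pd_mat[:, s]
    P[:, DEATH, DEATH] = 1.0
    rows = P.sum(axis=2)
    if np.any(np.abs(rows - 1.0) > _ROW_TOL):
        raise TransitionError("transition rows do not sum to 1")
    if np.any(P < -_ROW_TOL) or np.any(P > 1 + _ROW_TOL):
        raise TransitionError("transition probabilities outside [0,1]")
    return P


def build_transition_matrix(params: ParameterSet, arm: str, cycle: int,
                            age: float | None = None) -> np.ndarray:
    """Single-cycle transition matrix (a validated slice of the stack).

    ``age`` defaults to the attained age implied by the cycle; passing a
    different age is supported by shifting the starting age accordingly.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    p = params
    if age is not None and abs(age - params.age_at(cycle)) > 1e-9:
        p = params.with_edits(
            {"settings.start_age":
             age - cycle * params.settings.cycle_length_days / DAYS_PER_YEAR})
    return transition_matrices(p, arm, cycle + 1)[cycle]


def run_cohort(params: ParameterSet, arm: str) -> CohortTrace:
    """Propagate a unit cohort starting in first-line therapy.

    Returns a trace with floor(horizon * 365.25 / cycle_length) cycles plus
    the initial row; deterministic given the parameters.
    """
    params.validate()
    n = params.n_cycles
    P = transition_matrices(params, arm, n)
    occ = np.zeros((n + 1, N_STATES))
    occ[0, IDX["first_line"]] = 1.0
    for i in range(n):
        occ[i + 1] = occ[i] @ P[i]
    trace = CohortTrace(occupancy=occ, arm=arm,
                        cycle_length_days=params.settings.cycle_length_days,
                        start_age=params.settings.start_age)
    trace.validate()
    return trace


def microsimulate(params: ParameterSet, arm: str, n_patients: int,
                  seed: int) -> CohortTrace:
    """Individual-level simulation of the same process (validation oracle).

    Simulates ``n_patients`` independent patients through the identical
    per-cycle transition matrices and returns their occupancy fractions in
    CohortTrace form.  The cohort trace is the exact expectation of this
    simulation, so the two agree within Monte-Carlo error.
    """
    n = params.n_cycles
    P = transition_matrices(params, arm, n)
    cum = np.cumsum(P, axis=2)
    rng = np.random.default_rng(seed)
    state = np.full(n_patients, IDX["first_line"], dtype=np.int64)
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = np.bincount(state, minlength=N_STATES) / n_patients
    for i in range(n):
        u = rng.random(n_patients)
        nxt = np.empty_like(state)
        for s in range(N_STATES):
            mask = state == s
            if not mask.any():
                continue
            nxt[mask] = np.searchsorted(cum[i, s], u[mask], side="right")
        state = np.minimum(nxt, N_STATES - 1)
        occ[i + 1] = np.bincount(state, minlength=N_STATES) / n_patients
    return CohortTrace(occupancy=occ, arm=arm,
                       cycle_length_days=params.settings.cycle_length_days,
                       start_age=params.settings.start_age)
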