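"""Synthetic inputs with known ground truth.

Generates everything the pipeline consumes: right-censored time-to-PSA-
progression data drawn from a parametric survival model with a
proportional-hazards treatment effect (standing in for trial-level
individual-patient data, with administrative censoring at the 12-month trial
window), an age-specific mortality table with logistic shape (standing in
for census life-table data), and the complete parameter fixture carrying
every published table value plus provenance-tagged placeholder values for
parameters the source never reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lifetable import LifeTable
from .params import ParameterSet
from .survival import FAMILIES, SurvivalDataset

__all__ = [
    "GeneratorSpec",
    "gen_survival",
    "gen_life_table",
    "gen_fixture",
    "survival_quantile",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth recipe for a two-arm censored survival sample.

    Censoring: administrative at ``t_max`` days (default 364, a 12-month
    follow-up window of thirteen 28-day cycles) plus a ``dropout_frac``
    chance per subject of uniform early dropout on (0, t_max).
    """

    family: str = "loglogistic"
    shape: float = 1.5
    scale: float = 0.005
    n: int = 2000
    t_max: float = 364.0
    dropout_frac: float = 0.2
    hazard_ratio: float = 0.66   # treated vs reference arm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if not 0.0 <= self.dropout_frac < 1.0:
            raise ValueError("dropout fraction must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")


def survival_quantile(family: str, shape: float | None, scale: float,
                      s: np.ndarray) -> np.ndarray:
    """Time t at which S(t) = s (inverse survival function).

    For the log-logistic S = 1/(1 + lambda t**gamma) this is
    t = ((1 - s) / (lambda s)) ** (1/gamma).
    """
    s = np.asarray(s, dtype=float)
    if family == "exponential":
        return -np.log(s) / scale
    if family == "weibull":
        return (-np.log(s) / scale) ** (1.0 / shape)
    if family == "loglogistic":
        return ((1.0 - s) / (scale * s)) ** (1.0 / shape)
    if family == "lognormal":
        return np.exp(scale + shape * stats.norm.isf(s))
    if family == "gompertz":
        inner = 1.0 - shape * np.log(s) / scale
        if np.any(inner <= 0):
            raise ValueError("quantile beyond the Gompertz plateau")
        return np.log(inner) / shape
    raise ValueError(f"unknown family {family!r}")


def gen_survival(spec: GeneratorSpec) -> tuple[SurvivalDataset, SurvivalDataset]:
    """(reference arm, treated arm) censored datasets by inverse-CDF sampling.

    The treated arm is drawn from S_ref**HR: with U ~ Uniform(0, 1),
    T = Q_ref(U ** (1/HR)).  Bit-reproducible given the seed.
    """
    rng = np.random.default_rng(spec.seed)

    def one_arm(hr: float) -> SurvivalDataset:
        u = rng.uniform(size=spec.n)
        t = survival_quantile(spec.family, spec.shape, spec.scale,
                              u ** (1.0 / hr))
        t = np.maximum(t, 1e-9)
        cens = np.full(spec.n, spec.t_max)
        drop = rng.uniform(size=spec.n) < spec.dropout_frac
        cens[drop] = rng.uniform(0.0, spec.t_max, size=int(drop.sum()))
        cens = np.maximum(cens, 1e-9)
        obs = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        return SurvivalDataset(obs, event)

    reference = one_arm(1.0)
    treated = one_arm(spec.hazard_ratio)
    return reference, treated


def gen_life_table(L: float = 0.7, k: float = 0.09, a0: float = 97.0,
                   age_range: tuple[int, int] = (40, 100)) -> LifeTable:
    """Logistic-shaped annual mortality table on integer ages.

    qx(a) = L / (1 + exp(-k (a - a0))), clipped to [0, 0.999].
    """
    if not 0.0 < L <= 1.0 or k <= 0:
        raise ValueError("invalid logistic parameters")
    ages = np.arange(age_range[0], age_range[1] + 1)
    qx = np.clip(L / (1.0 + np.exp(-k * (ages - a0))), 0.0, 0.999)
    return LifeTable(ages.astype(float), qx)


# Provenance map of the default fixture.  "printed" marks values carried
# verbatim from the published model tables; "synthetic" marks placeholder
# values for parameters the source never reports.
_PROVENANCE: dict[str, str] = {
    "settings.cycle_length_days": "printed",
    "settings.horizon_years": "printed",
    "settings.discount_rate_cost": "printed",
    "settings.discount_rate_effect": "printed",
    "settings.start_age": "printed",
    "survival.family": "printed",
    "survival.shape": "synthetic",
    "survival.scale": "synthetic",
    "survival.hr_psa_recurrence": "synthetic",
    "second_line.response_rates": "printed",
    "second_line.chemo_skip_fraction": "printed",
    "second_line.post_abiraterone_exit": "synthetic",
    "second_line.supportive_exit": "synthetic",
    "mortality.logistic_asymptote": "synthetic",
    "mortality.logistic_steepness": "synthetic",
    "mortality.logistic_midpoint": "synthetic",
    "mortality.hr_post_progression": "printed",
    "drug_costs.degarelix_first_cycle": "printed",
    "drug_costs.degarelix_maintenance": "printed",
    "drug_costs.leuprorelin_per_cycle": "printed",
    "drug_costs.flare_cover_daily": "printed",
    "drug_costs.enzalutamide_daily": "printed",
    "drug_costs.docetaxel_daily": "printed",
    "drug_costs.abiraterone_daily": "printed",
    "drug_costs.dexamethasone_daily": "printed",
    "drug_costs.adt_during_aa_states": "synthetic",
    "management_costs.post_abiraterone_cycle": "printed",
    "management_costs.supportive_cycle": "printed",
    "management_costs.palliative_cycle": "printed",
    "management_costs.gp_visit": "printed",
    "management_costs.bone_scan": "printed",
    "management_costs.ct_scan": "printed",
    "management_costs.mri": "printed",
    "management_costs.blood_test": "printed",
    "admin_frequencies": "synthetic",
    "ae_costs": "printed",
    "utilities": "printed",
    "willingness.gdp_per_capita": "printed",
    "willingness.wtp_multiplier": "printed",
}
# Per-event tags: costs and decrements are published, incidences and severity
# mixes are not.
for _i in range(7):
    _PROVENANCE[f"adverse_events.{_i}.disutility"] = "printed"
    _PROVENANCE[f"adverse_events.{_i}.incidence"] = "synthetic"
    _PROVENANCE[f"adverse_events.{_i}.cost_mix"] = "synthetic"


def gen_fixture(seed: int = 0) -> ParameterSet:
    """The complete model-parameter fixture.

    All published values are fixed constants independent of the seed; the
    seed is accepted for interface symmetry with the stochastic generators
    (the fixture itself contains no random draws).  Placeholder values are
    tagged ``synthetic`` in the provenance map.
    """
    params = ParameterSet(provenance=dict(_PROVENANCE))
    params.validate()
    return params
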