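"""Model parameter containers and dot-path addressing.

The complete input to the cost-utility model is a single :class:`ParameterSet`:
global settings (cycle length, horizon, discounting, starting age), first-line
PSA-progression parameters, second-line response rates, background mortality,
drug prices, management and adverse-event costs, and state utilities.

Every sensitivity analysis — scenario edits, one-way perturbations, and
probabilistic draws — is expressed as a perturbation of a ParameterSet through
dot-addressed paths such as ``"drug_costs.degarelix_maintenance"`` or
``"second_line.response_rates.docetaxel"``.  Each field additionally carries a
provenance tag (``printed`` for values taken verbatim from published tables,
``synthetic`` for placeholder values the source never reports) so tests can
assert on published values only.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import yaml

#: Health states of the cohort model, in transition-matrix column order.
#: The chain runs first-line castration therapy -> anti-androgen addition ->
#: anti-androgen withdrawal -> {abiraterone (chemo-skip branch) | docetaxel}
#: -> abiraterone -> post-abiraterone continued treatment -> supportive care
#: -> palliative care; every living state also transitions to death.
STATES: tuple[str, ...] = (
    "first_line",
    "aa_addition",
    "aa_withdrawal",
    "docetaxel",
    "abiraterone",
    "post_abiraterone",
    "supportive_care",
    "palliative_care",
    "death",
)

#: States in which patients are on active oncological treatment (adverse
#: events are accrued here by default).
TREATMENT_STATES: tuple[str, ...] = STATES[:6]

ARMS: tuple[str, str] = ("degarelix", "leuprorelin")

DAYS_PER_YEAR = 365.25


class InvalidParameterError(ValueError):
    """A ParameterSet violates a hard invariant."""


@dataclass
class Settings:
    """Global model settings (28-day cycles, 30-year horizon, 5%/y discount)."""

    cycle_length_days: float = 28.0
    horizon_years: float = 30.0
    discount_rate_cost: float = 0.05
    discount_rate_effect: float = 0.05
    start_age: float = 68.0
    half_cycle_correction: bool = False


@dataclass
class FirstLineProgression:
    """Parametric time-to-PSA-progression curve for the reference arm.

    The reference (leuprorelin) arm follows the fitted parametric survival
    curve S(t); the treated (degarelix) arm is derived through a
    proportional-hazards effect, S(t)**hr_psa_recurrence.
    """

    family: str = "loglogistic"
    shape: float = 1.3          # gamma, dimensionless
    scale: float = 7.7e-5       # lambda, per day**gamma
    hr_psa_recurrence: float = 0.66  # degarelix vs leuprorelin hazard ratio
    reference_arm: str = "leuprorelin"


@dataclass
class SecondLine:
    """Second-line persistence and branching parameters.

    ``response_rates`` are per-cycle probabilities of remaining on each
    second-line treatment; patients leave at (1 - rate) per cycle.
    ``chemo_skip_fraction`` is the share of anti-androgen-withdrawal leavers
    who skip chemotherapy and move directly to abiraterone.
    """

    response_rates: dict[str, float] = field(
        default_factory=lambda: {
            "aa_addition": 0.83,
            "aa_withdrawal": 0.83,
            "docetaxel": 0.91,
            "abiraterone": 0.84,
        }
    )
    chemo_skip_fraction: float = 0.35
    post_abiraterone_exit: float = 0.17   # per-cycle, to supportive care
    supportive_exit: float = 0.17         # per-cycle, to palliative care


@dataclass
class Mortality:
    """Background mortality: logistic annual-death-probability curve of age.

    q(a) = L / (1 + exp(-k (a - a0))), scaled onto 28-day cycles by a
    constant-hazard-within-year conversion.  States after first-line therapy
    carry a mortality hazard ratio (default 2.39 for every post-progression
    state; ``state_hr`` overrides per state).
    """

    logistic_asymptote: float = 0.7   # L, probability scale
    logistic_steepness: float = 0.09  # k, per year
    logistic_midpoint: float = 97.0   # a0, years
    hr_post_progression: float = 2.39
    state_hr: dict[str, float] = field(default_factory=dict)
    age_min: float = 40.0
    age_max: float = 100.0

    def hazard_ratio_for(self, state: str) -> float:
        if state == "first_line":
            return self.state_hr.get(state, 1.0)
        return self.state_hr.get(state, self.hr_post_progression)


@dataclass
class DrugCosts:
    """First- and second-line drug acquisition costs, yuan.

    The degarelix starting dose (240 mg) is charged once at cycle 0 and the
    80 mg maintenance dose from cycle 1 on.  The leuprorelin arm adds 28 days
    of anti-androgen flare cover with the first dose only.  Daily prices are
    charged as daily cost x 28 per cycle.
    """

    degarelix_first_cycle: float = 8900.0
    degarelix_maintenance: float = 3200.0
    leuprorelin_per_cycle: float = 1389.29
    flare_cover_daily: float = 169.37
    enzalutamide_daily: float = 216.67     # carried but unused by default map
    docetaxel_daily: float = 245.66
    abiraterone_daily: float = 40.162
    dexamethasone_daily: float = 0.07
    adt_during_aa_states: bool = True      # castration continues through AA states


@dataclass
class ManagementCosts:
    """Bundled state costs per cycle and per-event administration costs, yuan."""

    post_abiraterone_cycle: float = 25200.0
    supportive_cycle: float = 7500.92
    palliative_cycle: float = 5804.82
    gp_visit: float = 28.25
    bone_scan: float = 563.75
    ct_scan: float = 457.50
    mri: float = 1440.0
    blood_test: float = 369.38


@dataclass
class AdverseEvent:
    """One adverse-event category: expected cost mix, disutility, incidence.

    ``cost_mix`` maps keys of ``ParameterSet.ae_costs`` to mixing fractions
    (summing to 1); expected cost per event is the mix-weighted cost.
    ``incidence`` is a per-cycle event probability per arm, applied while the
    cohort occupies any state in ``states``.  ``disutility`` is a (negative)
    utility decrement applied for one cycle per event.
    """

    name: str
    cost_mix: dict[str, float]
    disutility: float
    incidence: dict[str, float]
    states: tuple[str, ...] = TREATMENT_STATES

    def expected_cost(self, ae_costs: dict[str, float]) -> float:
        return sum(frac * ae_costs[k] for k, frac in self.cost_mix.items())


@dataclass
class Utilities:
    """Per-state preference weights in [0, 1]."""

    first_line: float = 0.90
    aa_addition: float = 0.80
    aa_withdrawal: float = 0.80
    docetaxel: float = 0.69
    abiraterone: float = 0.69
    post_abiraterone: float = 0.69
    supportive_care: float = 0.40
    palliative_care: float = 0.40
    death: float = 0.0

    def for_state(self, state: str) -> float:
        return getattr(self, state)

    def as_vector(self) -> list[float]:
        return [self.for_state(s) for s in STATES]


@dataclass
class Willingness:
    """Cost-effectiveness threshold: a multiple of GDP per capita."""

    gdp_per_capita: float = 80976.0  # yuan, China 2021
    wtp_multiplier: float = 3.0

    @property
    def wtp(self) -> float:
        return self.wtp_multiplier * self.gdp_per_capita


def _default_admin_frequencies() -> dict[str, dict[str, float]]:
    # Expected number of each administration item per 28-day cycle per state.
    return {
        "first_line": {"gp_visit": 1.0, "blood_test": 1.0, "bone_scan": 0.08,
                       "ct_scan": 0.04, "mri": 0.02},
        "aa_addition": {"gp_visit": 1.0, "blood_test": 1.0, "bone_scan": 0.12,
                        "ct_scan": 0.06, "mri": 0.02},
        "aa_withdrawal": {"gp_visit": 1.0, "blood_test": 1.0, "bone_scan": 0.12,
                          "ct_scan": 0.06, "mri": 0.02},
        "docetaxel": {"gp_visit": 1.0, "blood_test": 2.0, "bone_scan": 0.15,
                      "ct_scan": 0.08, "mri": 0.02},
        "abiraterone": {"gp_visit": 1.0, "blood_test": 1.5, "bone_scan": 0.15,
                        "ct_scan": 0.08, "mri": 0.02},
        "post_abiraterone": {"gp_visit": 1.0, "blood_test": 1.0,
                             "bone_scan": 0.10, "ct_scan": 0.05},
        "supportive_care": {"gp_visit": 0.5, "blood_test": 0.5},
        "palliative_care": {"gp_visit": 0.5},
        "death": {},
    }


def _default_ae_costs() -> dict[str, float]:
    return {
        "scc_radiotherapy": 30000.00,
        "scc_surgery": 40000.00,
        "msk_severe_joint": 27142.86,
        "msk_severe_fracture": 21500.00,
        "msk_severe_other": 24000.00,
        "msk_moderate_joint": 16276.50,
        "msk_moderate_fracture": 15276.72,
        "msk_moderate_other": 17776.50,
        "msk_mild_joint": 14528.25,
        "msk_mild_fracture": 7417.14,
        "msk_mild_other": 8278.25,
        "cv_fatal": 28723.96,
        "cv_nonfatal": 18369.28,
    }


_THIRD = 1.0 / 3.0


def _default_adverse_events() -> list[AdverseEvent]:
    return [
        AdverseEvent("scc_severe", {"scc_radiotherapy": 0.5, "scc_surgery": 0.5},
                     -0.20, {"degarelix": 0.0004, "leuprorelin": 0.0004}),
        AdverseEvent("scc_mild", {"scc_radiotherapy": 0.5, "scc_surgery": 0.5},
                     -0.37, {"degarelix": 0.0004, "leuprorelin": 0.0004}),
        AdverseEvent("msk_severe",
                     {"msk_severe_joint": _THIRD, "msk_severe_fracture": _THIRD,
                      "msk_severe_other": _THIRD},
                     -0.37, {"degarelix": 0.0010, "leuprorelin": 0.0010}),
        AdverseEvent("msk_moderate",
                     {"msk_moderate_joint": _THIRD, "msk_moderate_fracture": _THIRD,
                      "msk_moderate_other": _THIRD},
                     -0.26, {"degarelix": 0.0015, "leuprorelin": 0.0015}),
        AdverseEvent("msk_mild",
                     {"msk_mild_joint": _THIRD, "msk_mild_fracture": _THIRD,
                      "msk_mild_other": _THIRD},
                     -0.12, {"degarelix": 0.0025, "leuprorelin": 0.0025}),
        AdverseEvent("cv_fatal", {"cv_fatal": 1.0},
                     -0.73, {"degarelix": 0.0002, "leuprorelin": 0.0003}),
        AdverseEvent("cv_nonfatal", {"cv_nonfatal": 1.0},
                     -0.73, {"degarelix": 0.0013, "leuprorelin": 0.0020}),
    ]


@dataclass
class ParameterSet:
    """The complete model input; every analysis perturbs one of these."""

    settings: Settings = field(default_factory=Settings)
    survival: FirstLineProgression = field(default_factory=FirstLineProgression)
    second_line: SecondLine = field(default_factory=SecondLine)
    mortality: Mortality = field(default_factory=Mortality)
    drug_costs: DrugCosts = field(default_factory=DrugCosts)
    management_costs: ManagementCosts = field(default_factory=ManagementCosts)
    admin_frequencies: dict[str, dict[str, float]] = field(
        default_factory=_default_admin_frequencies)
    ae_costs: dict[str, float] = field(default_factory=_default_ae_costs)
    adverse_events: list[AdverseEvent] = field(
        default_factory=_default_adverse_events)
    utilities: Utilities = field(default_factory=Utilities)
    willingness: Willingness = field(default_factory=Willingness)
    provenance: dict[str, str] = field(default_factory=dict)

    # ---- derived quantities -------------------------------------------------

    @property
    def n_cycles(self) -> int:
        """Number of maintenance cycles after cycle 0 (391 for the defaults)."""
        return int(math.floor(
            self.settings.horizon_years * DAYS_PER_YEAR
            / self.settings.cycle_length_days))

    def age_at(self, cycle: int | float) -> float:
        """Attained cohort age at the start of a cycle."""
        return (self.settings.start_age
                + cycle * self.settings.cycle_length_days / DAYS_PER_YEAR)

    # ---- dot-path addressing ------------------------------------------------

    def get(self, path: str) -> Any:
        """Return the value at a dot-addressed path."""
        obj: Any = self
        for part in path.split("."):
            obj = _step(obj, part, path)
        return obj

    def set(self, path: str, value: Any) -> None:
        """Assign a value at a dot-addressed path, in place."""
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = _step(obj, part, path)
        last = parts[-1]
        if isinstance(obj, dict):
            if last not in obj:
                raise KeyError(f"unknown parameter path: {path!r}")
            obj[last] = value
        elif isinstance(obj, list):
            obj[int(last)] = value
        elif dataclasses.is_dataclass(obj):
            if not hasattr(obj, last):
                raise KeyError(f"unknown parameter path: {path!r}")
            setattr(obj, last, value)
        else:
            raise KeyError(f"cannot address into {type(obj).__name__} at {path!r}")

    def with_edits(self, edits: dict[str, Any]) -> "ParameterSet":
        """Return a deep copy with the given path -> value edits applied."""
        out = copy.deepcopy(self)
        for path, value in edits.items():
            out.set(path, value)
        return out

    # ---- provenance ---------------------------------------------------------

    def provenance_of(self, path: str) -> str:
        """Provenance tag of a path: exact entry, else longest tagged prefix."""
        if path in self.provenance:
            return self.provenance[path]
        parts = path.split(".")
        for i in range(len(parts) - 1, 0, -1):
            prefix = ".".join(parts[:i])
            if prefix in self.provenance:
                return self.provenance[prefix]
        return "untagged"

    def printed_paths(self) -> list[str]:
        return sorted(p for p, t in self.provenance.items() if t == "printed")

    def synthetic_paths(self) -> list[str]:
        return sorted(p for p, t in self.provenance.items() if t == "synthetic")

    # ---- validation ---------------------------------------------------------

    def validate(self, strict: bool = True) -> list[str]:
        """Check invariants; return warnings, raising on violations if strict."""
        problems: list[str] = []
        s = self.settings
        if s.cycle_length_days <= 0 or s.horizon_years <= 0:
            problems.append("cycle length and horizon must be positive")
        if s.discount_rate_cost < 0 or s.discount_rate_effect < 0:
            problems.append("discount rates must be non-negative")
        if self.survival.scale <= 0 or self.survival.shape <= 0:
            problems.append("survival scale and shape must be positive")
        if self.survival.hr_psa_recurrence <= 0:
            problems.append("PSA-recurrence hazard ratio must be positive")
        for name, rate in self.second_line.response_rates.items():
            if not 0.0 <= rate <= 1.0:
                problems.append(f"response rate {name} outside [0,1]")
        for p in (self.second_line.chemo_skip_fraction,
                  self.second_line.post_abiraterone_exit,
                  self.second_line.supportive_exit):
            if not 0.0 <= p <= 1.0:
                problems.append("second-line fractions must lie in [0,1]")
        m = self.mortality
        if not 0.0 <= m.logistic_asymptote <= 1.0 or m.logistic_steepness <= 0:
            problems.append("logistic mortality parameters out of domain")
        if m.hr_post_progression <= 0:
            problems.append("mortality hazard ratio must be positive")
        for f in dataclasses.fields(DrugCosts):
            v = getattr(self.drug_costs, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                problems.append(f"drug cost {f.name} negative")
        for f in dataclasses.fields(ManagementCosts):
            if getattr(self.management_costs, f.name) < 0:
                problems.append(f"management cost {f.name} negative")
        for k, v in self.ae_costs.items():
            if v < 0:
                problems.append(f"adverse-event cost {k} negative")
        for st in STATES:
            u = self.utilities.for_state(st)
            if not 0.0 <= u <= 1.0:
                problems.append(f"utility of {st} outside [0,1]")
        for ae in self.adverse_events:
            if not -1.0 <= ae.disutility <= 0.0:
                problems.append(f"AE decrement {ae.name} outside [-1,0]")
            mix = sum(ae.cost_mix.values())
            if abs(mix - 1.0) > 1e-9:
                problems.append(f"AE cost mix {ae.name} does not sum to 1")
            for arm, inc in ae.incidence.items():
                if not 0.0 <= inc <= 1.0:
                    problems.append(f"AE incidence {ae.name}/{arm} outside [0,1]")
            for st in ae.states:
                if st not in STATES:
                    problems.append(f"AE {ae.name} references unknown state {st}")
        if self.willingness.gdp_per_capita <= 0:
            problems.append("GDP per capita must be positive")
        if strict and problems:
            raise InvalidParameterError("; ".join(problems))
        return problems

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for ae in d["adverse_events"]:
            ae["states"] = list(ae["states"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        return cls(
            settings=Settings(**d.get("settings", {})),
            survival=FirstLineProgression(**d.get("survival", {})),
            second_line=SecondLine(**d.get("second_line", {})),
            mortality=Mortality(**d.get("mortality", {})),
            drug_costs=DrugCosts(**d.get("drug_costs", {})),
            management_costs=ManagementCosts(**d.get("management_costs", {})),
            admin_frequencies=d.get("admin_frequencies",
                                    _default_admin_frequencies()),
            ae_costs=d.get("ae_costs", _default_ae_costs()),
            adverse_events=[
                AdverseEvent(name=a["name"], cost_mix=a["cost_mix"],
                             disutility=a["disutility"],
                             incidence=a["incidence"],
                             states=tuple(a.get("states", TREATMENT_STATES)))
                for a in d.get("adverse_events", [])
            ] or _default_adverse_events(),
            utilities=Utilities(**d.get("utilities", {})),
            willingness=Willingness(**d.get("willingness", {})),
            provenance=d.get("provenance", {}),
        )

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def sha256(self) -> str:
        """Stable hash of the resolved parameter values (for report headers)."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()


def _step(obj: Any, part: str, path: str) -> Any:
    if isinstance(obj, dict):
        if part not in obj:
            raise KeyError(f"unknown parameter path: {path!r}")
        return obj[part]
    if isinstance(obj, (list, tuple)):
        try:
            return obj[int(part)]
        except (ValueError, IndexError) as exc:
            raise KeyError(f"unknown parameter path: {path!r}") from exc
    if dataclasses.is_dataclass(obj):
        if not hasattr(obj, part):
            raise KeyError(f"unknown parameter path: {path!r}")
        return getattr(obj, part)
    raise KeyError(f"cannot address into {type(obj).__name__} at {path!r}")
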