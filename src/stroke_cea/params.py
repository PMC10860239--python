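"""Model parameter containers, configuration I/O and validation.

The cohort model describes patients aged 60 with acute ischemic stroke (AIS)
who receive a 14-day course of a brain cytoprotective drug and are classified
on day 90 by modified Rankin Scale (mRS) into three health states:

* ``MRS01`` — mRS 0-1, no disability,
* ``MRS25`` — mRS 2-5, disability,
* ``DEAD``  — mRS 6, absorbing.

All monetary values are 2021 Chinese Yuan (CNY).  Parameters are loaded from
a YAML configuration file; a complete default file carrying the base-case
inputs (day-90 outcome distributions, recurrence schedule, hazard ratios,
age-specific mortality, costs, utilities and sensitivity ranges) ships with
the package under ``stroke_cea/data/default_config.yaml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "STATE_ORDER",
    "StateDistribution",
    "DrugRegimen",
    "ArmSpec",
    "RecurrenceSchedule",
    "MortalityBand",
    "MortalityTable",
    "CostInputs",
    "UtilityInputs",
    "TransitionInputs",
    "SensitivitySpec",
    "ModelParameters",
    "ValidationReport",
    "ConfigError",
    "load_model_config",
    "default_config_path",
    "validate_parameters",
    "adjust_cost_to_base_year",
    "params_to_dict",
    "save_model_config",
]


class ConfigError(ValueError):
    """Raised when a configuration file is missing fields or malformed."""


class HealthState(str, Enum):
    """The three mRS-based health states of the model."""

    MRS01 = "MRS01"
    MRS25 = "MRS25"
    DEAD = "DEAD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALIVE_STATES: tuple[HealthState, HealthState] = (HealthState.MRS01, HealthState.MRS25)
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.MRS01,
    HealthState.MRS25,
    HealthState.DEAD,
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StateDistribution:
    """Probability mass over the three health states."""

    mrs01: float
    mrs25: float
    dead: float = 0.0

    def of(self, state: HealthState) -> float:
        return {
            HealthState.MRS01: self.mrs01,
            HealthState.MRS25: self.mrs25,
            HealthState.DEAD: self.dead,
        }[state]

    def as_array(self):
        import numpy as np

        return np.array([self.mrs01, self.mrs25, self.dead], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StateDistribution":
        return cls(float(arr[0]), float(arr[1]), float(arr[2]))

    def problems(self) -> list[str]:
        out = []
        total = self.mrs01 + self.mrs25 + self.dead
        if abs(total - 1.0) > _SUM_TOL:
            out.append(f"distribution sums to {total:.10g}, expected 1")
        for state in STATE_ORDER:
            v = self.of(state)
            if not (0.0 <= v <= 1.0):
                out.append(f"probability for {state.value} is {v}, outside [0, 1]")
        return out


@dataclass(frozen=True)
class DrugRegimen:
    """Dosing and price of one study drug.

    ``unit_price`` is CNY per piece/bottle; the 14-day course cost is
    ``unit_price * units_per_dose * doses_per_day * duration_days``.
    """

    unit_price: float
    units_per_dose: int
    doses_per_day: int
    duration_days: int = 14

    def daily_cost(self) -> float:
        return self.unit_price * self.units_per_dose * self.doses_per_day

    def course_cost(self) -> float:
        return self.daily_cost() * self.duration_days


@dataclass(frozen=True)
class ArmSpec:
    """A treatment arm: label, day-90 mRS distribution and drug regimen."""

    name: str
    day90_distribution: StateDistribution
    regimen: DrugRegimen


@dataclass(frozen=True)
class RecurrenceSchedule:
    """Annual stroke-recurrence probabilities by year since the index event.

    ``annual_rates[k]`` applies to Markov cycle ``k + 1`` (year ``k``-to-
    ``k+1``); ``terminal_rate`` applies to every later cycle.
    """

    annual_rates: tuple[float, ...]
    terminal_rate: float

    def rate_for_cycle(self, cycle_index: int) -> float:
        if cycle_index < 1:
            raise ValueError("recurrence rates apply to Markov cycles >= 1")
        if cycle_index <= len(self.annual_rates):
            return self.annual_rates[cycle_index - 1]
        return self.terminal_rate


@dataclass(frozen=True)
class MortalityBand:
    lower: float
    upper: float
    rate: float


@dataclass(frozen=True)
class MortalityTable:
    """Age-banded annual all-cause death probabilities."""

    bands: tuple[MortalityBand, ...]

    def rate_at(self, age: float) -> float:
        for b in self.bands:
            if b.lower <= age < b.upper:
                return b.rate
        raise ValueError(f"age {age} not covered by the mortality table")

    def covers(self, age: float) -> bool:
        return any(b.lower <= age < b.upper for b in self.bands)

    @property
    def max_age(self) -> float:
        return max(b.upper for b in self.bands)


@dataclass(frozen=True)
class CostInputs:
    """Direct medical costs (2021 CNY).

    ``hospitalization`` is the cost of one inpatient episode by mRS state
    (the DEAD entry is the cost of a fatal stroke admission);
    ``annual_rehab_secondary_prevention`` is the yearly rehabilitation plus
    secondary-prevention cost of alive states.
    """

    hospitalization: dict[HealthState, float]
    annual_rehab_secondary_prevention: dict[HealthState, float]
    mean_length_of_stay_days: float
    cost_year: int = 2021

    def rehab(self, state: HealthState) -> float:
        return self.annual_rehab_secondary_prevention.get(state, 0.0)


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities (QALY weights per year); DEAD is fixed at 0."""

    utilities: dict[HealthState, float]
    recurrence_disutility: float

    def of(self, state: HealthState) -> float:
        if state is HealthState.DEAD:
            return 0.0
        return self.utilities[state]


@dataclass(frozen=True)
class TransitionInputs:
    """Death hazard ratios and post-recurrence destination distributions.

    ``post_recurrence[s][d]`` is the probability that a patient in state
    ``s`` who suffers a recurrent stroke ends the event in state ``d``
    (recurrences never improve the mRS state: no MRS25 -> MRS01 mass).
    """

    death_hazard_ratio: dict[HealthState, float]
    post_recurrence: dict[HealthState, dict[HealthState, float]]


@dataclass(frozen=True)
class SensitivitySpec:
    """One tunable parameter: its location, plausible range and PSA family.

    ``family`` is one of ``beta`` (utilities), ``gamma`` (costs),
    ``lognormal`` (hazard ratios) or ``fixed`` (varied in one-way analysis
    only, never sampled in the probabilistic analysis).
    """

    path: str
    low: float
    high: float
    family: str


@dataclass(frozen=True)
class ModelParameters:
    """Complete, validated input set for the two-stage cohort model."""

    start_age: float
    horizon_years: int
    cycle_length_years: float
    discount_rate: float
    short_term_days: int
    wtp_gdp_per_capita: float
    wtp_multipliers: tuple[float, ...]
    arms: dict[str, ArmSpec]
    costs: CostInputs
    utilities: UtilityInputs
    transitions: TransitionInputs
    recurrence: RecurrenceSchedule
    mortality: MortalityTable
    sensitivity: tuple[SensitivitySpec, ...] = ()
    markov_state_costs: str = "off"  # off | on | mrs25_only
    recurrence_event_costs: bool = True
    markov_death_costs: bool = True
    cycle0_fill: str = "calendar-only"  # calendar-only | accrue

    @property
    def wtp_thresholds(self) -> tuple[float, ...]:
        return tuple(m * self.wtp_gdp_per_capita for m in self.wtp_multipliers)


@dataclass
class ValidationReport:
    """Structured list of invariant violations found in a parameter set."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, fieldname: str, severity: str, message: str) -> None:
        self.entries.append((fieldname, severity, message))

    @property
    def errors(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[1] == "error"]

    @property
    def warnings(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[1] == "warning"]

    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            [
                {"field": f, "severity": s, "message": m}
                for f, s, m in self.entries
            ],
            indent=2,
        )


# ---------------------------------------------------------------------------
# Loading


def default_config_path() -> Path:
    """Path of the packaged base-case configuration file."""
    return Path(resources.files("stroke_cea").joinpath("data/default_config.yaml"))


def _require(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if key not in mapping or mapping[key] is None:
        raise ConfigError(f"missing required field '{key}' in section '{context}'")
    return mapping[key]


def _number(value: Any, where: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"malformed number {value!r} at '{where}'") from exc


def _state_map(raw: Mapping[str, Any], where: str) -> dict[HealthState, float]:
    out: dict[HealthState, float] = {}
    for key, val in raw.items():
        try:
            state = HealthState[key]
        except KeyError as exc:
            raise ConfigError(f"unknown health state '{key}' at '{where}'") from exc
        out[state] = _number(val, f"{where}.{key}")
    return out


def _parse_distribution(raw: Mapping[str, Any], where: str) -> StateDistribution:
    m = _state_map(raw, where)
    return StateDistribution(
        m.get(HealthState.MRS01, 0.0),
        m.get(HealthState.MRS25, 0.0),
        m.get(HealthState.DEAD, 0.0),
    )


def _parse_regimen(raw: Mapping[str, Any], where: str) -> DrugRegimen:
    return DrugRegimen(
        unit_price=_number(_require(raw, "unit_price", where), f"{where}.unit_price"),
        units_per_dose=int(_require(raw, "units_per_dose", where)),
        doses_per_day=int(_require(raw, "doses_per_day", where)),
        duration_days=int(raw.get("duration_days", 14)),
    )


def load_model_config(path: str | Path | None = None) -> ModelParameters:
    """Load model parameters from a YAML config (default: packaged base case).

    Raises :class:`ConfigError` naming the offending field when a required
    section is missing or a number fails to parse.  No unit conversion is
    performed.
    """
    if path is None:
        path = default_config_path()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return params_from_dict(raw)


def params_from_dict(raw: Mapping[str, Any]) -> ModelParameters:
    """Build :class:`ModelParameters` from a parsed configuration mapping."""
    for section in ("model", "costs", "utilities", "transitions", "recurrence",
                    "mortality", "arms"):
        if section not in raw:
            raise ConfigError(f"missing required field '{section}' (top-level section)")

    model = raw["model"]
    costs_raw = raw["costs"]
    util_raw = raw["utilities"]
    trans_raw = raw["transitions"]
    rec_raw = raw["recurrence"]
    mort_raw = raw["mortality"]
    arms_raw = raw["arms"]

    arms: dict[str, ArmSpec] = {}
    for role in ("intervention", "comparator"):
        arm = _require(arms_raw, role, "arms")
        arms[role] = ArmSpec(
            name=str(_require(arm, "name", f"arms.{role}")),
            day90_distribution=_parse_distribution(
                _require(arm, "day90_distribution", f"arms.{role}"),
                f"arms.{role}.day90_distribution",
            ),
            regimen=_parse_regimen(
                _require(arm, "regimen", f"arms.{role}"), f"arms.{role}.regimen"
            ),
        )

    bands = tuple(
        MortalityBand(
            lower=_number(_require(b, "lower", "mortality"), "mortality.lower"),
            upper=_number(_require(b, "upper", "mortality"), "mortality.upper"),
            rate=_number(_require(b, "rate", "mortality"), "mortality.rate"),
        )
        for b in _require(mort_raw, "bands", "mortality")
    )

    post_rec_raw = _require(trans_raw, "post_recurrence", "transitions")
    post_recurrence = {
        HealthState[s]: _state_map(d, f"transitions.post_recurrence.{s}")
        for s, d in post_rec_raw.items()
    }

    sens = tuple(
        SensitivitySpec(
            path=str(_require(s, "path", "sensitivity")),
            low=_number(_require(s, "low", "sensitivity"), "sensitivity.low"),
            high=_number(_require(s, "high", "sensitivity"), "sensitivity.high"),
            family=str(_require(s, "family", "sensitivity")),
        )
        for s in raw.get("sensitivity", [])
    )

    return ModelParameters(
        start_age=_number(_require(model, "start_age", "model"), "model.start_age"),
        horizon_years=int(_require(model, "horizon_years", "model")),
        cycle_length_years=_number(model.get("cycle_length_years", 1.0),
                                   "model.cycle_length_years"),
        discount_rate=_number(_require(model, "discount_rate", "model"),
                              "model.discount_rate"),
        short_term_days=int(model.get("short_term_days", 90)),
        wtp_gdp_per_capita=_number(_require(model, "wtp_gdp_per_capita", "model"),
                                   "model.wtp_gdp_per_capita"),
        wtp_multipliers=tuple(float(m) for m in model.get("wtp_multipliers", (1, 3))),
        arms=arms,
        costs=CostInputs(
            hospitalization=_state_map(
                _require(costs_raw, "hospitalization", "costs"),
                "costs.hospitalization",
            ),
            annual_rehab_secondary_prevention=_state_map(
                _require(costs_raw, "annual_rehab_secondary_prevention", "costs"),
                "costs.annual_rehab_secondary_prevention",
            ),
            mean_length_of_stay_days=_number(
                _require(costs_raw, "mean_length_of_stay_days", "costs"),
                "costs.mean_length_of_stay_days",
            ),
            cost_year=int(costs_raw.get("cost_year", 2021)),
        ),
        utilities=UtilityInputs(
            utilities=_state_map(
                _require(util_raw, "by_state", "utilities"), "utilities.by_state"
            ),
            recurrence_disutility=_number(
                _require(util_raw, "recurrence_disutility", "utilities"),
                "utilities.recurrence_disutility",
            ),
        ),
        transitions=TransitionInputs(
            death_hazard_ratio=_state_map(
                _require(trans_raw, "death_hazard_ratio", "transitions"),
                "transitions.death_hazard_ratio",
            ),
            post_recurrence=post_recurrence,
        ),
        recurrence=RecurrenceSchedule(
            annual_rates=tuple(
                _number(v, "recurrence.annual_rates")
                for v in _require(rec_raw, "annual_rates", "recurrence")
            ),
            terminal_rate=_number(
                _require(rec_raw, "terminal_rate", "recurrence"),
                "recurrence.terminal_rate",
            ),
        ),
        mortality=MortalityTable(bands=bands),
        sensitivity=sens,
        markov_state_costs=str(model.get("markov_state_costs", "off")),
        recurrence_event_costs=bool(model.get("recurrence_event_costs", True)),
        markov_death_costs=bool(model.get("markov_death_costs", True)),
        cycle0_fill=str(model.get("cycle0_fill", "calendar-only")),
    )


# ---------------------------------------------------------------------------
# Serialization (round-trip partner of load_model_config)


def params_to_dict(p: ModelParameters) -> dict[str, Any]:
    """Serialize parameters back to the configuration-file mapping."""

    def dist_map(d: StateDistribution) -> dict[str, float]:
        return {s.value: d.of(s) for s in STATE_ORDER}

    def state_keys(m: Mapping[HealthState, Any]) -> dict[str, Any]:
        return {s.value: v for s, v in m.items()}

    return {
        "model": {
            "start_age": p.start_age,
            "horizon_years": p.horizon_years,
            "cycle_length_years": p.cycle_length_years,
            "discount_rate": p.discount_rate,
            "short_term_days": p.short_term_days,
            "wtp_gdp_per_capita": p.wtp_gdp_per_capita,
            "wtp_multipliers": list(p.wtp_multipliers),
            "markov_state_costs": p.markov_state_costs,
            "recurrence_event_costs": p.recurrence_event_costs,
            "markov_death_costs": p.markov_death_costs,
            "cycle0_fill": p.cycle0_fill,
        },
        "arms": {
            role: {
                "name": arm.name,
                "day90_distribution": dist_map(arm.day90_distribution),
                "regimen": asdict(arm.regimen),
            }
            for role, arm in p.arms.items()
        },
        "costs": {
            "cost_year": p.costs.cost_year,
            "hospitalization": state_keys(p.costs.hospitalization),
            "annual_rehab_secondary_prevention": state_keys(
                p.costs.annual_rehab_secondary_prevention
            ),
            "mean_length_of_stay_days": p.costs.mean_length_of_stay_days,
        },
        "utilities": {
            "by_state": state_keys(p.utilities.utilities),
            "recurrence_disutility": p.utilities.recurrence_disutility,
        },
        "transitions": {
            "death_hazard_ratio": state_keys(p.transitions.death_hazard_ratio),
            "post_recurrence": {
                s.value: state_keys(d) for s, d in p.transitions.post_recurrence.items()
            },
        },
        "recurrence": {
            "annual_rates": list(p.recurrence.annual_rates),
            "terminal_rate": p.recurrence.terminal_rate,
        },
        "mortality": {"bands": [asdict(b) for b in p.mortality.bands]},
        "sensitivity": [asdict(s) for s in p.sensitivity],
    }


def save_model_config(p: ModelParameters, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(p), sort_keys=False))


# ---------------------------------------------------------------------------
# Validation


def validate_parameters(p: ModelParameters) -> ValidationReport:
    """Check every structural invariant; the report lists all violations."""
    rep = ValidationReport()

    if p.start_age <= 0:
        rep.add("model.start_age", "error", "start age must be positive")
    if p.horizon_years < 1:
        rep.add("model.horizon_years", "error", "horizon must be >= 1 year")
    if not (0.0 <= p.discount_rate <= 0.08):
        rep.add("model.discount_rate", "error",
                f"discount rate {p.discount_rate} outside the supported 0-8% range")
    if not (0 < p.short_term_days < 366):
        rep.add("model.short_term_days", "error",
                "short-term period must be within one year")
    if p.markov_state_costs not in ("off", "on", "mrs25_only"):
        rep.add("model.markov_state_costs", "error",
                f"unknown mode '{p.markov_state_costs}'")
    if p.cycle0_fill not in ("calendar-only", "accrue"):
        rep.add("model.cycle0_fill", "error",
                f"unknown mode '{p.cycle0_fill}'")

    for role, arm in p.arms.items():
        for msg in arm.day90_distribution.problems():
            rep.add(f"arms.{role}.day90_distribution", "error", msg)
        if arm.day90_distribution.dead > 0:
            rep.add(f"arms.{role}.day90_distribution", "warning",
                    "day-90 death mass is non-zero (base case assumes 0)")
        reg = arm.regimen
        if reg.unit_price <= 0 or reg.units_per_dose <= 0 or reg.doses_per_day <= 0:
            rep.add(f"arms.{role}.regimen", "error",
                    "regimen price and dosing must be strictly positive")
        if reg.duration_days < 0:
            rep.add(f"arms.{role}.regimen", "error", "duration must be >= 0 days")

    # costs
    for state, cost in p.costs.hospitalization.items():
        if cost < 0:
            rep.add(f"costs.hospitalization.{state.value}", "error",
                    "cost must be >= 0")
    for state, cost in p.costs.annual_rehab_secondary_prevention.items():
        if cost < 0:
            rep.add(f"costs.annual_rehab_secondary_prevention.{state.value}",
                    "error", "cost must be >= 0")
    if not (0 < p.costs.mean_length_of_stay_days < 90):
        rep.add("costs.mean_length_of_stay_days", "error",
                "mean length of stay must be in (0, 90) days")
    for state in STATE_ORDER:
        if state not in p.costs.hospitalization:
            rep.add("costs.hospitalization", "error",
                    f"missing hospitalization cost for {state.value}")
    for state in ALIVE_STATES:
        if state not in p.costs.annual_rehab_secondary_prevention:
            rep.add("costs.annual_rehab_secondary_prevention", "error",
                    f"missing rehabilitation cost for {state.value}")

    # utilities
    alive_utils = []
    for state in ALIVE_STATES:
        if state not in p.utilities.utilities:
            rep.add("utilities.by_state", "error",
                    f"missing utility for {state.value}")
            continue
        u = p.utilities.utilities[state]
        alive_utils.append(u)
        if not (0.0 <= u <= 1.0):
            rep.add(f"utilities.by_state.{state.value}", "error",
                    f"utility {u} outside [0, 1]")
    du = p.utilities.recurrence_disutility
    if alive_utils and not (0.0 <= du <= min(alive_utils)):
        rep.add("utilities.recurrence_disutility", "error",
                f"recurrence disutility {du} outside [0, min(alive utilities)]")

    # transitions
    for state in ALIVE_STATES:
        hr = p.transitions.death_hazard_ratio.get(state)
        if hr is None:
            rep.add("transitions.death_hazard_ratio", "error",
                    f"missing hazard ratio for {state.value}")
        elif hr <= 0:
            rep.add(f"transitions.death_hazard_ratio.{state.value}", "error",
                    f"hazard ratio {hr} must be > 0")
        dest = p.transitions.post_recurrence.get(state)
        if dest is None:
            rep.add("transitions.post_recurrence", "error",
                    f"missing post-recurrence distribution for {state.value}")
            continue
        total = sum(dest.values())
        if abs(total - 1.0) > _SUM_TOL:
            rep.add(f"transitions.post_recurrence.{state.value}", "error",
                    f"distribution sums to {total:.10g}, expected 1")
        for d, q in dest.items():
            if not (0.0 <= q <= 1.0):
                rep.add(f"transitions.post_recurrence.{state.value}.{d.value}",
                        "error", f"probability {q} outside [0, 1]")
        if state is HealthState.MRS25 and dest.get(HealthState.MRS01, 0.0) > 0:
            rep.add("transitions.post_recurrence.MRS25", "error",
                    "recurrence cannot improve disability (MRS25 -> MRS01)")

    # recurrence schedule
    for i, r in enumerate(p.recurrence.annual_rates, start=1):
        if not (0.0 <= r <= 1.0):
            rep.add(f"recurrence.annual_rates[{i}]", "error",
                    f"rate {r} outside [0, 1]")
    if not (0.0 <= p.recurrence.terminal_rate <= 1.0):
        rep.add("recurrence.terminal_rate", "error", "rate outside [0, 1]")

    # mortality table
    bands = sorted(p.mortality.bands, key=lambda b: b.lower)
    for b in bands:
        if not (0.0 <= b.rate <= 1.0):
            rep.add("mortality.bands", "error",
                    f"band [{b.lower}, {b.upper}) rate {b.rate} outside [0, 1]")
        if b.upper <= b.lower:
            rep.add("mortality.bands", "error",
                    f"band [{b.lower}, {b.upper}) is empty")
    for a, b in zip(bands, bands[1:]):
        if abs(a.upper - b.lower) > 1e-12:
            rep.add("mortality.bands", "error",
                    f"gap or overlap between bands at age {a.upper}")
        if b.rate < a.rate:
            rep.add("mortality.bands", "warning",
                    "mortality not non-decreasing with age")
    last_needed = p.start_age + p.horizon_years - 1
    if bands and not p.mortality.covers(last_needed):
        rep.add("mortality.bands", "error",
                f"mortality table does not cover age {last_needed} "
                f"(start age + horizon)")

    for s in p.sensitivity:
        if s.family not in ("beta", "gamma", "lognormal", "fixed"):
            rep.add(f"sensitivity[{s.path}]", "error",
                    f"unknown distribution family '{s.family}'")
        if s.low > s.high:
            rep.add(f"sensitivity[{s.path}]", "error", "low bound exceeds high bound")

    return rep


def adjust_cost_to_base_year(cost: float, cpi_ratio: float) -> float:
    """Rescale a cost into the analysis base year by a CPI ratio.

    The packaged defaults are already expressed in 2021 CNY; this helper is
    for users supplying costs from other price years (ratio = CPI of the base
    year divided by CPI of the source year, medical-care component).
    """
    if cpi_ratio <= 0:
        raise ValueError(f"cpi_ratio must be positive, got {cpi_ratio}")
    return cost * cpi_ratio
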