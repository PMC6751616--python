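"""Run configuration (YAML) and decision-rule (JSON) round-tripping."""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import ConstraintSpec, SimulationConfig, max_class_b
from .schedules import FAMILIES, ScheduleTable, ThresholdSchedule

__all__ = [
    "ConfigError",
    "EventConfig",
    "RunConfig",
    "DecisionRule",
    "load_config",
    "save_config",
    "write_rule",
    "read_rule",
]

SCHEMA_VERSION = 1

_KNOWN_TOP_LEVEL = {
    "schema",
    "seed",
    "log_level",
    "events",
    "simulation",
    "constraints",
    "thresholds",
    "priors",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EventConfig:
    event_id: str
    control_rate: float
    first_unacceptable: str = "D"
    weight: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.control_rate < 1.0:
            raise ConfigError(
                f"event {self.event_id}: control_rate must lie inside (0, 1)"
            )


@dataclass(frozen=True)
class RunConfig:
    events: tuple
    simulation: SimulationConfig
    constraints: ConstraintSpec
    tau_first: float = 0.95
    threshold_step: float = 0.01
    families: tuple = FAMILIES
    base_ess: float = 10.0
    eps: float = 1e-3
    seed: int | None = None
    log_level: str = "INFO"

    @property
    def event_ids(self) -> tuple:
        return tuple(e.event_id for e in self.events)

    @property
    def control_rates(self) -> dict:
        return {e.event_id: e.control_rate for e in self.events}


def _require(mapping: dict, key: str, context: str = "config"):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required field {key!r}")
    return mapping[key]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults.

    Defaults: L=11, n_trials=1000, mc_samples=100000, n_per_arm=162,
    tau_first=0.95, max_class_a=0.10 (class-b ceilings derived from event
    weights when present).  Unknown top-level fields raise a warning,
    missing required fields an error naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_TOP_LEVEL
    if unknown:
        warnings.warn(f"ignoring unknown config fields: {sorted(unknown)}")
    events_raw = _require(raw, "events")
    if not events_raw:
        raise ConfigError("config: 'events' must be a non-empty list")
    events = []
    for entry in events_raw:
        events.append(
            EventConfig(
                event_id=str(_require(entry, "id", "event")),
                control_rate=float(_require(entry, "control_rate", "event")),
                first_unacceptable=str(entry.get("first_unacceptable", "D")),
                weight=None if entry.get("weight") is None else float(entry["weight"]),
            )
        )
    sim_raw = raw.get("simulation", {}) or {}
    simulation = SimulationConfig(
        n_per_arm=int(sim_raw.get("n_per_arm", 162)),
        L=int(sim_raw.get("L", 11)),
        accrual=sim_raw.get("accrual"),
        n_trials=int(sim_raw.get("n_trials", 1000)),
        seed=int(sim_raw.get("seed", raw.get("seed", 0) or 0)),
        mc_samples=int(sim_raw.get("mc_samples", 100_000)),
    )
    cons_raw = raw.get("constraints", {}) or {}
    max_a = float(cons_raw.get("max_class_a", 0.10))
    if "max_class_b" in cons_raw:
        max_b = {str(k): float(v) for k, v in cons_raw["max_class_b"].items()}
    else:
        max_b = {
            e.event_id: max_class_b(e.weight)
            for e in events
            if e.weight is not None
        }
    constraints = ConstraintSpec(max_class_a=max_a, max_class_b_per_event=max_b)
    thr_raw = raw.get("thresholds", {}) or {}
    priors_raw = raw.get("priors", {}) or {}
    return RunConfig(
        events=tuple(events),
        simulation=simulation,
        constraints=constraints,
        tau_first=float(thr_raw.get("tau_first", 0.95)),
        threshold_step=float(thr_raw.get("step", 0.01)),
        families=tuple(thr_raw.get("families", FAMILIES)),
        base_ess=float(priors_raw.get("base_ess", 10.0)),
        eps=float(priors_raw.get("eps", 1e-3)),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
        log_level=str(raw.get("log_level", "INFO")),
    )


def save_config(config: RunConfig, path) -> None:
    payload = {
        "schema": SCHEMA_VERSION,
        "seed": config.seed,
        "log_level": config.log_level,
        "events": [
            {
                "id": e.event_id,
                "control_rate": e.control_rate,
                "first_unacceptable": e.first_unacceptable,
                "weight": e.weight,
            }
            for e in config.events
        ],
        "simulation": {
            "n_per_arm": config.simulation.n_per_arm,
            "L": config.simulation.L,
            "accrual": list(config.simulation.accrual),
            "n_trials": config.simulation.n_trials,
            "seed": config.simulation.seed,
            "mc_samples": config.simulation.mc_samples,
        },
        "constraints": {
            "max_class_a": config.constraints.max_class_a,
            "max_class_b": dict(config.constraints.max_class_b_per_event),
        },
        "thresholds": {
            "tau_first": config.tau_first,
            "step": config.threshold_step,
            "families": list(config.families),
        },
        "priors": {"base_ess": config.base_ess, "eps": config.eps},
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# decision-rule JSON
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecisionRule:
    """The calibrated rule: prior label, family, and per-event schedules."""

    prior_label: int
    family: str
    schedules: ScheduleTable

    @property
    def tau_final(self) -> dict:
        return {e: s.tau_final for e, s in self.schedules.schedules.items()}


def write_rule(rule: DecisionRule, path) -> None:
    """Serialise a complete rule; raw threshold values are kept losslessly."""
    if rule.prior_label is None or rule.family is None or not rule.schedules.schedules:
        raise ValueError("rule is incomplete")
    table = rule.schedules
    payload = {
        "schema": SCHEMA_VERSION,
        "prior_label": rule.prior_label,
        "family": rule.family,
        "L": table.L,
        "tau_first": table.tau_first,
        "events": [
            {
                "event_id": event,
                "tau_final": s.tau_final,
                "thresholds": list(s.values),
                "coefficients": list(s.coefficients) if s.coefficients else None,
            }
            for event, s in table.schedules.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_rule(path) -> DecisionRule:
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed rule JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    for key in ("prior_label", "family", "L", "tau_first", "events"):
        if key not in payload:
            raise ValueError(f"rule JSON missing field {key!r}")
    schedules = {}
    for entry in payload["events"]:
        schedules[entry["event_id"]] = ThresholdSchedule(
            family=payload["family"],
            L=payload["L"],
            tau_first=payload["tau_first"],
            tau_final=entry["tau_final"],
            values=tuple(entry["thresholds"]),
            coefficients=(
                tuple(entry["coefficients"]) if entry.get("coefficients") else None
            ),
        )
    table = ScheduleTable(
        family=payload["family"],
        L=payload["L"],
        tau_first=payload["tau_first"],
        schedules=schedules,
    )
    return DecisionRule(
        prior_label=int(payload["prior_label"]),
        family=payload["family"],
        schedules=table,
    )
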