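"""Operating-characteristics simulation and rule calibration.

Sequential trials are simulated under five truth scenarios obtained by
scaling the control prevalences, the decision rule is applied across a grid
of priors and final thresholds, and class-a / class-b misclassification
rates are tabulated against severity-weighted constraints to select the
final rule (prior, per-event final threshold, threshold family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .decision import PriorPair, TrialCounts, posterior_update, prob_exceeds_margin
from .mixtures import BetaMixture
from .schedules import FAMILIES, ScheduleTable, schedule_table

__all__ = [
    "SCENARIO_IDS",
    "SCENARIO_MULTIPLIERS",
    "Scenario",
    "SimulationConfig",
    "MisclassificationTable",
    "ConstraintSpec",
    "SimulationResult",
    "SelectionResult",
    "build_scenarios",
    "scale_prevalence",
    "max_class_b",
    "default_accrual",
    "simulate_trials",
    "misclassification_rates",
    "rates_from_probabilities",
    "calibrate_final_thresholds",
    "sequential_misclassification",
    "evaluate_families",
    "select_rule",
    "default_threshold_grid",
]

SCENARIO_IDS = ("A", "B", "C", "D", "E")
SCENARIO_MULTIPLIERS = {"A": 1.0, "B": 2.0 / 3.0, "C": 1.5, "D": 2.0, "E": 3.0}
_MULTIPLIER_FRACTIONS = {
    "A": Fraction(1),
    "B": Fraction(2, 3),
    "C": Fraction(3, 2),
    "D": Fraction(2),
    "E": Fraction(3),
}


def scale_prevalence(theta0: float, scenario_id: str) -> float:
    """Experimental prevalence: multiplier times theta0, capped at 1, 2 decimals.

    The product is formed in exact rational arithmetic before conversion to
    a double and half-even rounding, so printed-table ties like 0.225 -> 0.23
    come out right instead of inheriting float noise from the product.
    """
    product = Fraction(str(float(theta0))) * _MULTIPLIER_FRACTIONS[scenario_id]
    return min(1.0, round(float(product), 2))

ACCEPTABLE = "Acceptable"
UNACCEPTABLE = "Unacceptable"

_SCENARIO_RANK = {s: i for i, s in enumerate(SCENARIO_IDS)}


def _normalize_conclusion(value) -> bool:
    """True means 'Unacceptable excess concluded'."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("unacceptable", "u", "1", "true"):
        return True
    if text in ("acceptable", "acc", "a", "0", "false"):
        return False
    raise ValueError(f"cannot interpret conclusion/label {value!r}")


@dataclass(frozen=True)
class Scenario:
    """True prevalences for both arms plus per-event truth labels."""

    scenario_id: str
    multiplier: float
    event_ids: tuple
    theta0: tuple
    theta1: tuple
    truth_labels: tuple  # "Acceptable" / "Unacceptable" per event

    def __post_init__(self) -> None:
        if not (
            len(self.event_ids) == len(self.theta0) == len(self.theta1) == len(self.truth_labels)
        ):
            raise ValueError("per-event fields must have equal length")
        for t0, t1 in zip(self.theta0, self.theta1):
            if not (0.0 <= t0 <= 1.0 and 0.0 <= t1 <= 1.0):
                raise ValueError("prevalences must lie in [0, 1]")
            expected = scale_prevalence(t0, self.scenario_id)
            if abs(t1 - expected) > 1e-12:
                raise ValueError(
                    f"theta1 must equal min(1, round(multiplier*theta0, 2)); "
                    f"got {t1} vs {expected}"
                )


def build_scenarios(theta0, event_ids=None, first_unacceptable=None) -> list:
    """The five truth scenarios from the control prevalences.

    ``first_unacceptable`` names, per event, the first scenario (by id) whose
    excess counts as truly unacceptable.  The default -- C for the first two
    events and D for the rest -- encodes the worked four-event configuration
    and must be given explicitly otherwise.
    """
    theta0 = tuple(float(t) for t in theta0)
    if any(not 0.0 < t < 1.0 for t in theta0):
        raise ValueError("control prevalences must lie strictly inside (0, 1)")
    J = len(theta0)
    if event_ids is None:
        event_ids = tuple(f"event_{j + 1}" for j in range(J))
    event_ids = tuple(event_ids)
    if first_unacceptable is None:
        if J != 4:
            raise ValueError(
                "first_unacceptable defaults exist only for the 4-event layout"
            )
        first_unacceptable = ("C", "C", "D", "D")
    first_unacceptable = tuple(first_unacceptable)
    if len(first_unacceptable) != J:
        raise ValueError("first_unacceptable must have one entry per event")
    scenarios = []
    for sid in SCENARIO_IDS:
        mult = SCENARIO_MULTIPLIERS[sid]
        theta1 = tuple(scale_prevalence(t, sid) for t in theta0)
        labels = tuple(
            UNACCEPTABLE
            if _SCENARIO_RANK[sid] >= _SCENARIO_RANK[f]
            else ACCEPTABLE
            for f in first_unacceptable
        )
        scenarios.append(
            Scenario(
                scenario_id=sid,
                multiplier=mult,
                event_ids=event_ids,
                theta0=theta0,
                theta1=theta1,
                truth_labels=labels,
            )
        )
    return scenarios


def max_class_b(weight: float) -> float:
    """Maximal class-b misclassification rate for a severity weight in [0, 100]."""
    if not 0.0 <= weight <= 100.0:
        raise ValueError("weight must lie in [0, 100]")
    return 0.1 + 0.50 * (100.0 - weight) / 100.0


@dataclass(frozen=True)
class ConstraintSpec:
    """Misclassification ceilings: one class-a rate, per-event class-b rates."""

    max_class_a: float = 0.10
    max_class_b_per_event: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = [self.max_class_a, *self.max_class_b_per_event.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("constraint rates must lie in [0, 1]")

    @classmethod
    def from_weights(cls, weights: dict, max_class_a: float = 0.10) -> "ConstraintSpec":
        return cls(
            max_class_a=max_class_a,
            max_class_b_per_event={e: max_class_b(w) for e, w in weights.items()},
        )


def default_accrual(n_per_arm: int, L: int) -> tuple:
    """Equal-increment cumulative sample sizes: ceil(n*l/L)."""
    acc = tuple(int(math.ceil(n_per_arm * l / L)) for l in range(1, L + 1))
    return acc


@dataclass(frozen=True)
class SimulationConfig:
    n_per_arm: int = 162
    L: int = 11
    accrual: tuple | None = None
    n_trials: int = 1000
    seed: int = 0
    mc_samples: int = 100_000

    def __post_init__(self) -> None:
        accrual = self.accrual
        if accrual is None:
            accrual = default_accrual(self.n_per_arm, self.L)
        accrual = tuple(int(a) for a in accrual)
        object.__setattr__(self, "accrual", accrual)
        if len(accrual) != self.L:
            raise ValueError("accrual length must equal L")
        if any(b <= a for a, b in zip(accrual, accrual[1:])) or accrual[0] <= 0:
            raise ValueError("accrual must be strictly increasing and positive")
        if accrual[-1] != self.n_per_arm:
            raise ValueError("last accrual entry must equal n_per_arm")


@dataclass(frozen=True)
class MisclassificationTable:
    """Counts of the truth-vs-conclusion contingency table.

    A: concluded Unacceptable, truly Acceptable (class a)
    B: concluded Acceptable, truly Unacceptable (class b)
    C: concluded Acceptable, truly Acceptable
    D: concluded Unacceptable, truly Unacceptable
    """

    A: int
    B: int
    C: int
    D: int

    @property
    def n_trials(self) -> int:
        return self.A + self.B + self.C + self.D

    @property
    def rate_a(self) -> float | None:
        denom = self.A + self.C
        return None if denom == 0 else self.A / denom

    @property
    def rate_b(self) -> float | None:
        denom = self.B + self.D
        return None if denom == 0 else self.B / denom


def misclassification_rates(conclusions, truth_labels) -> MisclassificationTable:
    """Tabulate A/B/C/D from aligned conclusions and truth labels.

    A zero denominator leaves the corresponding rate ``None`` (undefined),
    never zero.
    """
    conclusions = [_normalize_conclusion(c) for c in conclusions]
    truths = [_normalize_conclusion(t) for t in truth_labels]
    if len(conclusions) != len(truths):
        raise ValueError("conclusions and truth labels must be aligned")
    A = sum(1 for c, t in zip(conclusions, truths) if c and not t)
    B = sum(1 for c, t in zip(conclusions, truths) if not c and t)
    C = sum(1 for c, t in zip(conclusions, truths) if not c and not t)
    D = sum(1 for c, t in zip(conclusions, truths) if c and t)
    return MisclassificationTable(A=A, B=B, C=C, D=D)


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------


def _per_event(mapping_or_value, event_ids):
    if isinstance(mapping_or_value, dict):
        missing = [e for e in event_ids if e not in mapping_or_value]
        if missing:
            raise KeyError(f"missing entries for events {missing}")
        return {e: mapping_or_value[e] for e in event_ids}
    return {e: mapping_or_value for e in event_ids}


def _schedule_values(schedules, event_ids, L):
    if isinstance(schedules, ScheduleTable):
        schedules = schedules.schedules
    per = _per_event(schedules, event_ids)
    out = {}
    for e, s in per.items():
        values = np.asarray(getattr(s, "values", s), dtype=float)
        if values.size != L:
            raise ValueError(f"schedule for {e} has length {values.size}, expected {L}")
        out[e] = values
    return out


@dataclass(frozen=True)
class SimulationResult:
    scenario_id: str
    event_ids: tuple
    probabilities: np.ndarray  # (n_trials, L, J)
    flags: np.ndarray  # bool, same shape
    conclusions: np.ndarray  # (n_trials, J) bool: True = Unacceptable
    first_flagged: np.ndarray  # (n_trials, J) int, 0 = never flagged

    def unacceptable_fraction(self) -> np.ndarray:
        return self.conclusions.mean(axis=0)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_trials(
    scenario: Scenario,
    config: SimulationConfig,
    priors,
    margins,
    schedules,
    seed=None,
) -> SimulationResult:
    """Simulate sequential trials under one scenario and apply the rule.

    ``priors``, ``margins`` and ``schedules`` may be single objects or
    per-event mappings.  Counts accrue as cumulative binomial increments on
    the accrual grid; a trial concludes Unacceptable for an event as soon as
    any interim analysis flags it.  Each trial owns a spawned random stream,
    so results are reproducible per (seed, trial index).
    """
    event_ids = scenario.event_ids
    J = len(event_ids)
    L = config.L
    priors = _per_event(priors, event_ids)
    margins = _per_event(margins, event_ids)
    taus = _schedule_values(schedules, event_ids, L)
    accrual = np.asarray(config.accrual)
    dn = np.diff(accrual, prepend=0)
    n_trials = config.n_trials
    probabilities = np.empty((n_trials, L, J))
    flags = np.zeros((n_trials, L, J), dtype=bool)
    first_flagged = np.zeros((n_trials, J), dtype=int)
    children = _seedseq(config.seed if seed is None else seed).spawn(n_trials)
    for t in range(n_trials):
        rng = np.random.default_rng(children[t])
        for j, event in enumerate(event_ids):
            y0 = np.cumsum(rng.binomial(dn, scenario.theta0[j]))
            y1 = np.cumsum(rng.binomial(dn, scenario.theta1[j]))
            prior = priors[event]
            for l in range(L):
                counts = TrialCounts(
                    analysis_index=l + 1,
                    n_control=int(accrual[l]),
                    events_control=int(y0[l]),
                    n_experimental=int(accrual[l]),
                    events_experimental=int(y1[l]),
                )
                posterior = posterior_update(prior, counts)
                p, _se = prob_exceeds_margin(
                    posterior, margins[event], config.mc_samples, rng=rng
                )
                probabilities[t, l, j] = p
                if p >= taus[event][l]:
                    flags[t, l, j] = True
                    if first_flagged[t, j] == 0:
                        first_flagged[t, j] = l + 1
    conclusions = flags.any(axis=1)
    return SimulationResult(
        scenario_id=scenario.scenario_id,
        event_ids=event_ids,
        probabilities=probabilities,
        flags=flags,
        conclusions=conclusions,
        first_flagged=first_flagged,
    )


# ---------------------------------------------------------------------------
# final-threshold calibration
# ---------------------------------------------------------------------------


def default_threshold_grid(step: float = 0.01) -> np.ndarray:
    """Grid over the open interval (0.50, 1.00)."""
    grid = np.round(np.arange(0.50 + step, 1.00, step), 10)
    return grid


def rates_from_probabilities(probabilities, truth_labels, thresholds) -> pd.DataFrame:
    """Misclassification rates when thresholding fixed posterior probabilities.

    One row per threshold; the independent-enumeration contract behind
    :func:`calibrate_final_thresholds`.
    """
    probs = np.asarray(probabilities, dtype=float)
    truths = np.array([_normalize_conclusion(t) for t in truth_labels])
    if probs.shape != truths.shape:
        raise ValueError("probabilities and truth labels must be aligned")
    records = []
    for tau in np.asarray(thresholds, dtype=float):
        concluded = probs >= tau
        table = misclassification_rates(concluded, truths)
        records.append(
            {
                "tau_final": float(tau),
                "A": table.A,
                "B": table.B,
                "C": table.C,
                "D": table.D,
                "rate_a": table.rate_a,
                "rate_b": table.rate_b,
            }
        )
    return pd.DataFrame.from_records(records)


def _final_probabilities_one(
    y0, y1, n, prior: PriorPair, margin, mc_samples: int, rng, block: int = 64
):
    """Vectorised per-trial P(theta1-theta0 > margin) at the final analysis."""
    y0 = np.asarray(y0)
    y1 = np.asarray(y1)
    n_trials = y0.size
    a0 = prior.control.alpha + y0
    b0 = prior.control.beta + n - y0
    a1 = prior.experimental.alpha + y1
    b1 = prior.experimental.beta + n - y1
    out = np.empty(n_trials)
    for start in range(0, n_trials, block):
        sl = slice(start, min(start + block, n_trials))
        m = sl.stop - sl.start
        t1 = rng.beta(a1[sl, None], b1[sl, None], size=(m, mc_samples))
        t0 = rng.beta(a0[sl, None], b0[sl, None], size=(m, mc_samples))
        if isinstance(margin, BetaMixture):
            x = margin.sample(m * mc_samples, rng=rng).reshape(m, mc_samples)
        else:
            x = float(margin)
        out[sl] = np.mean(t1 - t0 > x, axis=1)
    return out


def calibrate_final_thresholds(
    scenarios,
    config: SimulationConfig,
    prior_grids,
    margins,
    threshold_grid=None,
    seed=None,
) -> pd.DataFrame:
    """Final-analysis misclassification rates per (prior, event, threshold).

    Final counts are drawn directly as Binomial(n, theta) per trial (a
    single draw is exchangeable with the accrued increments), posterior
    exceedance probabilities are evaluated per prior, pooled over scenarios
    with their truth labels, and thresholded over the grid.

    ``prior_grids`` maps event_id to a list of labelled :class:`PriorPair`
    (or is one such list applied to every event); ``margins`` likewise.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("no scenarios supplied")
    event_ids = scenarios[0].event_ids
    grid = (
        default_threshold_grid()
        if threshold_grid is None
        else np.asarray(threshold_grid, dtype=float)
    )
    if np.any(grid <= 0.5) or np.any(grid >= 1.0):
        raise ValueError("threshold grid must lie strictly inside (0.50, 1.00)")
    if isinstance(prior_grids, dict):
        grids = _per_event(prior_grids, event_ids)
    else:
        grids = {e: list(prior_grids) for e in event_ids}
    labels = [p.label for p in next(iter(grids.values()))]
    for e, g in grids.items():
        if [p.label for p in g] != labels:
            raise ValueError("prior grids must share the same labels across events")
    margins = _per_event(margins, event_ids)
    root = _seedseq(config.seed if seed is None else seed)
    count_ss, mc_ss = root.spawn(2)
    count_rng = np.random.default_rng(count_ss)
    n = config.n_per_arm
    # final counts per (scenario, event)
    finals = {}
    for sc in scenarios:
        for j, e in enumerate(event_ids):
            y0 = count_rng.binomial(n, sc.theta0[j], size=config.n_trials)
            y1 = count_rng.binomial(n, sc.theta1[j], size=config.n_trials)
            finals[(sc.scenario_id, e)] = (y0, y1)
    records = []
    mc_children = iter(mc_ss.spawn(len(labels) * len(event_ids) * len(scenarios)))
    for li, label in enumerate(labels):
        for j, e in enumerate(event_ids):
            prior = grids[e][li]
            probs, truths = [], []
            for sc in scenarios:
                y0, y1 = finals[(sc.scenario_id, e)]
                rng = np.random.default_rng(next(mc_children))
                p = _final_probabilities_one(
                    y0, y1, n, prior, margins[e], config.mc_samples, rng
                )
                probs.append(p)
                truths.extend([sc.truth_labels[j]] * config.n_trials)
            pooled = np.concatenate(probs)
            frame = rates_from_probabilities(pooled, truths, grid)
            frame.insert(0, "event_id", e)
            frame.insert(0, "prior_label", label)
            records.append(frame)
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# sequential evaluation and rule selection
# ---------------------------------------------------------------------------


def sequential_misclassification(
    scenarios, config: SimulationConfig, priors, margins, schedules, seed=None
) -> pd.DataFrame:
    """Overall per-event misclassification rates of a full sequential rule."""
    scenarios = list(scenarios)
    event_ids = scenarios[0].event_ids
    children = _seedseq(config.seed if seed is None else seed).spawn(len(scenarios))
    conclusions = {e: [] for e in event_ids}
    truths = {e: [] for e in event_ids}
    for sc, child in zip(scenarios, children):
        result = simulate_trials(sc, config, priors, margins, schedules, seed=child)
        for j, e in enumerate(event_ids):
            conclusions[e].extend(result.conclusions[:, j].tolist())
            truths[e].extend([sc.truth_labels[j]] * config.n_trials)
    records = []
    for e in event_ids:
        table = misclassification_rates(conclusions[e], truths[e])
        records.append(
            {
                "event_id": e,
                "A": table.A,
                "B": table.B,
                "C": table.C,
                "D": table.D,
                "rate_a": table.rate_a,
                "rate_b": table.rate_b,
            }
        )
    return pd.DataFrame.from_records(records)


def evaluate_families(
    scenarios,
    config: SimulationConfig,
    priors,
    margins,
    tau_final: dict,
    tau_first: float = 0.95,
    families=FAMILIES,
    seed=None,
) -> pd.DataFrame:
    """Sequential misclassification rates for each threshold family."""
    frames = []
    root = _seedseq(config.seed if seed is None else seed)
    children = root.spawn(len(list(families)))
    for family, child in zip(families, children):
        table = schedule_table(
            list(tau_final.items()), family=family, L=config.L, tau_first=tau_first
        )
        frame = sequential_misclassification(
            scenarios, config, priors, margins, table, seed=child
        )
        frame.insert(0, "family", family)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SelectionResult:
    admissible: bool
    prior_label: int | None = None
    tau_final: dict | None = None
    family: str | None = None
    per_event: pd.DataFrame | None = None
    nearest_miss: dict | None = None


def _rate_ok(rate, ceiling) -> bool:
    # undefined rates (no trials in the denominator) cannot violate a ceiling
    if rate is None or (isinstance(rate, float) and math.isnan(rate)):
        return True
    return rate <= ceiling + 1e-12


def select_rule(
    calibration: pd.DataFrame,
    constraints: ConstraintSpec,
    family_results: pd.DataFrame | None = None,
) -> SelectionResult:
    """Pick the prior, per-event final thresholds and threshold family.

    A (prior, event, tau) cell is admissible when both misclassification
    rates respect their ceilings.  The retained prior must be admissible for
    every event; ties break by the smallest summed class-b rate, then the
    lowest label.  Per event, the smallest admissible threshold (lowest
    class-b rate) is retained.  If ``family_results`` is given, the family
    keeping every sequential rate within the ceilings (smallest summed rates
    on ties, then canonical order) is chosen.
    """
    required = {"prior_label", "event_id", "tau_final", "rate_a", "rate_b"}
    if not required.issubset(calibration.columns):
        raise ValueError(f"calibration frame must have columns {sorted(required)}")
    events = sorted(calibration["event_id"].unique())
    missing_b = [e for e in events if e not in constraints.max_class_b_per_event]
    if missing_b:
        raise ValueError(f"no class-b ceiling for events {missing_b}")

    def admissible_row(row) -> bool:
        return _rate_ok(row["rate_a"], constraints.max_class_a) and _rate_ok(
            row["rate_b"], constraints.max_class_b_per_event[row["event_id"]]
        )

    calib = calibration.copy()
    calib["admissible"] = calib.apply(admissible_row, axis=1)
    chosen = {}
    for label, group in calib.groupby("prior_label"):
        per_event = {}
        for e in events:
            ok = group[(group["event_id"] == e) & group["admissible"]]
            if ok.empty:
                per_event = None
                break
            row = ok.sort_values("tau_final").iloc[0]
            per_event[e] = row
        if per_event is not None:
            total_b = sum(
                0.0 if row["rate_b"] is None or pd.isna(row["rate_b"]) else row["rate_b"]
                for row in per_event.values()
            )
            chosen[label] = (total_b, per_event)
    if not chosen:
        return SelectionResult(
            admissible=False, nearest_miss=_nearest_miss(calib, constraints, events)
        )
    best_label = min(chosen, key=lambda lab: (chosen[lab][0], lab))
    _total_b, per_event_rows = chosen[best_label]
    tau_final = {e: float(row["tau_final"]) for e, row in per_event_rows.items()}
    per_event = pd.DataFrame([row for row in per_event_rows.values()])
    family = None
    if family_results is not None:
        family = _select_family(family_results, constraints)
    return SelectionResult(
        admissible=True,
        prior_label=int(best_label),
        tau_final=tau_final,
        family=family,
        per_event=per_event,
    )


def _select_family(family_results: pd.DataFrame, constraints: ConstraintSpec):
    order = {f: i for i, f in enumerate(FAMILIES)}
    candidates = []
    for family, group in family_results.groupby("family"):
        ok = all(
            _rate_ok(row["rate_a"], constraints.max_class_a)
            and _rate_ok(row["rate_b"], constraints.max_class_b_per_event[row["event_id"]])
            for _, row in group.iterrows()
        )
        if ok:
            total = float(group[["rate_a", "rate_b"]].fillna(0.0).to_numpy().sum())
            candidates.append((total, order.get(family, 99), family))
    if not candidates:
        return None
    return min(candidates)[2]


def _nearest_miss(calib: pd.DataFrame, constraints: ConstraintSpec, events) -> dict:
    """Smallest constraint violation per prior, for the failure report."""

    def violation(row) -> float:
        va = max(0.0, (row["rate_a"] or 0.0) - constraints.max_class_a)
        vb = max(
            0.0,
            (row["rate_b"] or 0.0)
            - constraints.max_class_b_per_event[row["event_id"]],
        )
        return max(va, vb)

    per_prior = {}
    for label, group in calib.groupby("prior_label"):
        worst = 0.0
        for e in events:
            sub = group[group["event_id"] == e]
            worst = max(worst, min(violation(row) for _, row in sub.iterrows()))
        per_prior[int(label)] = worst
    best = min(per_prior, key=per_prior.get)
    return {"prior_label": best, "max_violation": per_prior[best], "per_prior": per_prior}
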