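"""CSV/JSON serialisation of the pipeline's tabular interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .decision import TrialCounts
from .elicitation import ExpertAnswer
from .mixtures import BetaMixture

__all__ = [
    "read_expert_answers",
    "write_expert_answers",
    "read_control_rates",
    "write_margins",
    "read_margins",
    "read_trial_counts",
    "write_trial_counts",
    "write_monitoring_report",
]

_ANSWER_COLUMNS = ["expert_id", "event_id", "acceptable_rate", "severity_weight"]


def read_expert_answers(path) -> list:
    """Expert answers CSV -> list of :class:`ExpertAnswer`.

    Required columns: ``expert_id,event_id,acceptable_rate,severity_weight``;
    any extra columns become covariates.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _ANSWER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"expert answers CSV missing columns {missing}")
    extra = [c for c in frame.columns if c not in _ANSWER_COLUMNS]
    answers = []
    for _, row in frame.iterrows():
        answers.append(
            ExpertAnswer(
                expert_id=str(row["expert_id"]),
                event_id=str(row["event_id"]),
                acceptable_rate=float(row["acceptable_rate"]),
                severity_weight=float(row["severity_weight"]),
                covariates={c: row[c] for c in extra},
            )
        )
    return answers


def write_expert_answers(answers, path) -> None:
    records = []
    for a in answers:
        rec = {
            "expert_id": a.expert_id,
            "event_id": a.event_id,
            "acceptable_rate": a.acceptable_rate,
            "severity_weight": a.severity_weight,
        }
        rec.update(a.covariates)
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_control_rates(path) -> dict:
    """CSV with columns ``event_id,control_rate`` -> mapping."""
    frame = pd.read_csv(path)
    for c in ("event_id", "control_rate"):
        if c not in frame.columns:
            raise ValueError(f"control rates CSV missing column {c!r}")
    return {str(r["event_id"]): float(r["control_rate"]) for _, r in frame.iterrows()}


def write_margins(margins: dict, path) -> None:
    """Fitted margins -> JSON.

    ``margins`` maps event_id to a dict with keys ``mixture``
    (:class:`BetaMixture`), ``control_rate``, ``method``, ``criterion``
    (name/value pair), ``n_experts`` and ``median_difference``.
    """
    payload = []
    for event_id, entry in margins.items():
        mixture: BetaMixture = entry["mixture"]
        payload.append(
            {
                "event_id": event_id,
                "control_rate": entry["control_rate"],
                "components": [
                    {"a": a, "b": b, "w": w}
                    for (a, b), w in zip(mixture.shapes, mixture.weights)
                ],
                "method": entry["method"],
                "criterion": entry["criterion"],
                "n_experts": entry["n_experts"],
                "median_difference": entry["median_difference"],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))


def read_margins(path) -> dict:
    """Margin JSON -> mapping event_id -> entry with a live BetaMixture."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for entry in payload:
        mixture = BetaMixture(
            shapes=tuple((c["a"], c["b"]) for c in entry["components"]),
            weights=tuple(c["w"] for c in entry["components"]),
        )
        out[entry["event_id"]] = {
            "mixture": mixture,
            "control_rate": entry["control_rate"],
            "method": entry["method"],
            "criterion": entry["criterion"],
            "n_experts": entry["n_experts"],
            "median_difference": entry["median_difference"],
        }
    return out


def read_trial_counts(path) -> list:
    """Counts CSV (``analysis_index,arm,n_cum,events_cum``) -> TrialCounts list.

    ``arm`` is 0 for control, 1 for experimental; both arms are required at
    every analysis.
    """
    frame = pd.read_csv(path)
    for c in ("analysis_index", "arm", "n_cum", "events_cum"):
        if c not in frame.columns:
            raise ValueError(f"trial counts CSV missing column {c!r}")
    counts = []
    for l, group in frame.groupby("analysis_index"):
        by_arm = {int(r["arm"]): r for _, r in group.iterrows()}
        if set(by_arm) != {0, 1}:
            raise ValueError(f"analysis {l}: need exactly arms 0 and 1")
        counts.append(
            TrialCounts(
                analysis_index=int(l),
                n_control=int(by_arm[0]["n_cum"]),
                events_control=int(by_arm[0]["events_cum"]),
                n_experimental=int(by_arm[1]["n_cum"]),
                events_experimental=int(by_arm[1]["events_cum"]),
            )
        )
    counts.sort(key=lambda c: c.analysis_index)
    return counts


def write_trial_counts(counts, path) -> None:
    records = []
    for c in counts:
        records.append(
            {"analysis_index": c.analysis_index, "arm": 0, "n_cum": c.n_control, "events_cum": c.events_control}
        )
        records.append(
            {"analysis_index": c.analysis_index, "arm": 1, "n_cum": c.n_experimental, "events_cum": c.events_experimental}
        )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_monitoring_report(result, path, seed=None) -> None:
    """Monitoring result -> JSON (per-analysis probability/SE/threshold/flag)."""
    payload = {
        "seed": seed,
        "stopped_at": result.stopped_at,
        "analyses": [
            {
                "analysis_index": l,
                "posterior_probability": r.posterior_probability,
                "mc_standard_error": r.mc_standard_error,
                "threshold": r.threshold,
                "flag": r.flag,
            }
            for l, r in enumerate(result.results, start=1)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
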