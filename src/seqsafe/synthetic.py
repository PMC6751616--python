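"""Seeded synthetic-data generators.

Everything downstream (elicitation fitting, monitoring, calibration) can be
exercised without any external data: expert panels are drawn from a
two-cluster difference distribution (a near-zero spike plus a diffuse
cluster, echoing zero-heavy real panels), and sequential trial counts are
cumulative binomial increments on an accrual grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decision import TrialCounts
from .elicitation import ExpertAnswer

__all__ = [
    "ExpertGeneratorSpec",
    "TrialGeneratorSpec",
    "generate_expert_answers",
    "generate_trial_dataset",
]

#: default severity-weight sampler per event: ("fixed", v), ("uniform", lo, hi)
#: or ("normal", mu, sd) -- normal draws are truncated to [0, 100]
DEFAULT_WEIGHT_SPEC = ("uniform", 50, 95)


@dataclass(frozen=True)
class ExpertGeneratorSpec:
    n_experts: int = 43
    spike_probability: float = 0.6
    spike_shape: tuple = (1.0, 200.0)
    diffuse_shape: tuple = (4.0, 36.0)
    weight_distribution: dict = field(default_factory=dict)  # event_id -> spec
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must lie in [0, 1]")
        for a, b in (self.spike_shape, self.diffuse_shape):
            if not (a > 0 and b > 0):
                raise ValueError("shape parameters must be strictly positive")
        if self.n_experts < 1:
            raise ValueError("need at least one expert")


@dataclass(frozen=True)
class TrialGeneratorSpec:
    theta0: dict  # event_id -> control prevalence
    theta1: dict  # event_id -> experimental prevalence
    accrual: tuple
    seed: int = 0

    def __post_init__(self) -> None:
        accrual = tuple(int(a) for a in self.accrual)
        object.__setattr__(self, "accrual", accrual)
        for mapping in (self.theta0, self.theta1):
            if any(not 0.0 <= v <= 1.0 for v in mapping.values()):
                raise ValueError("prevalences must lie in [0, 1]")
        if set(self.theta0) != set(self.theta1):
            raise ValueError("theta0 and theta1 must cover the same events")
        if accrual[0] <= 0 or any(b <= a for a, b in zip(accrual, accrual[1:])):
            raise ValueError("accrual must be strictly increasing and positive")


def _sample_weights(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        return rng.integers(int(spec[1]), int(spec[2]) + 1, size=n).astype(float)
    if kind == "normal":
        return np.clip(rng.normal(float(spec[1]), float(spec[2]), size=n), 0.0, 100.0)
    raise ValueError(f"unknown weight spec {spec!r}")


def generate_expert_answers(spec: ExpertGeneratorSpec, control_rates: dict) -> list:
    """Draw one panel of expert answers covering every event.

    Acceptable rates are ``control_rate + d`` with ``d`` from the
    spike/diffuse mixture, truncated to [0, 1].  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    E = spec.n_experts
    answers = []
    for event_id, control_rate in control_rates.items():
        if not 0.0 < control_rate < 1.0:
            raise ValueError(f"control rate for {event_id} must lie inside (0, 1)")
        spike = rng.random(E) < spec.spike_probability
        d_spike = rng.beta(*spec.spike_shape, size=E)
        d_diffuse = rng.beta(*spec.diffuse_shape, size=E)
        d = np.where(spike, d_spike, d_diffuse)
        h = np.clip(control_rate + d, 0.0, 1.0)
        wspec = spec.weight_distribution.get(event_id, DEFAULT_WEIGHT_SPEC)
        w = _sample_weights(wspec, E, rng)
        for e in range(E):
            answers.append(
                ExpertAnswer(
                    expert_id=f"expert_{e + 1:03d}",
                    event_id=event_id,
                    acceptable_rate=float(h[e]),
                    severity_weight=float(w[e]),
                )
            )
    return answers


def generate_trial_dataset(spec: TrialGeneratorSpec) -> dict:
    """Cumulative two-arm counts per event on the accrual grid.

    Increments are Binomial(delta_n, theta); the cumulative final count is
    therefore exchangeable with a single Binomial(n, theta) draw.
    """
    rng = np.random.default_rng(spec.seed)
    accrual = np.asarray(spec.accrual)
    dn = np.diff(accrual, prepend=0)
    dataset = {}
    for event_id in spec.theta0:
        y0 = np.cumsum(rng.binomial(dn, spec.theta0[event_id]))
        y1 = np.cumsum(rng.binomial(dn, spec.theta1[event_id]))
        dataset[event_id] = [
            TrialCounts(
                analysis_index=l + 1,
                n_control=int(accrual[l]),
                events_control=int(y0[l]),
                n_experimental=int(accrual[l]),
                events_experimental=int(y1[l]),
            )
            for l in range(accrual.size)
        ]
    return dataset
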