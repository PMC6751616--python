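"""Conjugate posteriors, margin-exceedance probabilities and the stopping rule.

Each arm's event rate carries a beta prior; with binomial counts the
posterior is beta in closed form, so the posterior probability that the
arm difference exceeds the (distribution-valued) margin is evaluated by
direct conjugate Monte-Carlo sampling -- no MCMC is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mixtures import BetaMixture

__all__ = [
    "ArmPrior",
    "PriorPair",
    "TrialCounts",
    "PosteriorPair",
    "DecisionResult",
    "MonitoringResult",
    "posterior_update",
    "prob_exceeds_margin",
    "decide",
    "monitor_sequential",
    "build_prior_grid",
    "PRIOR_LOCATION_KEYS",
    "PRIOR_PRECISIONS",
]

#: precision multipliers of the informative prior grid, in label order
PRIOR_PRECISIONS = (1.0, 1.0 / 3.0, 1.0 / 10.0, 1.0 / 20.0)
PRIOR_LOCATION_KEYS = ("zero", "median_difference", "control_rate")


@dataclass(frozen=True)
class ArmPrior:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"beta parameters must be strictly positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class PriorPair:
    """Priors for the control (arm 0) and experimental (arm 1) rates."""

    control: ArmPrior
    experimental: ArmPrior
    label: int | None = None


@dataclass(frozen=True)
class TrialCounts:
    """Cumulative per-arm subjects and events at one interim analysis."""

    analysis_index: int
    n_control: int
    events_control: int
    n_experimental: int
    events_experimental: int

    def __post_init__(self) -> None:
        if self.analysis_index < 1:
            raise ValueError("analysis_index starts at 1")
        for n, y, arm in (
            (self.n_control, self.events_control, "control"),
            (self.n_experimental, self.events_experimental, "experimental"),
        ):
            if not 0 <= y <= n:
                raise ValueError(f"{arm} arm: need 0 <= events <= subjects, got {y}/{n}")


@dataclass(frozen=True)
class PosteriorPair:
    control: ArmPrior
    experimental: ArmPrior


@dataclass(frozen=True)
class DecisionResult:
    """Outcome of one interim look for one event."""

    posterior_probability: float
    mc_standard_error: float
    threshold: float
    flag: bool

    def __post_init__(self) -> None:
        if self.flag != (self.posterior_probability >= self.threshold):
            raise ValueError("flag inconsistent with probability/threshold")


def posterior_update(prior: PriorPair, counts: TrialCounts) -> PosteriorPair:
    """Conjugate update: shape1 = alpha + Y, shape2 = beta + n - Y, per arm."""
    return PosteriorPair(
        control=ArmPrior(
            prior.control.alpha + counts.events_control,
            prior.control.beta + counts.n_control - counts.events_control,
        ),
        experimental=ArmPrior(
            prior.experimental.alpha + counts.events_experimental,
            prior.experimental.beta + counts.n_experimental - counts.events_experimental,
        ),
    )


def prob_exceeds_margin(
    posterior: PosteriorPair,
    margin,
    n_samples: int = 100_000,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Monte-Carlo estimate of P(theta1 - theta0 > margin) with its SE.

    ``margin`` is either a :class:`BetaMixture` (margin drawn per sample) or
    a number (point-mass mode).  Returns ``(probability, standard_error)``.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    if rng is None:
        rng = np.random.default_rng(seed)
    t1 = rng.beta(posterior.experimental.alpha, posterior.experimental.beta, n_samples)
    t0 = rng.beta(posterior.control.alpha, posterior.control.beta, n_samples)
    if isinstance(margin, BetaMixture):
        x = margin.sample(n_samples, rng=rng)
    else:
        x = float(margin)
        if not np.isfinite(x):
            raise ValueError("point-mass margin must be finite")
    p = float(np.mean(t1 - t0 > x))
    se = math.sqrt(p * (1.0 - p) / n_samples)
    return p, se


def decide(probability: float, threshold: float) -> bool:
    """Unacceptable-excess flag: closed comparison ``probability >= threshold``."""
    for name, v in (("probability", probability), ("threshold", threshold)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return bool(probability >= threshold)


@dataclass(frozen=True)
class MonitoringResult:
    results: tuple
    stopped_at: int | None  # first flagged analysis (1-based), None if never

    @property
    def flagged(self) -> bool:
        return self.stopped_at is not None


def _threshold_values(schedule, n: int) -> np.ndarray:
    values = getattr(schedule, "values", schedule)
    values = np.asarray(values, dtype=float)
    if values.size != n:
        raise ValueError(
            f"schedule length {values.size} does not match {n} analyses"
        )
    return values


def monitor_sequential(
    analyses,
    schedule,
    prior: PriorPair | None = None,
    margin=None,
    n_samples: int = 100_000,
    seed=None,
) -> MonitoringResult:
    """Apply the decision rule at each interim analysis in order.

    ``analyses`` is either a sequence of posterior probabilities
    (probability mode) or of :class:`TrialCounts` (counts mode, requiring
    ``prior`` and ``margin``).  Every analysis is evaluated for reporting;
    ``stopped_at`` is the first flagged one.
    """
    analyses = list(analyses)
    if not analyses:
        raise ValueError("no analyses supplied")
    taus = _threshold_values(schedule, len(analyses))
    counts_mode = isinstance(analyses[0], TrialCounts)
    if counts_mode:
        if prior is None or margin is None:
            raise ValueError("counts mode requires a prior and a margin")
        indices = [c.analysis_index for c in analyses]
        if indices != sorted(indices):
            raise ValueError("analyses must be ordered by analysis_index")
        for prev, cur in zip(analyses, analyses[1:]):
            if (
                cur.n_control < prev.n_control
                or cur.n_experimental < prev.n_experimental
                or cur.events_control < prev.events_control
                or cur.events_experimental < prev.events_experimental
            ):
                raise ValueError("counts must be cumulative (non-decreasing)")
        rng = np.random.default_rng(seed)
    results = []
    stopped_at = None
    for l, item in enumerate(analyses, start=1):
        if counts_mode:
            posterior = posterior_update(prior, item)
            p, se = prob_exceeds_margin(posterior, margin, n_samples, rng=rng)
        else:
            p, se = float(item), 0.0
        flag = decide(p, taus[l - 1])
        results.append(
            DecisionResult(
                posterior_probability=p,
                mc_standard_error=se,
                threshold=float(taus[l - 1]),
                flag=flag,
            )
        )
        if flag and stopped_at is None:
            stopped_at = l
    return MonitoringResult(results=tuple(results), stopped_at=stopped_at)


def build_prior_grid(
    control_rate: float,
    median_difference: float,
    base_ess: float = 10.0,
    eps: float = 1e-3,
) -> list:
    """The 13-prior sensitivity grid for one event.

    Prior 1 is Beta(1, 1) on both arms.  Priors 2-13 cross three locations
    of the prior mean difference E(pi1 - pi0) -- 0, the median elicited
    difference, and the control rate -- with four precision multipliers
    (1, 1/3, 1/10, 1/20) scaling a base per-arm effective sample size.
    """
    if not 0.0 < control_rate < 1.0:
        raise ValueError("control_rate must lie strictly inside (0, 1)")
    if not 0.0 < median_difference < 1.0:
        raise ValueError("median_difference must lie strictly inside (0, 1)")
    grid = [PriorPair(ArmPrior(1.0, 1.0), ArmPrior(1.0, 1.0), label=1)]
    locations = (0.0, median_difference, control_rate)
    label = 2
    for delta in locations:
        for precision in PRIOR_PRECISIONS:
            ess = precision * base_ess
            m0 = control_rate
            m1 = min(max(control_rate + delta, eps), 1.0 - eps)
            grid.append(
                PriorPair(
                    control=ArmPrior(m0 * ess, (1.0 - m0) * ess),
                    experimental=ArmPrior(m1 * ess, (1.0 - m1) * ess),
                    label=label,
                )
            )
            label += 1
    return grid
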