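"""Turn expert answers into margin distributions.

Each expert states, per safety event, the maximal event rate they would
tolerate in the experimental arm together with a severity weight in
[0, 100].  Differences to the control-arm reference rate are fitted with a
mixture of at most three beta densities by three competing methods:

1. ``em_mixture`` -- expectation-maximisation over 1..3 components;
2. ``manual_two_component`` -- every dichotomisation of the sorted
   differences, one beta per side, mixed over a fixed 21-point weight grid;
3. ``hybrid`` -- the left component and its weight from method 2, the right
   side refitted by a 2-component EM.

The method with the best (lowest) goodness-of-fit criterion wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .mixtures import (
    BetaMixture,
    criterion_score,
    criterion_table,
    degenerate_beta,
    fit_beta_ml,
    fit_beta_weighted,
    _moment_init,
    _validate_open_unit,
    CRITERIA,
)

__all__ = [
    "ExpertAnswer",
    "ElicitedDifferences",
    "FitConfig",
    "FitDiagnostics",
    "compute_differences",
    "median_weight",
    "fit_mixture_em",
    "fit_manual_two_component",
    "fit_hybrid",
    "select_margin_fit",
    "WEIGHT_GRID",
]

#: the 21 candidate first-component weights tried by the manual method
WEIGHT_GRID = tuple(np.round(np.arange(0, 21) * 0.05, 2))

METHOD_ORDER = ("em_mixture", "manual_two_component", "hybrid")


@dataclass(frozen=True)
class ExpertAnswer:
    """One expert's answer for one event."""

    expert_id: str
    event_id: str
    acceptable_rate: float
    severity_weight: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.acceptable_rate <= 1.0:
            raise ValueError(
                f"acceptable_rate must lie in [0, 1], got {self.acceptable_rate}"
            )
        if not 0.0 <= self.severity_weight <= 100.0:
            raise ValueError(
                f"severity_weight must lie in [0, 100], got {self.severity_weight}"
            )


@dataclass(frozen=True)
class ElicitedDifferences:
    """Per-event acceptable differences, clamped strictly inside (0, 1)."""

    event_id: str
    control_rate: float
    differences: tuple
    n_experts: int

    def __post_init__(self) -> None:
        d = tuple(float(v) for v in self.differences)
        object.__setattr__(self, "differences", d)
        if any(not (0.0 < v < 1.0) for v in d):
            raise ValueError("differences must lie strictly inside (0, 1)")
        if len(d) > self.n_experts:
            raise ValueError("more differences than answering experts")

    @property
    def median(self) -> float:
        return float(np.median(self.differences))


@dataclass(frozen=True)
class FitConfig:
    """Knobs shared by the fitting methods.

    ``criterion`` selects the goodness-of-fit criterion used both to pick
    the component count inside EM and to compare the three methods.
    ``max_cut_candidates`` caps the number of dichotomisation cuts tried by
    the manual method (None = all cuts, as with a ~40-expert panel).
    """

    criterion: str = "bic"
    eps: float = 1e-3
    max_components: int = 3
    n_restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    max_cut_candidates: int | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")
        if not 1 <= self.max_components <= 3:
            raise ValueError("max_components must be 1..3")


@dataclass
class FitDiagnostics:
    method_id: str
    log_likelihood: float
    criterion_values: dict
    chosen_cut: int | None = None
    chosen_weight: float | None = None
    n_components: int = 1
    loglik_trace: tuple = ()
    competing: dict | None = None

    def __post_init__(self) -> None:
        if not self.criterion_values:
            raise ValueError("criterion_values must be non-empty")
        manual_fields = self.chosen_cut is not None and self.chosen_weight is not None
        if self.method_id == "em_mixture" and manual_fields:
            raise ValueError("em_mixture diagnostics carry no cut/weight")
        if self.method_id in ("manual_two_component", "hybrid") and not manual_fields:
            raise ValueError(f"{self.method_id} diagnostics require cut and weight")


# ---------------------------------------------------------------------------
# elicitation preprocessing
# ---------------------------------------------------------------------------


def compute_differences(
    answers, control_rate: float, eps: float = 1e-3
) -> ElicitedDifferences:
    """Acceptable differences ``d_e = h_e - control_rate``, clamped.

    Zero (or boundary) differences are not admissible margins, so every
    difference is clamped to ``[eps, 1 - eps]``.  Expert order is preserved.
    """
    answers = list(answers)
    if not answers:
        raise ValueError("no elicitation data")
    if not 0.0 < control_rate < 1.0:
        raise ValueError("control_rate must lie strictly inside (0, 1)")
    event_ids = {a.event_id for a in answers}
    if len(event_ids) != 1:
        raise ValueError(f"answers span multiple events: {sorted(event_ids)}")
    h = np.array([a.acceptable_rate for a in answers], dtype=float)
    d = np.clip(h - control_rate, eps, 1.0 - eps)
    return ElicitedDifferences(
        event_id=answers[0].event_id,
        control_rate=float(control_rate),
        differences=tuple(d),
        n_experts=len(answers),
    )


def median_weight(answers) -> float:
    """Median severity weight over a collection of answers (or raw weights)."""
    values = [
        a.severity_weight if isinstance(a, ExpertAnswer) else float(a) for a in answers
    ]
    if not values:
        raise ValueError("no severity weights supplied")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# method 1: EM over 1..K components
# ---------------------------------------------------------------------------


class _EMFailure(RuntimeError):
    pass


def _log_component_matrix(x, shapes, weights):
    parts = []
    for (a, b), w in zip(shapes, weights):
        parts.append(np.log(max(w, 1e-300)) + stats.beta.logpdf(x, a, b))
    return np.stack(parts, axis=0)


def _em_once(x, shapes, weights, max_iter, tol):
    """Run EM from one starting point; returns (mixture, loglik, trace).

    The trace is monotone non-decreasing by construction: an M-step that
    fails to improve the observed-data log-likelihood (numerically) reverts
    and terminates.
    """
    shapes = [tuple(s) for s in shapes]
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    n = x.size
    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        logm = _log_component_matrix(x, shapes, weights)
        lognorm = special.logsumexp(logm, axis=0)
        ll = float(np.sum(lognorm))
        if not np.isfinite(ll):
            raise _EMFailure("non-finite log-likelihood")
        if ll < prev_ll:  # numerical stall: keep the previous (better) state
            break
        trace.append(ll)
        if np.isfinite(prev_ll) and ll - prev_ll <= tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        resp = np.exp(logm - lognorm)
        new_weights = resp.sum(axis=1) / n
        if np.any(new_weights * n < 2.0):
            raise _EMFailure("component collapsed")
        new_shapes = []
        for k, (a, b) in enumerate(shapes):
            new_shapes.append(fit_beta_weighted(x, resp[k], init=(a, b)))
        shapes, weights = new_shapes, new_weights
    mixture = BetaMixture(shapes=tuple(shapes), weights=tuple(weights))
    return mixture, prev_ll, tuple(trace)


def _partition_init(x_sorted, assignment, K):
    shapes, weights = [], []
    for k in range(K):
        xk = x_sorted[assignment == k]
        if xk.size < 2:
            raise _EMFailure("empty init block")
        shapes.append(_moment_init(float(np.mean(xk)), float(np.var(xk))))
        weights.append(xk.size)
    return shapes, np.asarray(weights, dtype=float)


def _em_best(x, K, config: FitConfig):
    """Best of method-of-moments quantile init plus seeded random restarts."""
    xs = np.sort(x)
    n = xs.size
    starts = []
    quantile_assignment = np.minimum((np.arange(n) * K) // n, K - 1)
    starts.append(quantile_assignment)
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_restarts):
        starts.append(rng.integers(0, K, size=n))
    best = None
    for assignment in starts:
        try:
            init_shapes, init_weights = _partition_init(xs, np.asarray(assignment), K)
            fit = _em_once(xs, init_shapes, init_weights, config.max_iter, config.tol)
        except _EMFailure:
            continue
        if best is None or fit[1] > best[1]:
            best = fit
    if best is None:
        raise _EMFailure(f"EM failed for K={K}")
    return best


def fit_mixture_em(values, max_components: int = 3, config: FitConfig | None = None):
    """EM fits for K = 1..max_components; K chosen by the configured criterion."""
    cfg = config or FitConfig()
    cfg = replace(cfg, max_components=max_components)
    x = _validate_open_unit(values)
    n_distinct = np.unique(x).size
    per_k = {}
    for K in range(1, max_components + 1):
        if n_distinct < 2 * K:
            warnings.warn(f"skipping K={K}: fewer than {2 * K} distinct values")
            continue
        if K == 1:
            a, b = fit_beta_ml(x)
            mixture = BetaMixture(shapes=((a, b),), weights=(1.0,))
            ll = mixture.loglik(x)
            per_k[K] = (mixture, ll, (ll,))
        else:
            try:
                per_k[K] = _em_best(x, K, cfg)
            except _EMFailure as exc:
                warnings.warn(f"skipping K={K}: {exc}")
    if not per_k:
        raise RuntimeError("EM failed for every component count")
    scored = {}
    for K, (mixture, ll, _trace) in per_k.items():
        table = criterion_table(mixture, x, loglik=ll)
        scored[K] = (criterion_score(cfg.criterion, table), table)
    best_k = min(scored, key=lambda K: (scored[K][0], K))
    mixture, ll, trace = per_k[best_k]
    diagnostics = FitDiagnostics(
        method_id="em_mixture",
        log_likelihood=ll,
        criterion_values=scored[best_k][1],
        n_components=best_k,
        loglik_trace=trace,
    )
    return mixture, diagnostics


# ---------------------------------------------------------------------------
# method 2: manual dichotomisation x weight grid
# ---------------------------------------------------------------------------


def _fit_side(values) -> tuple:
    if np.unique(values).size < 2:
        return degenerate_beta(float(np.mean(values)))
    return fit_beta_ml(values)


def _cut_candidates(n: int, cap: int | None):
    # left side spans from the two smallest values to all but the two largest
    cuts = np.arange(2, n - 1)
    if cap is not None and cuts.size > cap:
        idx = np.unique(np.linspace(0, cuts.size - 1, cap).round().astype(int))
        cuts = cuts[idx]
    return cuts


def fit_manual_two_component(values, config: FitConfig | None = None):
    """Two betas split at every candidate cut, mixed over the 21-weight grid.

    Returns the (cut, weight) pair minimising the configured criterion.
    Endpoint weights 0 and 1 collapse the mixture to a single side.
    """
    cfg = config or FitConfig()
    x = _validate_open_unit(values)
    if x.size < 4:
        raise ValueError("manual two-component fit needs at least 4 values")
    xs = np.sort(x)
    best = None  # (score, n_active, cut, w1, mixture, ll)
    for cut in _cut_candidates(xs.size, cfg.max_cut_candidates):
        left, right = xs[:cut], xs[cut:]
        a1, b1 = _fit_side(left)
        a2, b2 = _fit_side(right)
        logf1 = stats.beta.logpdf(xs, a1, b1)
        logf2 = stats.beta.logpdf(xs, a2, b2)
        for w1 in WEIGHT_GRID:
            if w1 == 0.0:
                mixture = BetaMixture(shapes=((a2, b2),), weights=(1.0,))
                ll = float(np.sum(logf2))
            elif w1 == 1.0:
                mixture = BetaMixture(shapes=((a1, b1),), weights=(1.0,))
                ll = float(np.sum(logf1))
            else:
                mixture = BetaMixture(
                    shapes=((a1, b1), (a2, b2)), weights=(w1, 1.0 - w1)
                )
                ll = float(
                    np.sum(
                        special.logsumexp(
                            np.stack(
                                [np.log(w1) + logf1, np.log(1.0 - w1) + logf2]
                            ),
                            axis=0,
                        )
                    )
                )
            table = criterion_table(mixture, xs, loglik=ll)
            score = criterion_score(cfg.criterion, table)
            key = (score, mixture.n_components, int(cut), float(w1))
            if best is None or key < (best[0], best[1], best[2], best[3]):
                best = (score, mixture.n_components, int(cut), float(w1), mixture, ll, table)
    score, _k, cut, w1, mixture, ll, table = best
    diagnostics = FitDiagnostics(
        method_id="manual_two_component",
        log_likelihood=ll,
        criterion_values=table,
        chosen_cut=cut,
        chosen_weight=w1,
        n_components=mixture.n_components,
        loglik_trace=(ll,),
    )
    return mixture, diagnostics


# ---------------------------------------------------------------------------
# method 3: hybrid (manual left + 2-component EM right)
# ---------------------------------------------------------------------------


def fit_hybrid(values, config: FitConfig | None = None):
    """Left component from method 2; right side refitted by 2-component EM.

    Final weights are ``(w1, (1-w1) v1, (1-w1) v2)`` with ``(v1, v2)`` the
    EM weights.  Falls back to the method-2 result (re-tagged) whenever the
    right side cannot support a 2-component EM.
    """
    cfg = config or FitConfig()
    x = _validate_open_unit(values)
    if x.size < 6:
        raise ValueError("hybrid fit needs at least 6 values")
    manual_mixture, manual_diag = fit_manual_two_component(x, cfg)
    cut, w1 = manual_diag.chosen_cut, manual_diag.chosen_weight
    xs = np.sort(x)
    right = xs[cut:]
    fallback = w1 in (0.0, 1.0) or np.unique(right).size < 4
    if not fallback:
        try:
            em_mixture, _ll, _trace = _em_best(right, 2, cfg)
        except _EMFailure:
            fallback = True
    if fallback:
        warnings.warn("hybrid fit fell back to the manual two-component result")
        diagnostics = FitDiagnostics(
            method_id="hybrid",
            log_likelihood=manual_diag.log_likelihood,
            criterion_values=dict(manual_diag.criterion_values),
            chosen_cut=cut,
            chosen_weight=w1,
            n_components=manual_mixture.n_components,
            loglik_trace=manual_diag.loglik_trace,
        )
        return manual_mixture, diagnostics
    left_shape = manual_mixture.shapes[0]
    v1, v2 = em_mixture.weights
    mixture = BetaMixture(
        shapes=(left_shape, em_mixture.shapes[0], em_mixture.shapes[1]),
        weights=(w1, (1.0 - w1) * v1, (1.0 - w1) * v2),
    )
    ll = mixture.loglik(xs)
    diagnostics = FitDiagnostics(
        method_id="hybrid",
        log_likelihood=ll,
        criterion_values=criterion_table(mixture, xs, loglik=ll),
        chosen_cut=cut,
        chosen_weight=w1,
        n_components=3,
        loglik_trace=(ll,),
    )
    return mixture, diagnostics


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


def select_margin_fit(values, config: FitConfig | None = None):
    """Run all applicable fitting methods and keep the best criterion.

    Ties break toward fewer components, then toward the earlier method in
    ``(em_mixture, manual_two_component, hybrid)``.  The winner's
    diagnostics carry the criterion value of every method that competed.
    """
    cfg = config or FitConfig()
    x = _validate_open_unit(values)
    candidates = {}
    runners = [
        ("em_mixture", lambda: fit_mixture_em(x, cfg.max_components, cfg)),
        ("manual_two_component", lambda: fit_manual_two_component(x, cfg)),
        ("hybrid", lambda: fit_hybrid(x, cfg)),
    ]
    for name, run in runners:
        try:
            candidates[name] = run()
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"method {name} not applicable: {exc}")
    if not candidates:
        raise RuntimeError("no fitting method succeeded")
    competing = {
        name: criterion_score(cfg.criterion, diag.criterion_values)
        for name, (_m, diag) in candidates.items()
    }
    order = {name: i for i, name in enumerate(METHOD_ORDER)}
    winner = min(
        candidates,
        key=lambda name: (
            competing[name],
            candidates[name][0].n_components,
            order[name],
        ),
    )
    mixture, diagnostics = candidates[winner]
    diagnostics.competing = {
        name: diag.criterion_values[cfg.criterion]
        for name, (_m, diag) in candidates.items()
    }
    return mixture, diagnostics
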