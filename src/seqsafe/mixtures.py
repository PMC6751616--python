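"""Finite mixtures of beta distributions and beta maximum-likelihood fitting.

A margin distribution is represented as a :class:`BetaMixture` with at most
three components.  Single-component maximum-likelihood fitting is the shared
building block for all the higher-level fitting routines in
:mod:`seqsafe.elicitation`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MAX_COMPONENTS",
    "SHAPE_BOUNDS",
    "DEGENERATE_ESS",
    "DegenerateFitWarning",
    "BetaMixture",
    "fit_beta_ml",
    "fit_beta_weighted",
    "degenerate_beta",
    "ks_distance",
    "criterion_table",
    "criterion_score",
    "CRITERIA",
]

MAX_COMPONENTS = 3

#: bounds on each beta shape parameter during optimisation
SHAPE_BOUNDS = (1e-3, 1e4)

#: effective sample size of the sharp-spike fallback used when a fitting
#: subset has fewer than two distinct values
DEGENERATE_ESS = 1000.0

CRITERIA = ("loglik", "aic", "bic", "ks")

_LOG_SHAPE_BOUNDS = (math.log(SHAPE_BOUNDS[0]), math.log(SHAPE_BOUNDS[1]))


class DegenerateFitWarning(UserWarning):
    """Raised (as a warning) when a degenerate spike replaces a beta MLE."""


@dataclass(frozen=True)
class BetaMixture:
    """Mixture of up to three beta densities on (0, 1).

    Parameters
    ----------
    shapes
        Sequence of ``(a, b)`` pairs, all strictly positive.
    weights
        Mixing weights, same length as ``shapes``, non-negative, summing
        to one within ``1e-9``.
    """

    shapes: tuple
    weights: tuple

    def __post_init__(self) -> None:
        shapes = tuple((float(a), float(b)) for a, b in self.shapes)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "shapes", shapes)
        object.__setattr__(self, "weights", weights)
        if not 1 <= len(shapes) <= MAX_COMPONENTS:
            raise ValueError(
                f"mixture must have 1..{MAX_COMPONENTS} components, got {len(shapes)}"
            )
        if len(weights) != len(shapes):
            raise ValueError("shapes and weights must have the same length")
        for a, b in shapes:
            if not (a > 0 and b > 0) or not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"shape parameters must be strictly positive, got ({a}, {b})")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 within 1e-9, got {sum(weights)}")

    # -- basic descriptors -------------------------------------------------

    @property
    def n_components(self) -> int:
        return len(self.shapes)

    @property
    def component_means(self) -> tuple:
        return tuple(a / (a + b) for a, b in self.shapes)

    def mean(self) -> float:
        return float(sum(w * m for w, m in zip(self.weights, self.component_means)))

    def pruned(self) -> "BetaMixture":
        """Drop zero-weight components (re-normalising is a no-op then)."""
        keep = [(s, w) for s, w in zip(self.shapes, self.weights) if w > 0.0]
        if len(keep) == len(self.shapes):
            return self
        shapes, weights = zip(*keep)
        return BetaMixture(shapes=shapes, weights=weights)

    # -- density / distribution --------------------------------------------

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for (a, b), w in zip(self.shapes, self.weights):
            if w > 0:
                out = out + w * stats.beta.pdf(x, a, b)
        return out

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        parts = [
            np.log(w) + stats.beta.logpdf(x, a, b)
            for (a, b), w in zip(self.shapes, self.weights)
            if w > 0
        ]
        return special.logsumexp(np.stack(parts, axis=0), axis=0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for (a, b), w in zip(self.shapes, self.weights):
            if w > 0:
                out = out + w * stats.beta.cdf(x, a, b)
        return out

    def loglik(self, values) -> float:
        return float(np.sum(self.logpdf(values)))

    def sample(self, n: int, seed=None, rng: np.random.Generator | None = None):
        """Draw ``n`` values: component first, then a beta draw.

        Exactly one of ``seed`` or ``rng`` should be supplied; ``rng`` takes
        precedence so callers can share one stream.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        w = np.asarray(self.weights)
        comp = rng.choice(self.n_components, size=n, p=w / w.sum())
        a = np.array([s[0] for s in self.shapes])[comp]
        b = np.array([s[1] for s in self.shapes])[comp]
        return rng.beta(a, b)


def point_mass_mixture(location: float, ess: float = 1e6) -> BetaMixture:
    """Near-degenerate single-component mixture concentrated at ``location``."""
    if not 0 < location < 1:
        raise ValueError("location must lie strictly inside (0, 1)")
    return BetaMixture(shapes=((location * ess, (1 - location) * ess),), weights=(1.0,))


# ---------------------------------------------------------------------------
# single-beta maximum likelihood
# ---------------------------------------------------------------------------


def _validate_open_unit(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no values supplied")
    if np.any(~np.isfinite(x)) or np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("all values must lie strictly inside (0, 1)")
    return x


def degenerate_beta(mean: float, ess: float = DEGENERATE_ESS) -> tuple:
    """Sharp-spike beta with the given mean and a fixed effective sample size.

    Fallback for subsets with fewer than two distinct values, where the
    likelihood has no interior maximum.  Emits :class:`DegenerateFitWarning`.
    """
    m = min(max(float(mean), 1e-6), 1 - 1e-6)
    a = np.clip(m * ess, *SHAPE_BOUNDS)
    b = np.clip((1 - m) * ess, *SHAPE_BOUNDS)
    warnings.warn(
        f"degenerate subset: using spike Beta({a:.4g}, {b:.4g}) at mean {m:.4g}",
        DegenerateFitWarning,
        stacklevel=3,
    )
    return float(a), float(b)


def _moment_init(mean: float, var: float) -> tuple:
    # method-of-moments, guarded against over-dispersion
    m = min(max(mean, 1e-6), 1 - 1e-6)
    vmax = m * (1 - m)
    if not np.isfinite(var) or var <= 0 or var >= vmax:
        var = vmax / 4.0
    t = vmax / var - 1.0
    t = max(t, 1e-2)
    return max(m * t, SHAPE_BOUNDS[0]), max((1 - m) * t, SHAPE_BOUNDS[0])


def _mle_from_stats(s1: float, s2: float, init: tuple) -> tuple:
    """Maximise the beta log-likelihood given mean-log sufficient statistics.

    ``s1 = mean(log x)``, ``s2 = mean(log(1-x))``.  Optimised over
    ``(log a, log b)`` with analytic gradient.
    """

    def nll(u):
        a, b = np.exp(u)
        return special.betaln(a, b) - (a - 1.0) * s1 - (b - 1.0) * s2

    def grad(u):
        a, b = np.exp(u)
        dab = special.digamma(a + b)
        return np.array(
            [
                a * (special.digamma(a) - dab - s1),
                b * (special.digamma(b) - dab - s2),
            ]
        )

    u0 = np.log(np.clip(init, *SHAPE_BOUNDS))
    res = optimize.minimize(
        nll,
        u0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[_LOG_SHAPE_BOUNDS, _LOG_SHAPE_BOUNDS],
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_beta_ml(values) -> tuple:
    """Maximum-likelihood ``(a, b)`` for a single beta on values in (0, 1).

    Initialised by the method of moments.  With fewer than two distinct
    values the degenerate spike fallback is returned (with a warning).
    """
    x = _validate_open_unit(values)
    if np.unique(x).size < 2:
        return degenerate_beta(float(np.mean(x)))
    s1 = float(np.mean(np.log(x)))
    s2 = float(np.mean(np.log1p(-x)))
    init = _moment_init(float(np.mean(x)), float(np.var(x)))
    return _mle_from_stats(s1, s2, init)


def fit_beta_weighted(values, weights, init: tuple | None = None) -> tuple:
    """Weighted beta MLE (M-step of EM); ``weights`` are responsibilities."""
    x = np.asarray(values, dtype=float)
    r = np.asarray(weights, dtype=float)
    total = float(r.sum())
    if total <= 0:
        raise ValueError("total responsibility is zero")
    s1 = float(np.sum(r * np.log(x)) / total)
    s2 = float(np.sum(r * np.log1p(-x)) / total)
    if init is None:
        m = float(np.sum(r * x) / total)
        v = float(np.sum(r * (x - m) ** 2) / total)
        init = _moment_init(m, v)
    return _mle_from_stats(s1, s2, init)


# ---------------------------------------------------------------------------
# goodness-of-fit criteria
# ---------------------------------------------------------------------------


def ks_distance(mixture: BetaMixture, values) -> float:
    """Kolmogorov-Smirnov distance between the mixture CDF and the ECDF."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    cdf = mixture.cdf(x)
    hi = np.max(np.arange(1, n + 1) / n - cdf)
    lo = np.max(cdf - np.arange(0, n) / n)
    return float(max(hi, lo))


def n_free_parameters(n_components: int) -> int:
    """2 shapes per component plus K-1 free weights."""
    return 3 * n_components - 1


def criterion_table(mixture: BetaMixture, values, loglik: float | None = None) -> dict:
    """All goodness-of-fit criteria for one fitted mixture on one sample."""
    x = np.asarray(values, dtype=float).ravel()
    if loglik is None:
        loglik = mixture.loglik(x)
    active = sum(1 for w in mixture.weights if w > 0)
    k = n_free_parameters(active)
    n = x.size
    return {
        "loglik": float(loglik),
        "aic": float(2 * k - 2 * loglik),
        "bic": float(k * math.log(n) - 2 * loglik),
        "ks": ks_distance(mixture, x),
    }


def criterion_score(name: str, table: dict) -> float:
    """Lower-is-better score for a named criterion."""
    if name not in CRITERIA:
        raise ValueError(f"unknown criterion {name!r}; choose from {CRITERIA}")
    value = table[name]
    return -value if name == "loglik" else value
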