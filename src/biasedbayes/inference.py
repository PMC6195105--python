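"""Exponentially biased Bayesian updating.

The central object of the package is the update rule

    P(H | D)  ∝  P(D | H)**beta * P(H)**alpha

where ``alpha`` exponentially biases the prior and ``beta`` the likelihood.
``alpha = beta = 1`` recovers standard Bayes; exponents below 1 flatten the
corresponding distribution (raise its entropy), exponents above 1 sharpen it.
All probability arithmetic happens in log space and normalization is a
log-sum-exp, so extreme exponents remain numerically stable.

Discrete hypothesis spaces live in :class:`DiscreteDistribution` (normalized)
and :class:`LikelihoodTable` (unnormalized weights).  Gaussian prior/likelihood
pairs additionally admit the conjugate closed form
(:func:`gaussian_biased_update`), which the grid machinery is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BiasParams",
    "DiscreteDistribution",
    "LikelihoodTable",
    "GaussianDist",
    "RewardFunction",
    "biased_update",
    "exponential_bias",
    "gaussian_biased_update",
    "sequential_update",
    "combine_with_reward",
    "point_estimate",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class BiasParams:
    """The (alpha, beta) point on the bias plane.

    ``alpha`` is the exponent applied to the prior, ``beta`` the exponent
    applied to the likelihood.  Both must be non-negative; zero is allowed as
    the flattening limit.  ``math.inf`` is accepted as a sentinel (maximum
    prior / maximum likelihood limits) but only mode-returning estimation in
    :mod:`biasedbayes.plane` consumes it — :func:`biased_update` rejects it.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if math.isnan(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def finite(self) -> bool:
        return math.isfinite(self.alpha) and math.isfinite(self.beta)


def _check_support(support: np.ndarray) -> np.ndarray:
    if support.ndim != 1 or support.size == 0:
        raise ValueError("support must be a non-empty 1-d array")
    if support.dtype.kind in "fiu":
        if not np.all(np.diff(support.astype(float)) > 0):
            raise ValueError("numeric support must be strictly increasing")
    else:
        if len(set(support.tolist())) != support.size:
            raise ValueError("support entries must be unique")
    return support


def _same_support(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and bool(np.array_equal(a, b))


class DiscreteDistribution:
    """A normalized probability mass function on a finite support.

    Parameters
    ----------
    support
        Ordered hypothesis values — a strictly increasing numeric grid or a
        sequence of unique categorical labels.
    log_mass
        One log value per support point; normalized on construction.  Entries
        may be ``-inf`` (zero mass) but not all of them.
    """

    def __init__(self, support, log_mass) -> None:
        self.support = _check_support(np.asarray(support))
        lm = np.asarray(log_mass, dtype=float)
        if lm.shape != self.support.shape:
            raise ValueError("log_mass must match support length")
        if np.any(np.isnan(lm)) or np.any(lm == np.inf):
            raise ValueError("log_mass must be finite or -inf")
        z = logsumexp(lm)
        if not np.isfinite(z):
            raise ValueError("all-zero mass is forbidden")
        self.log_mass = lm - z

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_probs(cls, support, probs) -> "DiscreteDistribution":
        p = np.asarray(probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        with np.errstate(divide="ignore"):
            return cls(support, np.log(p))

    @classmethod
    def uniform(cls, support) -> "DiscreteDistribution":
        support = np.asarray(support)
        return cls(support, np.zeros(len(support)))

    # -- views -------------------------------------------------------------
    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_mass)

    @property
    def is_numeric(self) -> bool:
        return self.support.dtype.kind in "fiu"

    def entropy(self) -> float:
        """Shannon entropy in nats, treating 0·log 0 as 0."""
        p = self.probs
        nz = p > 0
        return float(-np.sum(p[nz] * self.log_mass[nz]))

    def prob_of(self, value) -> float:
        idx = np.nonzero(self.support == value)[0]
        if idx.size == 0:
            raise KeyError(f"{value!r} not in support")
        return float(np.exp(self.log_mass[idx[0]]))

    def __len__(self) -> int:
        return len(self.support)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiscreteDistribution(n={len(self)}, support=[{self.support[0]!r}..{self.support[-1]!r}])"


class LikelihoodTable:
    """Unnormalized evidence weights P(D | H) on a support.

    Unlike :class:`DiscreteDistribution` the weights need not sum to one —
    a likelihood is a function of the hypothesis, not a distribution over it.
    """

    def __init__(self, support, log_weight) -> None:
        self.support = _check_support(np.asarray(support))
        lw = np.asarray(log_weight, dtype=float)
        if lw.shape != self.support.shape:
            raise ValueError("log_weight must match support length")
        if np.any(np.isnan(lw)) or np.any(lw == np.inf):
            raise ValueError("log_weight must be finite or -inf")
        if not np.any(np.isfinite(lw)):
            raise ValueError("at least one weight must be non-zero")
        self.log_weight = lw

    @classmethod
    def from_weights(cls, support, weights) -> "LikelihoodTable":
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        with np.errstate(divide="ignore"):
            return cls(support, np.log(w))

    def __len__(self) -> int:
        return len(self.support)


@dataclass(frozen=True)
class GaussianDist:
    """Gaussian distribution, the conjugate companion of the grid machinery."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"variance must be > 0, got {self.variance}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def grid(self, lo: float | None = None, hi: float | None = None, n: int = 2001) -> np.ndarray:
        """Default evaluation grid [mean ± 6 sd] with ``n`` points."""
        if lo is None:
            lo = self.mean - 6 * self.sd
        if hi is None:
            hi = self.mean + 6 * self.sd
        return np.linspace(lo, hi, n)

    def log_pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return -0.5 * (x - self.mean) ** 2 / self.variance - 0.5 * math.log(
            2 * math.pi * self.variance
        )

    def discretize(self, grid: np.ndarray) -> DiscreteDistribution:
        return DiscreteDistribution(grid, self.log_pdf(grid))

    def to_likelihood(self, grid: np.ndarray) -> LikelihoodTable:
        return LikelihoodTable(grid, self.log_pdf(grid))


class RewardFunction:
    """Strictly positive reward values Rwd(x) aligned with a support."""

    def __init__(self, support, values) -> None:
        self.support = _check_support(np.asarray(support))
        v = np.asarray(values, dtype=float)
        if v.shape != self.support.shape:
            raise ValueError("values must match support length")
        if not np.all(v > 0):
            raise ValueError("reward values must be strictly positive")
        self.values = v

    def __len__(self) -> int:
        return len(self.support)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _scaled_log(log_values: np.ndarray, exponent: float) -> np.ndarray:
    """exponent * log_values with the convention 0 * (-inf) = 0.

    An exponent of exactly zero flattens the distribution completely — the
    term drops out of the update even at zero-mass points.
    """
    if exponent == 0.0:
        return np.zeros_like(log_values)
    return exponent * log_values


def biased_update(
    prior: DiscreteDistribution, likelihood: LikelihoodTable, bias: BiasParams
) -> DiscreteDistribution:
    """One exponentially biased Bayes step on a shared support.

    Returns the normalized posterior with
    ``log_mass ∝ beta * log P(D|H) + alpha * log P(H)``.  The normalization
    constant is the log-sum-exp of that combination.

    Raises
    ------
    ValueError
        If the supports differ, the bias is non-finite, or every support
        point has zero combined mass (degenerate posterior).
    """
    if not _same_support(prior.support, likelihood.support):
        raise ValueError("prior and likelihood supports do not match")
    if not bias.finite:
        raise ValueError("biased_update requires finite (alpha, beta); "
                         "infinite sentinels are handled by plane.estimate")
    combined = _scaled_log(likelihood.log_weight, bias.beta) + _scaled_log(
        prior.log_mass, bias.alpha
    )
    if not np.any(np.isfinite(combined)):
        raise ValueError("degenerate posterior: zero mass everywhere")
    return DiscreteDistribution(prior.support, combined)


def exponential_bias(dist: DiscreteDistribution, gamma: float) -> DiscreteDistribution:
    """Raise a distribution to the power ``gamma`` and renormalize.

    ``gamma < 1`` flattens (entropy can only increase), ``gamma > 1`` sharpens
    (entropy can only decrease), ``gamma = 0`` yields the uniform distribution.
    """
    if math.isnan(gamma) or gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    return DiscreteDistribution(dist.support, _scaled_log(dist.log_mass, gamma))


def gaussian_biased_update(
    prior: GaussianDist, likelihood: GaussianDist, bias: BiasParams
) -> GaussianDist:
    """Closed-form biased update for a Gaussian prior/likelihood pair.

    Raising a Gaussian to a power rescales its precision, so the biased
    posterior is again Gaussian::

        precision = alpha / var_prior + beta / var_like
        mean      = (alpha * mu_p / var_p + beta * mu_l / var_l) / precision

    ``alpha = beta = 0`` is rejected: a flat density on unbounded support is
    improper (on a bounded grid the same limit is simply uniform).
    """
    if not bias.finite:
        raise ValueError("gaussian_biased_update requires finite bias")
    precision = bias.alpha / prior.variance + bias.beta / likelihood.variance
    if precision <= 0:
        raise ValueError("improper (flat) posterior on unbounded support: alpha = beta = 0")
    mean = (
        bias.alpha * prior.mean / prior.variance
        + bias.beta * likelihood.mean / likelihood.variance
    ) / precision
    return GaussianDist(mean, 1.0 / precision)


def sequential_update(
    initial_prior: DiscreteDistribution,
    likelihood_stream,
    bias: BiasParams,
) -> list[DiscreteDistribution]:
    """Iterated biased updating: each posterior becomes the next prior.

    The prior exponent ``alpha`` is applied once per step, so after *n* steps
    the initial prior enters with total exponent ``alpha**n`` — with
    ``alpha < 1`` the initial belief is progressively forgotten, with
    ``alpha > 1`` it hardens into a stereotype.

    Returns the full trajectory ``[initial_prior, post_1, ..., post_n]``.
    """
    trajectory = [initial_prior]
    current = initial_prior
    for table in likelihood_stream:
        current = biased_update(current, table, bias)
        trajectory.append(current)
    return trajectory


def combine_with_reward(
    posterior: DiscreteDistribution, reward: RewardFunction
) -> LikelihoodTable:
    """Expected-value table: log EV(x) = log P(x) + log Rwd(x).

    The result is deliberately *not* renormalized — expected value is not a
    probability.  It is returned as a :class:`LikelihoodTable` so downstream
    code (e.g. the 2AFC starting point) can take ratios directly.
    """
    if not _same_support(posterior.support, reward.support):
        raise ValueError("posterior and reward supports do not match")
    return LikelihoodTable(posterior.support, posterior.log_mass + np.log(reward.values))


def point_estimate(dist: DiscreteDistribution, kind: str = "mode"):
    """Collapse a distribution to a representative value.

    ``mode`` works on any support (ties broken toward the smallest / first
    support value, deterministically); ``mean`` and ``median`` require a
    numeric support.  The median is the smallest support value whose CDF
    reaches 0.5.
    """
    if kind == "mode":
        return dist.support[int(np.argmax(dist.log_mass))]
    if not dist.is_numeric:
        raise ValueError(f"{kind} requires a numeric support")
    x = dist.support.astype(float)
    p = dist.probs
    if kind == "mean":
        return float(np.sum(x * p))
    if kind == "median":
        cdf = np.cumsum(p)
        return float(x[int(np.searchsorted(cdf, 0.5))])
    raise ValueError(f"unknown point estimate kind: {kind!r}")
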