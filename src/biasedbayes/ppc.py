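"""Probabilistic population codes over log-densities.

A population of units with basis (tuning) functions ``h_i(x)`` represents a
distribution through ``log P(x) = sum_i r_i h_i(x) + const``.  Because the
code is linear in log probability, multiplying distributions is *adding* rate
vectors, and the biased update becomes a pure gain change at the combination:
``r_posterior = alpha * r_prior + beta * r_likelihood``.

The basis here is a bank of Gaussian bumps with evenly spaced centers and a
shared width, plus an implicit constant direction that absorbs the additive
normalizer ("const."): encoding projects the log-density onto the bump span
with the constant direction removed, decoding exponentiates and renormalizes.
Rates may be negative — the code carries log probabilities; a non-negative
"biological" view is a display offset, not part of the math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .inference import BiasParams, DiscreteDistribution, LikelihoodTable

__all__ = [
    "BasisSet",
    "PopulationRates",
    "BiasOriginRecord",
    "encode",
    "decode",
    "combine",
    "gain_modulate",
    "simulate_bias_origin",
]

#: log-mass floor applied before projection so zero-mass grid points stay finite
LOG_FLOOR = -745.0


@dataclass(frozen=True)
class BasisSet:
    """Gaussian-bump basis on an evaluation grid.

    ``design_matrix`` is H with shape (n_grid, n_units); ``includes_constant``
    appends a column of ones during encoding only (its coefficient is
    discarded — the constant belongs to the normalizer, not the code).
    """

    grid: np.ndarray
    centers: np.ndarray
    width: float
    amplitude: float = 1.0
    includes_constant: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")

    @classmethod
    def gaussian(
        cls, grid, n_units: int, width: float, amplitude: float = 1.0,
        includes_constant: bool = True,
    ) -> "BasisSet":
        """Evenly spaced bump centers spanning the grid."""
        grid = np.asarray(grid, dtype=float)
        centers = np.linspace(grid[0], grid[-1], n_units)
        return cls(grid, centers, width, amplitude, includes_constant)

    @property
    def n_units(self) -> int:
        return len(self.centers)

    @property
    def design_matrix(self) -> np.ndarray:
        d = self.grid[:, None] - self.centers[None, :]
        return self.amplitude * np.exp(-0.5 * (d / self.width) ** 2)

    def matches(self, other: "BasisSet") -> bool:
        return (
            np.array_equal(self.grid, other.grid)
            and np.array_equal(self.centers, other.centers)
            and self.width == other.width
            and self.amplitude == other.amplitude
        )


@dataclass
class PopulationRates:
    """Rate coefficients of one population, tied to its basis."""

    rates: np.ndarray
    basis: BasisSet
    provenance: str = "prior"  # {prior, likelihood, posterior}
    residual: float = 0.0  # RMS log-density reconstruction error at encoding

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (self.basis.n_units,):
            raise ValueError("rates length must equal basis n_units")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")


def _log_values(dist) -> np.ndarray:
    if isinstance(dist, DiscreteDistribution):
        return dist.log_mass
    if isinstance(dist, LikelihoodTable):
        return dist.log_weight
    raise TypeError("expected DiscreteDistribution or LikelihoodTable")


def encode(
    dist,
    basis: BasisSet,
    provenance: str | None = None,
    residual_tol: float = 0.1,
) -> PopulationRates:
    """Project a log-density onto the basis span, constant direction removed.

    Ordinary least squares on the design matrix (with a ones column when the
    basis carries a constant element); the constant coefficient is dropped.
    The RMS residual of the fit — invariant to additive constants — is stored
    on the result and triggers a warning above ``residual_tol``.
    """
    if not np.array_equal(np.asarray(dist.support, dtype=float), basis.grid):
        raise ValueError("distribution support must equal the basis grid")
    y = np.maximum(_log_values(dist), LOG_FLOOR)
    H = basis.design_matrix
    A = np.column_stack([H, np.ones(len(basis.grid))]) if basis.includes_constant else H
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient basis: design matrix has dependent columns")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ coef
    residual = float(np.sqrt(np.mean((y - fit) ** 2)))
    if residual > residual_tol:
        warnings.warn(
            f"encoding residual {residual:.3g} exceeds tolerance {residual_tol:.3g}",
            stacklevel=2,
        )
    rates = coef[: basis.n_units]
    if provenance is None:
        provenance = "likelihood" if isinstance(dist, LikelihoodTable) else "prior"
    return PopulationRates(rates, basis, provenance, residual)


def decode(rates: PopulationRates, basis: BasisSet | None = None) -> DiscreteDistribution:
    """Invert the code: mass ∝ exp(H r) on the grid, normalized.

    The additive constant dropped at encoding is resolved by normalization.
    """
    basis = rates.basis if basis is None else basis
    if not rates.basis.matches(basis):
        raise ValueError("rates were encoded with a different basis")
    return DiscreteDistribution(basis.grid, basis.design_matrix @ rates.rates)


def combine(
    r_prior: PopulationRates, r_likelihood: PopulationRates, bias: BiasParams
) -> PopulationRates:
    """Gain-modulated rate summation: alpha * r_prior + beta * r_likelihood."""
    if not r_prior.basis.matches(r_likelihood.basis):
        raise ValueError("populations use different bases")
    rates = bias.alpha * r_prior.rates + bias.beta * r_likelihood.rates
    return PopulationRates(rates, r_prior.basis, "posterior")


def gain_modulate(rates: PopulationRates, gain: float) -> PopulationRates:
    """Multiplicative gain on a whole population.

    Decoding the result yields the ``gain``-th exponential bias of the decoded
    original: amplitude scaling of a log-probability code *is* distribution
    sharpening/flattening.
    """
    if gain < 0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    return PopulationRates(gain * rates.rates, rates.basis, rates.provenance, rates.residual)


@dataclass
class BiasOriginRecord:
    """Layer-by-layer record distinguishing the two origins of a bias.

    ``rate_bias``: the bias is already present in the layer-1 representation
    (the likelihood population fires beta times harder) and the combination
    uses unit gains.  ``connection_bias``: layer-1 rates are unbiased and the
    bias lives in the connection gains.  The decoded posteriors are identical
    by linearity — the layer-1 rates are the observable that tells the two
    apart.
    """

    origin: str
    layer1_prior: PopulationRates
    layer1_likelihood: PopulationRates
    layer2: PopulationRates
    posterior: DiscreteDistribution


def simulate_bias_origin(
    prior: DiscreteDistribution,
    likelihood: LikelihoodTable,
    bias: BiasParams,
    basis: BasisSet,
    origin: str = "connection_bias",
) -> BiasOriginRecord:
    if origin not in ("rate_bias", "connection_bias"):
        raise ValueError(f"unknown origin {origin!r}")
    rp = encode(prior, basis, provenance="prior")
    rl = encode(likelihood, basis, provenance="likelihood")
    if origin == "rate_bias":
        rp = gain_modulate(rp, bias.alpha)
        rl = gain_modulate(rl, bias.beta)
        layer2 = combine(rp, rl, BiasParams(1.0, 1.0))
    else:
        layer2 = combine(rp, rl, bias)
    return BiasOriginRecord(origin, rp, rl, layer2, decode(layer2))
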