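"""The (alpha, beta) bias plane: estimator taxonomy and neuromodulator offsets.

Every point of the plane is an inference method.  (1, 1) is standard Bayes
(MAP if a mode is returned); the alpha axis interpolates MAP with maximum
likelihood (alpha → 0) and "maximum prior" (alpha → ∞); the beta axis does
the same through the likelihood exponent.  The half-plane alpha < beta is
likelihood-dominated ("ML-like" inference, where base-rate neglect and
representativeness live), alpha > beta is prior-dominated ("robust"
inference, home of conservatism and anchoring).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .inference import (
    BiasParams,
    DiscreteDistribution,
    LikelihoodTable,
    biased_update,
    point_estimate,
)

__all__ = [
    "RegionLabel",
    "NeuromodulatorEffect",
    "classify_region",
    "estimator_path_prior",
    "estimator_path_likelihood",
    "estimate",
    "apply_neuromodulator",
    "PSYCHOLOGICAL_BIAS_REGIONS",
]

#: Documented correspondence between classic probability-judgment biases and
#: bias-plane regions.  These are label aliases, not separate code paths: a
#: base-rate fallacy is any inference run at alpha < beta, etc.
PSYCHOLOGICAL_BIAS_REGIONS = {
    "base_rate_fallacy": "ml_like",
    "representativeness": "ml_like",
    "conservatism": "robust",
    "anchoring_and_adjustment": "robust",
}


@dataclass(frozen=True)
class RegionLabel:
    """Total classification of a bias-plane point.

    ``overall`` is one of ``standard`` (exactly (1, 1)), ``ml_like``
    (alpha < beta), ``robust`` (alpha > beta), ``balanced`` (alpha = beta ≠ 1)
    or ``flat_degenerate`` (both exponents below ``eps`` — the posterior is
    essentially flat regardless of the inputs).  ``alpha_regime`` /
    ``beta_regime`` flag the per-axis deviations: forgetting / stereotyping
    for the prior exponent, rigidity / flexibility for the likelihood one;
    ``None`` on the unbiased axis value 1.
    """

    overall: str
    alpha_regime: str | None
    beta_regime: str | None

    def labels(self) -> tuple[str, ...]:
        out = [r for r in (self.alpha_regime, self.beta_regime) if r is not None]
        out.append(self.overall)
        return tuple(out)


def classify_region(bias: BiasParams, eps: float = 1e-6) -> RegionLabel:
    """Classify a bias-plane point.  Total: every valid point gets a label."""
    a, b = bias.alpha, bias.beta
    alpha_regime = "forgetting" if a < 1 else ("stereotyping" if a > 1 else None)
    beta_regime = "rigidity" if b < 1 else ("flexibility" if b > 1 else None)
    if a < eps and b < eps:
        overall = "flat_degenerate"
    elif a == 1 and b == 1:
        overall = "standard"
    elif a < b:
        overall = "ml_like"
    elif a > b:
        overall = "robust"
    else:
        overall = "balanced"
    return RegionLabel(overall, alpha_regime, beta_regime)


def estimator_path_prior(k1: float) -> BiasParams:
    """The horizontal estimator path (alpha = k1, beta = 1).

    k1 = 0 is maximum likelihood, k1 = 1 is MAP/Bayes, 0 < k1 < 1 the
    ML–MAP intermediate (forgetting), k1 > 1 the MAP–MP intermediate
    (stereotyping); ``k1 = math.inf`` is the maximum-prior sentinel.
    """
    if math.isnan(k1) or k1 < 0:
        raise ValueError(f"k1 must be >= 0, got {k1}")
    return BiasParams(alpha=k1, beta=1.0)


def estimator_path_likelihood(k2: float) -> BiasParams:
    """The vertical estimator path (alpha = 1, beta = 1/k2).

    k2 = 1 is MAP/Bayes, 0 < k2 < 1 the ML–MAP intermediate (flexibility),
    k2 > 1 the MAP–MP intermediate (rigidity).  k2 = 0 maps to the beta = ∞
    sentinel: :func:`estimate` resolves it as the likelihood-mode (ML) point
    estimate, past the scale break of the plane.
    """
    if math.isnan(k2) or k2 < 0:
        raise ValueError(f"k2 must be >= 0, got {k2}")
    beta = math.inf if k2 == 0 else 1.0 / k2
    return BiasParams(alpha=1.0, beta=beta)


def _one_hot(support: np.ndarray, index: int) -> DiscreteDistribution:
    lm = np.full(len(support), -np.inf)
    lm[index] = 0.0
    return DiscreteDistribution(support, lm)


def estimate(
    prior: DiscreteDistribution,
    likelihood: LikelihoodTable,
    bias: BiasParams,
    return_kind: str = "mode",
):
    """Unified estimation entry point over the whole (extended) bias plane.

    ``return_kind='distribution'`` returns the biased posterior,
    ``return_kind='mode'`` its mode.  At (1, 1) these are Bayesian and MAP
    estimation; at the beta = ∞ sentinel the argmax of the likelihood (ML);
    at the alpha = ∞ sentinel the argmax of the prior (maximum prior, MP).
    With an infinite sentinel and ``return_kind='distribution'`` the result
    is the corresponding one-hot point mass on the grid.
    """
    if return_kind not in ("mode", "distribution"):
        raise ValueError(f"unknown return_kind: {return_kind!r}")
    if math.isinf(bias.alpha) and math.isinf(bias.beta):
        raise ValueError("alpha and beta cannot both be infinite")
    if math.isinf(bias.beta):
        idx = int(np.argmax(likelihood.log_weight))
        return (
            likelihood.support[idx]
            if return_kind == "mode"
            else _one_hot(likelihood.support, idx)
        )
    if math.isinf(bias.alpha):
        idx = int(np.argmax(prior.log_mass))
        return prior.support[idx] if return_kind == "mode" else _one_hot(prior.support, idx)
    posterior = biased_update(prior, likelihood, bias)
    return posterior if return_kind == "distribution" else point_estimate(posterior, "mode")


# ---------------------------------------------------------------------------
# neuromodulator offsets
# ---------------------------------------------------------------------------

_PRESET_QUADRANTS = {
    # name: (sign of lambda1, sign of lambda2); 0 means unconstrained sign
    "norepinephrine": (+1, +1),
    "acetylcholine": (-1, +1),
    "ei_excess": (+1, +1),
    "ie_excess": (-1, -1),
}


@dataclass(frozen=True)
class NeuromodulatorEffect:
    """Additive offset (lambda1, lambda2) of the bias-plane point.

    ``lambda1`` acts on the recurrent/prior gain (alpha), ``lambda2`` on the
    feedforward/likelihood gain (beta).  ``theta`` is the direction of the
    offset vector in degrees, in [0, 360).  Presets encode the quadrants of
    the major neuromodulators: norepinephrine and excitatory excess push both
    gains up (0°–90°), acetylcholine trades recurrent gain for feedforward
    gain (90°–180°), inhibitory excess pulls both down (180°–270°).
    """

    lambda1: float
    lambda2: float
    preset: str | None = None

    def __post_init__(self) -> None:
        if self.preset is not None:
            if self.preset not in _PRESET_QUADRANTS:
                raise ValueError(f"unknown preset {self.preset!r}")
            s1, s2 = _PRESET_QUADRANTS[self.preset]
            if self.lambda1 * s1 < 0 or self.lambda2 * s2 < 0:
                raise ValueError(
                    f"preset {self.preset!r} violated: "
                    f"(lambda1, lambda2) = ({self.lambda1}, {self.lambda2}) "
                    f"outside its quadrant"
                )

    @property
    def theta(self) -> float:
        """Angle of the offset vector, degrees in [0, 360)."""
        t = math.degrees(math.atan2(self.lambda2, self.lambda1))
        return t % 360.0

    @classmethod
    def norepinephrine(cls, lambda1: float, lambda2: float) -> "NeuromodulatorEffect":
        return cls(lambda1, lambda2, preset="norepinephrine")

    @classmethod
    def acetylcholine(cls, lambda1: float, lambda2: float) -> "NeuromodulatorEffect":
        return cls(lambda1, lambda2, preset="acetylcholine")

    @classmethod
    def ei_excess(cls, lambda1: float, lambda2: float) -> "NeuromodulatorEffect":
        return cls(lambda1, lambda2, preset="ei_excess")

    @classmethod
    def ie_excess(cls, lambda1: float, lambda2: float) -> "NeuromodulatorEffect":
        return cls(lambda1, lambda2, preset="ie_excess")


def apply_neuromodulator(bias: BiasParams, effect: NeuromodulatorEffect) -> BiasParams:
    """Shift (alpha, beta) by (lambda1, lambda2), clipped at zero.

    Negative results are clamped to 0 (the positivity assumption of the
    framework) with a warning — below zero the exponents have no meaning.
    """
    a = bias.alpha + effect.lambda1
    b = bias.beta + effect.lambda2
    if a < 0 or b < 0:
        warnings.warn(
            f"neuromodulator offset clipped at zero: ({a:.3g}, {b:.3g})",
            stacklevel=2,
        )
    return BiasParams(max(0.0, a), max(0.0, b))
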