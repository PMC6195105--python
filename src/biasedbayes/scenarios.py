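"""Named synthetic scenarios used across the package and the CLI.

Each scenario realizes a standard laboratory situation: the rare-disease
screening problem (discrete two-hypothesis update), Gaussian cue combination
(conjugate prior/likelihood pair), a motion-discrimination log-likelihood-
ratio stream for the 2AFC simulator, and a balanced Stroop trial block.
Defaults live in the packaged ``data/scenarios.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .inference import (
    DiscreteDistribution,
    GaussianDist,
    LikelihoodTable,
    RewardFunction,
)
from .stroop import StroopTrial, make_balanced_block

__all__ = ["Scenario", "make_scenario", "available_scenarios", "load_scenario_config"]

_GRID_SCENARIOS = ("disease_test", "gaussian_cue_combination")
_ALL_SCENARIOS = _GRID_SCENARIOS + ("dot_motion_llr", "stroop_block")


@dataclass
class Scenario:
    name: str
    prior: DiscreteDistribution | GaussianDist
    likelihood: LikelihoodTable | GaussianDist
    reward: RewardFunction | None = None
    note: str = ""


def load_scenario_config() -> dict:
    text = resources.files("biasedbayes.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


def available_scenarios() -> tuple[str, ...]:
    return _ALL_SCENARIOS


def make_scenario(name: str, params: dict | None = None, seed: int | None = None):
    """Build a named scenario.

    ``disease_test`` and ``gaussian_cue_combination`` return a
    :class:`Scenario`; ``dot_motion_llr`` returns a seeded numpy array of
    per-bin llr draws; ``stroop_block`` returns a list of
    :class:`~biasedbayes.stroop.StroopTrial`.  ``params`` overrides the
    packaged defaults key by key.
    """
    cfg = load_scenario_config()
    if name not in cfg:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        )
    spec = dict(cfg[name])
    spec.update(params or {})

    if name == "disease_test":
        support = np.asarray(spec["support"])
        prior = DiscreteDistribution.from_probs(support, spec["prior"])
        likelihood = LikelihoodTable.from_weights(support, spec["likelihood_positive"])
        return Scenario(name, prior, likelihood, note=spec.get("note", ""))

    if name == "gaussian_cue_combination":
        prior = GaussianDist(spec["prior"]["mean"], spec["prior"]["variance"])
        likelihood = GaussianDist(spec["likelihood"]["mean"], spec["likelihood"]["variance"])
        return Scenario(name, prior, likelihood, note=spec.get("note", ""))

    if name == "dot_motion_llr":
        rng = np.random.default_rng(seed)
        dt = float(spec["dt"])
        n = int(spec["n_bins"])
        return rng.normal(
            float(spec["llr_mean"]) * dt, float(spec["llr_sd"]) * np.sqrt(dt), n
        )

    if name == "stroop_block":
        return make_balanced_block(int(spec["n"]), tuple(spec["palette"]), seed=seed)

    raise AssertionError("unreachable")  # pragma: no cover


def scenario_on_grid(scenario: Scenario, n: int = 2001):
    """Discretize a Gaussian scenario onto a shared grid (no-op for grids).

    Returns ``(prior, likelihood)`` as grid objects ready for
    :func:`~biasedbayes.inference.biased_update`.  The grid spans both
    Gaussians' ±6 sd ranges.
    """
    prior, like = scenario.prior, scenario.likelihood
    if isinstance(prior, DiscreteDistribution):
        return prior, like
    lo = min(prior.mean - 6 * prior.sd, like.mean - 6 * like.sd)
    hi = max(prior.mean + 6 * prior.sd, like.mean + 6 * like.sd)
    grid = np.linspace(lo, hi, n)
    return prior.discretize(grid), like.to_likelihood(grid)
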