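"""Stroop conflict monitoring as biased Bayesian inference.

Two perception channels emit log-likelihood vectors over the response labels:
a word-reading channel (strong pathway, weight ``w_word``) and an ink-color
channel (weak pathway, ``w_color``).  A response-layer integrator accumulates
``beta_word * r_word + beta_color * r_color`` from a flat prior; the response
is read out when the softmax posterior over labels crosses a threshold.

Conflict is the pairwise product of the softmax response activations —
maximal when candidate responses fire equally, zero when one dominates —
and drives a between-trial gain controller that increments the task-relevant
beta in proportion to the conflict (the monitor→controller loop).  A static
"task set" additionally attenuates the task-irrelevant channel; without some
task-dependent asymmetry a two-pathway race cannot produce the asymmetric
interference that defines the Stroop effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integrator import IntegratorConfig, IntegratorState, step as integrator_step

__all__ = [
    "StroopConfig",
    "StroopTrial",
    "StroopResult",
    "perception_rates",
    "effective_gains",
    "response_step",
    "conflict",
    "control_update",
    "simulate_stroop_trial",
    "simulate_stroop_block",
    "make_balanced_block",
]

DEFAULT_PALETTE = ("red", "green")
TASKS = ("word_reading", "color_naming")


def _default_integrator() -> IntegratorConfig:
    return IntegratorConfig(tau_neuron=1.0, alpha=1.0, beta=1.0, dt=0.1)


@dataclass(frozen=True)
class StroopConfig:
    """Network and controller parameters.

    ``w_word > w_color`` encodes the over-trained reading pathway.
    ``task_set_attenuation`` scales the task-irrelevant channel's gain before
    any conflict-driven control (the task-demand baseline); ``eta`` is the
    conflict-to-gain learning rate and ``beta_max`` the gain ceiling.
    ``noise_sd`` is per-step Gaussian input noise so RTs and errors have
    distributions.
    """

    w_word: float = 1.0
    w_color: float = 0.6
    beta_word: float = 1.0
    beta_color: float = 1.0
    contrast: float = 1.0
    task_set_attenuation: float = 0.5
    integrator: IntegratorConfig = field(default_factory=_default_integrator)
    response_threshold: float = 0.75
    eta: float = 0.0
    beta_max: float = 2.0
    noise_sd: float = 0.05
    max_time: float = 50.0
    suppress_irrelevant: bool = False
    palette: tuple[str, ...] = DEFAULT_PALETTE
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w_word <= self.w_color:
            warnings.warn(
                "w_word <= w_color: the reading pathway is conventionally the "
                "stronger one",
                stacklevel=2,
            )
        if not (0 <= self.beta_word <= self.beta_max and 0 <= self.beta_color <= self.beta_max):
            raise ValueError("gains must lie in [0, beta_max]")
        if not (0.5 < self.response_threshold < 1):
            raise ValueError("response_threshold must lie in (0.5, 1)")
        if self.eta < 0 or self.noise_sd < 0:
            raise ValueError("eta and noise_sd must be >= 0")
        if len(self.palette) < 2:
            raise ValueError("palette needs at least 2 colors")


@dataclass(frozen=True)
class StroopTrial:
    word: str
    ink: str
    task: str  # "word_reading" | "color_naming"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def congruent(self) -> bool:
        return self.word == self.ink

    @property
    def correct_response(self) -> str:
        return self.word if self.task == "word_reading" else self.ink


@dataclass
class StroopResult:
    trial: StroopTrial
    response: str
    rt: float
    correct: bool
    censored: bool
    conflict_trace: np.ndarray
    gains: tuple[float, float]  # (beta_word, beta_color) in force on this trial


def _softmax(r: np.ndarray) -> np.ndarray:
    z = r - np.max(r)
    e = np.exp(z)
    return e / e.sum()


def perception_rates(trial: StroopTrial, config: StroopConfig):
    """Log-likelihood vectors over response labels from the two channels.

    Two-level template: each channel puts ``contrast`` on its own feature's
    label and 0 elsewhere, scaled by its pathway strength.
    """
    palette = list(config.palette)
    for label in (trial.word, trial.ink):
        if label not in palette:
            raise ValueError(f"unknown color label {label!r}")
    word_rates = np.zeros(len(palette))
    color_rates = np.zeros(len(palette))
    word_rates[palette.index(trial.word)] = config.contrast
    color_rates[palette.index(trial.ink)] = config.contrast
    return config.w_word * word_rates, config.w_color * color_rates


def effective_gains(
    config: StroopConfig, task: str, gains: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Controller gains with the task-set attenuation of the irrelevant channel."""
    bw, bc = gains if gains is not None else (config.beta_word, config.beta_color)
    if task == "word_reading":
        return bw, bc * config.task_set_attenuation
    return bw * config.task_set_attenuation, bc


def response_step(
    state: IntegratorState,
    word_rates: np.ndarray,
    color_rates: np.ndarray,
    config: StroopConfig,
    gains: tuple[float, float] | None = None,
    noise: np.ndarray | None = None,
) -> IntegratorState:
    """One response-layer integrator step with gain-weighted channel input."""
    bw, bc = gains if gains is not None else (config.beta_word, config.beta_color)
    u = bw * word_rates + bc * color_rates
    if noise is not None:
        u = u + noise
    return integrator_step(state, u, config.integrator)


def conflict(response_rates: np.ndarray) -> float:
    """Pairwise-product (energy) conflict of the softmax response activations.

    For K labels the measure peaks at the uniform activation pattern
    ((K-1)/(2K)) and vanishes for a one-hot pattern.
    """
    r = np.asarray(response_rates, dtype=float)
    if r.size < 2:
        raise ValueError("conflict needs at least 2 response units")
    p = _softmax(r)
    return float((np.sum(p) ** 2 - np.sum(p**2)) / 2.0)


def control_update(
    gains: tuple[float, float], conflict_value: float, task: str, config: StroopConfig
) -> tuple[float, float]:
    """Conflict-proportional gain increment on the task-relevant channel.

    With ``suppress_irrelevant`` the irrelevant gain is decremented by the
    same amount (biased-competition variant); default is enhancement only.
    Gains are clipped to [0, beta_max].
    """
    if conflict_value < 0:
        raise ValueError("conflict must be >= 0")
    bw, bc = gains
    delta = config.eta * conflict_value
    if task == "word_reading":
        bw += delta
        if config.suppress_irrelevant:
            bc -= delta
    else:
        bc += delta
        if config.suppress_irrelevant:
            bw -= delta
    clip = lambda g: float(min(max(g, 0.0), config.beta_max))
    return clip(bw), clip(bc)


def simulate_stroop_trial(
    trial: StroopTrial,
    config: StroopConfig,
    gains: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> StroopResult:
    """Integrate one trial to the response threshold or the deadline.

    The response layer starts flat (zero rates — a uniform prior in the log
    code) and accumulates the gain-weighted channel input plus per-step noise;
    the response is the label whose softmax mass first exceeds the threshold.
    At the deadline the currently strongest label is forced and the result is
    flagged censored.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if gains is None:
        gains = (config.beta_word, config.beta_color)
    wr, cr = perception_rates(trial, config)
    eff = effective_gains(config, trial.task, gains)
    k = len(config.palette)
    state = IntegratorState(np.zeros(k), 0.0)
    n_steps = int(round(config.max_time / config.integrator.dt))
    conflicts = np.empty(n_steps)
    response_idx = None
    censored = False
    for i in range(n_steps):
        noise = rng.normal(0.0, config.noise_sd, k)
        state = response_step(state, wr, cr, config, gains=eff, noise=noise)
        conflicts[i] = conflict(state.r)
        p = _softmax(state.r)
        j = int(np.argmax(p))
        if p[j] >= config.response_threshold:
            response_idx = j
            conflicts = conflicts[: i + 1]
            break
    if response_idx is None:
        response_idx = int(np.argmax(state.r))
        censored = True
    response = config.palette[response_idx]
    return StroopResult(
        trial=trial,
        response=response,
        rt=float(state.t),
        correct=response == trial.correct_response,
        censored=censored,
        conflict_trace=conflicts,
        gains=gains,
    )


def simulate_stroop_block(
    trials: list[StroopTrial], config: StroopConfig
) -> tuple[list[StroopResult], pd.DataFrame]:
    """Seeded block with optional between-trial conflict control.

    With ``eta > 0`` the mean conflict of each trial increments the next
    trial's task-relevant gain.  Returns per-trial results and the 2x2
    task × congruency summary (mean RT, error rate, mean conflict).
    """
    rng = np.random.default_rng(config.seed)
    gains = (config.beta_word, config.beta_color)
    results: list[StroopResult] = []
    for trial in trials:
        res = simulate_stroop_trial(trial, config, gains=gains, rng=rng)
        results.append(res)
        if config.eta > 0:
            gains = control_update(
                gains, float(np.mean(res.conflict_trace)), trial.task, config
            )
    rows = []
    for task in TASKS:
        for congruent in (True, False):
            sub = [
                r
                for r in results
                if r.trial.task == task and r.trial.congruent == congruent
            ]
            if not sub:
                continue
            rows.append(
                {
                    "task": task,
                    "congruency": "congruent" if congruent else "incongruent",
                    "n": len(sub),
                    "mean_rt": float(np.mean([r.rt for r in sub])),
                    "error_rate": float(np.mean([not r.correct for r in sub])),
                    "mean_conflict": float(
                        np.mean([np.mean(r.conflict_trace) for r in sub])
                    ),
                }
            )
    return results, pd.DataFrame(rows)


def make_balanced_block(
    n: int, palette: tuple[str, ...] = DEFAULT_PALETTE, seed: int | None = None
) -> list[StroopTrial]:
    """Balanced task × congruency trial list (exactly n/4 per cell), shuffled.

    ``n`` must be divisible by 4.
    """
    if n % 4 != 0:
        raise ValueError("n must be divisible by 4 for a balanced 2x2 design")
    rng = np.random.default_rng(seed)
    trials: list[StroopTrial] = []
    per_cell = n // 4
    k = len(palette)
    for task in TASKS:
        for congruent in (True, False):
            for i in range(per_cell):
                word = palette[i % k]
                ink = word if congruent else palette[(i + 1) % k]
                trials.append(StroopTrial(word=word, ink=ink, task=task))
    order = rng.permutation(n)
    return [trials[i] for i in order]
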