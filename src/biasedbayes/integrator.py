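"""Firing-rate dynamics of the recurrent implementation.

A population obeying

    tau * dr/dt = -r + Input = -r + alpha * r + beta * r_likelihood(t)

performs repeated biased updating in continuous time when its state encodes a
log-density: the recurrent gain alpha plays the role of the prior exponent and
the feedforward gain beta that of the likelihood exponent.  alpha = 1 is a
balanced integrator (perfect memory), alpha < 1 leaks (the encoded
distribution flattens over time — forgetting), alpha > 1 is unstable (the
distribution sharpens — stereotyping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["IntegratorConfig", "IntegratorState", "Trajectory", "step", "run", "regime"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Time constant, gains, and step size of one rate population.

    The default guard ``dt <= tau_neuron / 10`` keeps the explicit Euler
    scheme in its accurate regime; disable it only for deliberate
    coarse-stepping experiments.
    """

    tau_neuron: float
    alpha: float
    beta: float = 1.0
    dt: float = 0.01
    enforce_dt_guard: bool = True

    def __post_init__(self) -> None:
        if self.tau_neuron <= 0:
            raise ValueError("tau_neuron must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.enforce_dt_guard and self.dt > self.tau_neuron / 10 + 1e-15:
            raise ValueError(
                f"dt = {self.dt} violates the Euler guard dt <= tau/10 "
                f"(tau = {self.tau_neuron}); pass enforce_dt_guard=False to override"
            )


@dataclass(frozen=True)
class IntegratorState:
    r: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if not np.all(np.isfinite(self.r)):
            raise ValueError("state rates must be finite")


@dataclass
class Trajectory:
    """Dense record of a run: times (n+1,) and rates (n+1, n_units)."""

    times: np.ndarray
    rates: np.ndarray

    @property
    def final(self) -> IntegratorState:
        return IntegratorState(self.rates[-1], float(self.times[-1]))


def step(
    state: IntegratorState, input_rates: np.ndarray, config: IntegratorConfig
) -> IntegratorState:
    """One explicit-Euler step: r += (dt/tau) * ((alpha - 1) r + beta * input)."""
    u = np.asarray(input_rates, dtype=float)
    if u.shape != state.r.shape:
        raise ValueError("input shape does not match state")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input rates")
    dr = (config.dt / config.tau_neuron) * (
        (config.alpha - 1.0) * state.r + config.beta * u
    )
    return IntegratorState(state.r + dr, state.t + config.dt)


def _exact_step(r: np.ndarray, u: np.ndarray, config: IntegratorConfig) -> np.ndarray:
    # closed form of the linear ODE over one dt with input held constant
    k = (config.alpha - 1.0) / config.tau_neuron
    if abs(k) < 1e-15:
        return r + config.beta * u * config.dt / config.tau_neuron
    e = math.exp(k * config.dt)
    return r * e + (config.beta / config.tau_neuron) * u * (e - 1.0) / k


def run(
    config: IntegratorConfig,
    input_series: np.ndarray,
    r0: np.ndarray,
    method: str = "euler",
) -> Trajectory:
    """Integrate over a full input series (one rate vector per step).

    ``method='euler'`` matches the discrete-update reading used by the 2AFC
    model; ``method='exact'`` uses the per-step closed form of the linear ODE
    (input held constant within each step).  Deterministic: identical inputs
    give identical trajectories.
    """
    if method not in ("euler", "exact"):
        raise ValueError(f"unknown method {method!r}")
    u = np.atleast_2d(np.asarray(input_series, dtype=float))
    r0 = np.asarray(r0, dtype=float)
    if u.shape[1] != r0.shape[0]:
        raise ValueError(
            f"input series has {u.shape[1]} units but r0 has {r0.shape[0]}"
        )
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input series")
    n_steps = u.shape[0]
    rates = np.empty((n_steps + 1, r0.shape[0]))
    rates[0] = r0
    if method == "euler":
        state = IntegratorState(r0, 0.0)
        for i in range(n_steps):
            state = step(state, u[i], config)
            rates[i + 1] = state.r
    else:
        r = r0.copy()
        for i in range(n_steps):
            r = _exact_step(r, u[i], config)
            rates[i + 1] = r
    times = config.dt * np.arange(n_steps + 1)
    return Trajectory(times, rates)


def regime(config: IntegratorConfig, tol: float = 1e-12) -> str:
    """Classify the recurrent gain: leaky (alpha<1) / balanced / unstable."""
    if abs(config.alpha - 1.0) <= tol:
        return "balanced"
    return "leaky" if config.alpha < 1.0 else "unstable"
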