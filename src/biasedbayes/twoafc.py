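"""Biased diffusion model of two-alternative forced choice.

The decision variable is the log posterior-probability ratio
``L = log P(H1 | data) / P(H2 | data)``.  It starts at the log
expected-value ratio ``S0 = log(P(H1) Rwd1) - log(P(H2) Rwd2)`` — priors and
payoffs shift the starting point, not the drift — and evolves by the biased
update

    L'  =  alpha**dt * L  +  beta**dt * (llr_t + noise_t)

until it crosses a symmetric bound ±theta.  alpha = 1 is the perfect
integrator of the drift-diffusion model; alpha < 1 leaks old evidence
(recency), alpha > 1 amplifies it (primacy).  Psychophysical reverse
correlation (:func:`reverse_correlation`) recovers exactly this temporal
weighting from choices and stimulus fluctuations: a flat kernel means perfect
integration, a rising kernel a leak, a falling kernel instability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "TrialConfig",
    "TrialResult",
    "Kernel",
    "starting_point",
    "step_update",
    "simulate_trial",
    "simulate_block",
    "reverse_correlation",
    "psychometric_summary",
]


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of one 2AFC diffusion trial.

    Time is in abstract units; ``dt`` defaults to 0.001 (millisecond-like
    steps of a one-second-like unit).  ``llr_mean`` and ``llr_sd`` are the
    per-unit-time drift and fluctuation scale of the stimulus
    log-likelihood-ratio stream; ``noise_sd`` is internal integration noise.
    With ``noise_in_input`` (default) the noise enters the likelihood channel
    and is scaled by ``beta**dt`` together with the signal; otherwise it is
    added outside the gain.
    """

    prior_probs: tuple[float, float] = (0.5, 0.5)
    rewards: tuple[float, float] = (1.0, 1.0)
    bound: float = 1.0
    dt: float = 0.001
    alpha: float = 1.0
    beta: float = 1.0
    noise_sd: float = 0.0
    llr_mean: float = 0.0
    llr_sd: float = 1.0
    max_time: float = 5.0
    t0: float = 0.0
    seed: int | None = None
    noise_in_input: bool = True

    def __post_init__(self) -> None:
        p1, p2 = self.prior_probs
        if not (0 < p1 < 1 and 0 < p2 < 1 and abs(p1 + p2 - 1) < 1e-9):
            raise ValueError("prior_probs must lie in (0,1) and sum to 1")
        if min(self.rewards) <= 0:
            raise ValueError("rewards must be strictly positive")
        if self.bound <= 0 or self.dt <= 0 or self.max_time <= 0:
            raise ValueError("bound, dt, max_time must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.noise_sd < 0 or self.llr_sd < 0 or self.t0 < 0:
            raise ValueError("noise_sd, llr_sd, t0 must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.max_time / self.dt))


@dataclass
class TrialResult:
    choice: str  # "H1" | "H2"
    rt: float  # decision time + t0
    trajectory: np.ndarray  # L at steps 0..k (index 0 is the starting point)
    fluctuations: np.ndarray  # realized stimulus llr draws up to the decision
    censored: bool
    true_hypothesis: str
    dt: float

    @property
    def decision_steps(self) -> int:
        return len(self.fluctuations)

    @property
    def correct(self) -> bool:
        return self.choice == self.true_hypothesis


@dataclass
class Kernel:
    """Reverse-correlation kernel with bootstrap confidence band.

    ``mean`` is the per-bin mean stimulus fluctuation (per unit time) among
    H1 choices minus among H2 choices; ``slope`` the weighted least-squares
    line through it — the scalar flatness diagnostic.
    """

    bin_centers: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: np.ndarray
    slope: float
    slope_lo: float
    slope_hi: float
    ci_level: float
    align: str


def starting_point(prior_probs, rewards) -> float:
    """Log expected-value ratio: log(P(H1) Rwd1) - log(P(H2) Rwd2)."""
    p1, p2 = prior_probs
    r1, r2 = rewards
    if r1 <= 0 or r2 <= 0:
        raise ValueError("rewards must be strictly positive")
    if not (p1 > 0 and p2 > 0):
        raise ValueError("prior probabilities must be positive")
    return math.log(p1 * r1) - math.log(p2 * r2)


def step_update(L: float, llr_t: float, config: TrialConfig, noise_draw: float = 0.0) -> float:
    """One biased update of the log posterior ratio.

    The previous posterior ratio becomes the prior ratio weighted by
    ``alpha**dt``; the incoming log-likelihood ratio enters weighted by
    ``beta**dt``.
    """
    if not (math.isfinite(L) and math.isfinite(llr_t) and math.isfinite(noise_draw)):
        raise ValueError("non-finite input to step_update")
    a = config.alpha ** config.dt
    b = config.beta ** config.dt
    if config.noise_in_input:
        return a * L + b * (llr_t + noise_draw)
    return a * L + b * llr_t + noise_draw


def _accumulate(config: TrialConfig, s0: float, drive: np.ndarray) -> np.ndarray:
    """L_k = a L_{k-1} + drive_k as an IIR filter, plus the decaying s0 term."""
    a = config.alpha ** config.dt
    L = lfilter([1.0], [1.0, -a], drive)
    if s0 != 0.0:
        L = L + s0 * a ** np.arange(1, len(drive) + 1)
    return L


def simulate_trial(
    config: TrialConfig, true_hypothesis: str = "H1", rng: np.random.Generator | None = None
) -> TrialResult:
    """Run one trial to bound crossing or the deadline.

    Stimulus llr draws are N(±llr_mean·dt, llr_sd²·dt) with the sign set by
    the true hypothesis; integration noise is N(0, noise_sd²·dt).  The first
    step k with |L_k| ≥ bound decides by the sign of L_k; at the deadline the
    choice is forced by the sign of the final L (ties to H1) and the trial is
    flagged censored.
    """
    if true_hypothesis not in ("H1", "H2"):
        raise ValueError("true_hypothesis must be 'H1' or 'H2'")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_steps
    sign = 1.0 if true_hypothesis == "H1" else -1.0
    sd = config.llr_sd * math.sqrt(config.dt)
    stim = rng.normal(sign * config.llr_mean * config.dt, sd, n)
    noise = rng.normal(0.0, config.noise_sd * math.sqrt(config.dt), n)
    b = config.beta ** config.dt
    drive = b * (stim + noise) if config.noise_in_input else b * stim + noise
    s0 = starting_point(config.prior_probs, config.rewards)
    L = _accumulate(config, s0, drive)

    crossed = np.abs(L) >= config.bound
    if crossed.any():
        k = int(np.argmax(crossed))
        choice = "H1" if L[k] > 0 else "H2"
        rt = (k + 1) * config.dt + config.t0
        censored = False
    else:
        k = n - 1
        choice = "H1" if L[k] >= 0 else "H2"
        rt = config.max_time + config.t0
        censored = True
    return TrialResult(
        choice=choice,
        rt=rt,
        trajectory=np.concatenate(([s0], L[: k + 1])),
        fluctuations=stim[: k + 1],
        censored=censored,
        true_hypothesis=true_hypothesis,
        dt=config.dt,
    )


def simulate_block(
    config: TrialConfig,
    n_trials: int,
    hypothesis_schedule=None,
) -> tuple[list[TrialResult], pd.DataFrame]:
    """Seeded block of trials with a per-condition summary.

    All trials draw from one generator seeded with ``config.seed``, so a block
    is bitwise reproducible and a block of one trial equals a single
    :func:`simulate_trial` call with the same seed.  The default schedule
    alternates H1/H2.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if hypothesis_schedule is None:
        hypothesis_schedule = ["H1" if i % 2 == 0 else "H2" for i in range(n_trials)]
    if len(hypothesis_schedule) != n_trials:
        raise ValueError("hypothesis schedule length must equal n_trials")
    rng = np.random.default_rng(config.seed)
    results = [simulate_trial(config, h, rng) for h in hypothesis_schedule]
    rows = []
    for hyp in sorted(set(hypothesis_schedule)):
        sub = [r for r in results if r.true_hypothesis == hyp]
        rows.append(
            {
                "true_hypothesis": hyp,
                "n": len(sub),
                "accuracy": float(np.mean([r.correct for r in sub])),
                "mean_rt": float(np.mean([r.rt for r in sub])),
                "censored_frac": float(np.mean([r.censored for r in sub])),
            }
        )
    return results, pd.DataFrame(rows)


def _binned_fluctuations(
    results: list[TrialResult], n_bins: int, t_max: float, align: str
) -> np.ndarray:
    """(n_trials, n_bins) per-trial mean fluctuation per unit time; NaN where
    a trial has no steps in a bin (already decided / trial too short)."""
    F = np.full((len(results), n_bins), np.nan)
    edges = np.linspace(0.0, t_max, n_bins + 1)
    for i, r in enumerate(results):
        k = r.decision_steps
        t = (np.arange(k) + 0.5) * r.dt
        if align == "choice":
            t = k * r.dt - t  # time before the decision
        idx = np.searchsorted(edges, t, side="right") - 1
        ok = (idx >= 0) & (idx < n_bins)
        if not ok.any():
            continue
        x = r.fluctuations / r.dt  # per unit time
        sums = np.bincount(idx[ok], weights=x[ok], minlength=n_bins)
        cnts = np.bincount(idx[ok], minlength=n_bins)
        nz = cnts > 0
        F[i, nz] = sums[nz] / cnts[nz]
    return F


def _kernel_and_slope(F: np.ndarray, is_h1: np.ndarray, centers: np.ndarray):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-bin nanmean
        m1 = np.nanmean(F[is_h1], axis=0)
        m2 = np.nanmean(F[~is_h1], axis=0)
        n1 = np.sum(~np.isnan(F[is_h1]), axis=0)
        n2 = np.sum(~np.isnan(F[~is_h1]), axis=0)
    kernel = m1 - m2
    n = np.minimum(n1, n2)
    ok = (n > 0) & np.isfinite(kernel)
    if ok.sum() < 2:
        return kernel, n, float("nan")
    wls = sm.WLS(kernel[ok], sm.add_constant(centers[ok]), weights=n[ok]).fit()
    return kernel, n, float(wls.params[1])


def reverse_correlation(
    results: list[TrialResult],
    n_bins: int = 10,
    align: str = "stimulus_onset",
    t_max: float | None = None,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> Kernel:
    """Choice-triggered average of stimulus fluctuations.

    For each time bin, the mean realized stimulus fluctuation (per unit time,
    over steps preceding each trial's decision) among H1 choices minus among
    H2 choices.  ``align='stimulus_onset'`` measures time from trial start,
    ``align='choice'`` backwards from the decision.  ``t_max`` defaults to the
    median decision time.  The confidence band and the slope interval come
    from a seeded percentile bootstrap over trials.
    """
    if align not in ("stimulus_onset", "choice"):
        raise ValueError(f"unknown align {align!r}")
    if len(results) < 100:
        warnings.warn(
            f"reverse correlation on only {len(results)} trials; >= 100 recommended",
            stacklevel=2,
        )
    choices = np.array([r.choice for r in results])
    is_h1 = choices == "H1"
    if is_h1.all() or not is_h1.any():
        raise ValueError("kernel undefined: all trials share one choice")
    if t_max is None:
        t_max = float(np.median([r.decision_steps * r.dt for r in results]))
    edges = np.linspace(0.0, t_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = _binned_fluctuations(results, n_bins, t_max, align)

    kernel, n, slope = _kernel_and_slope(F, is_h1, centers)

    rng = np.random.default_rng(seed)
    boot_k = np.empty((n_boot, n_bins))
    boot_s = np.empty(n_boot)
    n_trials = len(results)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n_trials, n_trials)
            bh = is_h1[idx]
            if bh.any() and not bh.all():
                break
        boot_k[b], _, boot_s[b] = _kernel_and_slope(F[idx], bh, centers)
    q = np.array([(1 - ci) / 2, (1 + ci) / 2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = np.nanquantile(boot_k, q, axis=0)
    s_lo, s_hi = np.nanquantile(boot_s, q)
    return Kernel(
        bin_centers=centers,
        mean=kernel,
        lo=lo,
        hi=hi,
        n=n,
        slope=slope,
        slope_lo=float(s_lo),
        slope_hi=float(s_hi),
        ci_level=ci,
        align=align,
    )


def psychometric_summary(results_by_level: dict[float, list[TrialResult]]) -> pd.DataFrame:
    """Accuracy and mean RT per stimulus-strength (llr_mean) level."""
    if len(results_by_level) < 2:
        raise ValueError("need at least 2 stimulus levels")
    rows = []
    for level in sorted(results_by_level):
        res = results_by_level[level]
        rows.append(
            {
                "llr_mean": level,
                "n": len(res),
                "accuracy": float(np.mean([r.correct for r in res])),
                "mean_rt": float(np.mean([r.rt for r in res])),
            }
        )
    return pd.DataFrame(rows)
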