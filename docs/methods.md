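# Methods

This note documents the models implemented in `biasedbayes`, the parameter
choices that matter, the synthetic designs the tests run on, and the places
where the design was genuinely open and a choice had to be made.

## The biased update

The core operation is `P(H|D) ∝ P(D|H)^β P(H)^α` with `α, β ≥ 0`. All
discrete-distribution arithmetic is done in log space; the proportionality
constant is realized as a log-sum-exp normalizer, so extreme exponents
(e.g. `β = 1000`) are handled without overflow. Exponents of exactly zero
drop their term entirely (a convention that makes `α = 0` produce a uniform
prior even at zero-mass support points, rather than NaN from `0 · (−∞)`).
`α = β = 0` on a finite grid is the uniform posterior and is valid; for
Gaussians the same limit is an improper flat density and raises an error.

Continuous distributions are represented two ways: a Gaussian conjugate
closed form (posterior precision `α/σ_p² + β/σ_l²`, precision-weighted mean),
and discretization onto a bounded grid (default `mean ± 6 sd`, 2001 points).
The two routes are tested against each other over the lattice
`{0, 0.5, 1, 2}²` minus the all-zero corner; for that sweep the tests use a
wider grid (`[−12, 15]`, 4001 points) because flattening exponents double the
posterior standard deviation and `±6 sd` of the *prior* would truncate
meaningful tail mass.

Ties in the mode are broken toward the smallest (first) support value,
deterministically. The median is the smallest support value whose CDF
reaches 0.5.

Negative exponents are not supported anywhere: the framework assumes
positive bias levels, with zero as the flattening limit.

### Sequential updating

`sequential_update` feeds each posterior back as the next prior and applies
`α` once per step, so after `n` steps the initial prior carries total
exponent `αⁿ`. With `α < 1` the initial belief washes out geometrically
(forgetting); with `α > 1` it hardens (stereotyping). This "one α per
update" convention is the discrete-step reading of the `α^Δt` factor used by
the diffusion model below with `Δt = 1`.

## The bias plane

`classify_region` is total. Per-axis regimes: forgetting (`α < 1`) /
stereotyping (`α > 1`), rigidity (`β < 1`) / flexibility (`β > 1`). Overall:
`standard` exactly at (1, 1), `ml_like` for `α < β`, `robust` for `α > β`,
and `flat_degenerate` when both exponents fall below a configurable
`ε = 1e-6` (the region where the posterior is essentially flat has no
canonical cutoff; ε is exposed as an argument). The diagonal `α = β ≠ 1` is
neither likelihood- nor prior-dominated and gets its own label, `balanced`.

The estimator paths are `(α = k₁, β = 1)` and `(α = 1, β = 1/k₂)`. `k₂ = 0`
(and symmetrically `k₁ → ∞`) are represented by an infinity *sentinel*, not a
float overflow: only mode-returning estimation accepts it, returning the
argmax of the likelihood (ML) or of the prior (maximum prior, MP). When a
distribution is requested at a sentinel the result is the corresponding
one-hot point mass on the grid — the closest representable object.

Classic probability-judgment biases are exposed as a documentation table
(`PSYCHOLOGICAL_BIAS_REGIONS`): base-rate fallacy and representativeness are
inference at `α < β`; conservatism and anchoring-and-adjustment at `α > β`.
They are aliases for regions, not separate algorithms.

Neuromodulator effects are additive offsets `(α+λ₁, β+λ₂)`, clipped at zero
with a warning (below zero the exponents are meaningless). Presets enforce
quadrants: norepinephrine and excitatory excess `λ₁, λ₂ ≥ 0` (offset angle
0–90°), acetylcholine `λ₁ ≤ 0, λ₂ ≥ 0` (90–180°), inhibitory excess
`λ₁, λ₂ ≤ 0` (180–270°). These are parameter settings only; the package
attaches no diagnostic meaning to them.

## Population codes

The code is `log P(x) = Σᵢ rᵢ hᵢ(x) + const`. Basis functions are Gaussian
bumps with evenly spaced centers and one shared width — the shape of
sensory tuning curves under attentional gain modulation — plus an implicit
constant direction. Encoding is ordinary least squares of the (floored)
log-density on `[H, 1]` with the constant coefficient discarded: the
constant belongs to the normalizer and is resolved at decoding by
renormalization. The log floor (−745, near the smallest double whose exp is
nonzero) keeps zero-mass grid points finite for the projection. The RMS
fit residual is carried on the rate object; above a configurable tolerance
encoding warns but does not fail.

Because the code is linear in log probability, the biased update is exactly
`r_post = α r_prior + β r_like`, and multiplicative gain `g` on a population
decodes to the `g`-th exponential bias of the decoded distribution — gain
modulation *is* sharpening/flattening. For log-densities inside the basis
span these identities are exact to float precision (tested at 1e-10 total
variation over a 9-point bias lattice); off-span distributions incur the
encoding residual.

Rates may be negative (log probabilities are negative numbers). A
non-negative "biological" display is an additive offset and does not change
the mathematics, so the package does not model it.

`simulate_bias_origin` builds the two-layer circuit both ways: *rate bias*
(layer-1 populations already fire α-/β-scaled, unit-gain combination) and
*connection bias* (unbiased layer 1, biased gains at the combination). The
decoded posteriors are identical by linearity; the layer-1 rate records
differ by exactly the gain factor — the observable that distinguishes a
representation bias from an inference bias.

## The neural integrator

`τ dr/dt = −r + αr + βu(t)`, integrated by explicit Euler with a guard
`dt ≤ τ/10` (removable), plus an exact per-step exponential integrator for
the linear system. Regimes: leaky (`α < 1`, steady state `βc/(1−α)` for
constant input `c`, relaxation time constant `τ/(1−α)`), balanced (`α = 1`,
zero-input Euler increment is exactly zero, so rates are conserved bitwise),
unstable (`α > 1`, growth `exp((α−1)t/τ)`). When the state encodes a PPC
log-density, leak flattens the encoded distribution (entropy rises toward
uniform — forgetting) and instability sharpens it (stereotyping); the tests
assert this as entropy monotonicity. The discrete per-step retention of the
Euler scheme is `1 + (α−1)dt/τ`, which agrees with the `α^(dt/τ)` convention
of the decision model to `O(dt²)`.

Multiple concurrent input sources enter additively (the equation is linear),
each with its own feedforward gain.

## The 2AFC diffusion model

The decision variable is `L = log[P(H₁|data)/P(H₂|data)]`, starting at
`S₀ = log[P(H₁)Rwd₁] − log[P(H₂)Rwd₂]` (priors and payoffs move the starting
point, not the drift) and updated per step as
`L ← α^dt L + β^dt (llr_t + noise_t)`. Stimulus evidence is drawn per bin as
`N(±llr_mean·dt, llr_sd²·dt)` with the sign set by the true hypothesis;
internal noise is `N(0, σ²dt)`. By default noise enters the likelihood
channel (inside the `β^dt` factor, the whole input arrow scaled); a
config flag moves it outside the gain. Time units are abstract; `dt`
defaults to 0.001 (millisecond-like steps), though the simulation designs
below use `dt = 0.01` for economy — the update depends on `α^dt`, so the
dynamics are invariant to re-binning up to discretization error.

A trial ends at the first `|L| ≥ bound` (choice by sign) or at `max_time`,
where the choice is forced by the sign of the final `L` (ties to H₁,
deterministic) and the trial is flagged censored. With `α = 1` the recursion
is an exact sum, verified against re-summation of the recorded inputs; with
`α ≠ 1` it is a discrete Ornstein–Uhlenbeck process whose mean
`a^n S₀ + m(1−a^n)/(1−a)` and variance `v(1−a^{2n})/(1−a²)`
(`a = α^dt`) the tests check at n = 5000 trials within three standard
errors.

### Reverse correlation

The kernel is the per-time-bin mean realized stimulus fluctuation (per unit
time, over steps preceding each trial's decision) among H₁ choices minus
among H₂ choices, with a seeded percentile bootstrap (default 1000
resamples) for the confidence band. The flatness statistic is the slope of
a weighted least-squares line through the kernel (weights: per-bin trial
counts); its bootstrap interval is the significance test. Alignment is
stimulus onset by default, with a choice-aligned variant; the analysis
window defaults to the median decision time.

The canonical diagnostic design is the *interrogation* protocol: a zero-mean
stimulus stream (`llr_mean = 0, llr_sd = 1`) of fixed duration (2 time
units, `dt = 0.01`), no internal noise, and a bound far beyond reach, so the
choice is the sign of `L` at the deadline. Under this design a perfect
integrator's kernel is exactly flat by exchangeability, a leaky integrator
(`α = 0.8`) weights late evidence (positive slope) and an unstable one
(`α = 1.2`) weights early evidence (negative slope); the tests check these
at n = 5000 trials. In a bound-crossing paradigm the stimulus-aligned
kernel of even a perfect integrator is tilted by the decision-locked
crossing sample, whose hazard rises over the trial — a known property of
bounded accumulation, which is why the fixed-duration design is the clean
read-out of the integration weights. Bound-crossing blocks remain fully
supported by `reverse_correlation`; their kernels simply mix selection
effects with the integration profile.

What the synthetic design does not emulate: real stimuli have bounded,
non-Gaussian fluctuation distributions, observers have non-stationary
criteria and lapses, and empirical kernels mix sensory and decisional
weighting. Passing these tests shows the estimator recovers the model's own
temporal weights, not that any organism integrates this way.

## The Stroop model

Two perception channels emit two-level log-likelihood templates over the
response palette (default {red, green}): `contrast` at the channel's own
feature label, zero elsewhere, scaled by pathway strengths
`w_word = 1.0 > w_color = 0.6` (reading is over-trained). The response layer
is a balanced integrator (`τ = 1`, `dt = 0.1`) over
`β_word r_word + β_color r_color` plus per-step Gaussian input noise
(sd 0.05), starting from zero rates — a flat prior in the log code. The
response is the label whose softmax mass first exceeds 0.75 (a posterior
threshold, keeping the Bayesian reading of the layer).

Conflict is the pairwise product of the softmax response activations
(`(1 − Σp²)/2`), maximal at uniform activation (`(K−1)/2K` for K labels),
zero at one-hot — an energy-style monitor of response co-activation.

Two asymmetries shape behavior. First, a static *task set* multiplies the
task-irrelevant channel's gain by `task_set_attenuation = 0.5` before any
conflict control: in a pure two-pathway race the drive difference
`|w_word − w_color|` is the same in both tasks, so without a task baseline
the model cannot produce the larger interference in color naming that
defines the Stroop effect; the attenuation is the analogue of task-demand
input in conflict-monitoring network models. How the bias levels are set is
an open question in the framework, so this is an explicit design choice.
Second, the conflict-driven controller updates gains *between* trials:
task-relevant gain `+= η · mean-conflict`, clipped to `[0, beta_max = 2]`
(enhancement-only by default; a biased-competition variant also decrements
the irrelevant gain). With `η = 0.4` on a run of incongruent color-naming
trials the color gain climbs to ceiling within ~20 trials and the
interference in the second half of the run falls well below the first half.

At the default noise level the model's Stroop effect is carried almost
entirely by reaction times; error rates are near zero because the
drift-to-noise ratio at threshold is high. Raising `noise_sd` produces
errors at the cost of noisier RT summaries.

## Seeds and reproducibility

Every stochastic component takes an explicit seed or `numpy` Generator.
Blocks draw all trials from a single seeded stream, so a block is bitwise
reproducible and a one-trial block equals a single seeded trial. The CLI
and the acceptance script fan a single global seed out to per-component
child seeds via `SeedSequence(global_seed, crc32(component))`, so
sub-simulations are independently reproducible; derived seeds stay below
2³¹.

## Problem sizes

The test suite and the acceptance script use: 1000 random discrete problems
for the Bayes-oracle check; a 4001-point grid for the Gaussian lattice; 100
random in-span pairs for population-code commutation; 5000 trials per
recurrent-gain condition for reverse correlation (interrogation design, 200
steps per trial); 2000 trials (500 per task × congruency cell) for the
Stroop block and a 100-trial incongruent run for the control effect. These
sizes put Monte-Carlo standard errors comfortably inside the asserted
margins while keeping a full run in the tens of seconds.

## Known limitations

- No fitting of `(α, β)` to behavioral data; the framework's identifiability
  concerns are real and estimation-from-data is out of scope.
- Population codes are rate-based and deterministic: no Poisson spiking
  variability, no plasticity.
- The diffusion model is two-alternative only, with fixed symmetric bounds
  (no collapsing bounds, no multi-alternative race).
- The Stroop model abstracts the monitor/controller loop; it does not model
  anatomy, error monitoring or post-error slowing.
- Negative bias exponents are rejected throughout.
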