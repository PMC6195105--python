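# biasedbayes

Exponentially biased Bayesian inference for computational neuroscience and
cognitive modelling.

Human and animal probability judgments deviate from Bayes' rule in systematic
ways — base-rate neglect, conservatism, anchoring, primacy/recency effects.
A large family of these deviations can be written as a single generalized
update with two exponents,

```
P(H | D)  ∝  P(D | H)^β  P(H)^α
log P(H | D) = β log P(D | H) + α log P(H) + const.
```

where `α` weights the prior and `β` the likelihood. `α = β = 1` is standard
Bayes. `α < 1` flattens the prior (*forgetting*), `α > 1` sharpens it
(*stereotyping*); `β < 1` under-weights evidence (*rigidity*), `β > 1`
over-weights it (*flexibility*). Points of the (α, β) plane are estimation
methods: `(0, 1)` is maximum likelihood, `(1, 1)` is MAP/Bayes, `β → ∞`
collapses to the likelihood mode, `α → ∞` to the prior mode, and the
half-planes `α < β` / `α > β` are likelihood-dominated ("ML-like") and
prior-dominated ("robust") inference.

The package is aimed at modellers who want this update rule **and** its
neural realizations in one tested toolbox:

- **`biasedbayes.inference`** — the biased update on discrete grids (log-space
  throughout) and the Gaussian conjugate closed form; sequential updating,
  reward-weighted expected value (`log EV = log P + log Rwd`), point estimates.
- **`biasedbayes.plane`** — bias-plane region classification, the `k₁`/`k₂`
  estimator paths between ML, MAP and maximum-prior estimation, and additive
  neuromodulator offsets `(α+λ₁, β+λ₂)` with presets for norepinephrine,
  acetylcholine and E/I balance.
- **`biasedbayes.ppc`** — probabilistic population codes
  (`log P(x) = Σᵢ rᵢ hᵢ(x) + const`): encoding, decoding, and biased inference
  as gain-modulated rate summation `r_post = α r_prior + β r_like`, including
  the rate-bias vs connection-bias distinction.
- **`biasedbayes.integrator`** — the firing-rate equation
  `τ dr/dt = −r + αr + β r_like(t)` with leaky / balanced / unstable regimes.
- **`biasedbayes.twoafc`** — a biased diffusion model of two-alternative
  forced choice on the log posterior ratio, with reward-dependent starting
  point `log[P(H₁)Rwd₁ / P(H₂)Rwd₂]`, per-step update `α^Δt L + β^Δt llr`,
  and psychophysical reverse correlation with bootstrap kernel diagnostics.
- **`biasedbayes.stroop`** — a Stroop conflict-monitoring network where
  top-down control sets the gains (β_word, β_color).
- **`biasedbayes.scenarios`** / **CLI** — named fixtures and a `biasedbayes`
  command with `update`, `plane`, `ppc-demo`, `integrate`, `2afc-sim`,
  `revcorr`, `stroop-sim` and `scenario` subcommands.

## Worked example: the rare-disease test

A disease has base rate 1/10,000; a test is 99% accurate for both ill and
healthy people; your result is positive. The unbiased posterior:

```sh
$ biasedbayes update --scenario disease_test --alpha 1 --beta 1
ill     0.00980392
healthy 0.990196
```

Despite the positive test you are almost certainly healthy — the posterior
probability of illness is ≈ 0.0098, because the tiny base rate dominates.
People who answer "about 99%" are doing the `α = 0` inference, which the same
command reproduces by flattening the prior:

```sh
$ biasedbayes update --scenario disease_test --alpha 0 --beta 1
ill     0.99
healthy 0.01
```

That is base-rate neglect as a point on the bias plane:

```sh
$ biasedbayes plane classify --alpha 0.5 --beta 1.5
labels  forgetting, flexibility, ml_like
overall ml_like
```

The same arithmetic in Python, with the Gaussian closed form
(prior N(0, 1), likelihood N(3, 1), prior counted twice via `α = 2`):

```python
>>> from biasedbayes import GaussianDist, BiasParams, gaussian_biased_update
>>> gaussian_biased_update(GaussianDist(0, 1), GaussianDist(3, 1), BiasParams(2, 1))
GaussianDist(mean=1.0, variance=0.3333333333333333)
```

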