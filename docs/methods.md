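# Methods

## The measurement problem

A person choosing repeatedly between two options described by K attributes
(scaled to [0, 1]) can be modelled as computing a value for each option and
choosing noisily in favour of the higher one. `heurfit` measures two elements
of that process from choices alone — the signed attribute weights and the
choice *method* (which simplifying heuristics, if any, were used) — and
quantifies how well a self-report of the process agrees with the fitted one.

## Choice models

The core is the weighted additive rule: option value `v = w · x` with weights
`w ∈ [−1, 1]^K`, and

```
P(choose A) = logistic(beta · (w · x̃_A − w · x̃_B))
```

a softmax over the two option values written as a logistic in the value
difference (algebraically identical, numerically stabler). `beta ≥ 0` is the
inverse temperature: 0 is coin flipping, large values approach deterministic
choice of the higher-valued option.

Three heuristics restrict this core:

* **single attribute** (take-the-best / lexicographic): exactly one weight is
  ±1, the rest 0;
* **binary weights** (equal weights, with exclusion allowed): every weight in
  {−1, 0, 1};
* **binary attribute values** (weighted pros): `x̃` replaces each attribute
  pair by an indicator of which option is greater (1/0; exact ties map to
  0.5/0.5 so a tied attribute cancels from the value difference — ties cannot
  occur under the default task generator anyway).

Single-attribute and binary-weights cannot be combined (the former is a
special case of the latter), leaving six models: (1) none of the heuristics
("classically rational"), (2) binary values only, (3) binary weights only,
(4) binary weights + binary values, (5) single attribute, (6) single
attribute + binary values. Models 1–2 have continuous weights; models 3–6
have finitely many admissible weight vectors (3^K for 3–4, including the
all-zero vector, which yields chance responding; 2K for 5–6).

Assumptions worth stating: weights and method are constant across trials,
attributes combine linearly (no interactions), and choices are conditionally
independent given the parameters. Sequential-sampling mechanisms (response
times, accumulation dynamics) are outside the measured level.

## Priors and inference

Weights have uniform priors over each model's admissible set; beta has a
Gamma(shape 4, rate 1) prior (mean 4, i.e. clearly-but-not-perfectly
deterministic choice on the unit value scale). Per participant and model we
compute the MAP parameters and the marginal likelihood
`Z_m = ∫ p(choices | w, beta) dPrior`; normalizing the six `Z_m` under a
uniform model prior gives posterior model probabilities — the Bayesian
Occam's razor that penalizes the flexible continuous models automatically.
Heuristic-family probabilities sum the relevant models
(P(single) = p5+p6, P(binary weights) = p3+p4, P(binary values) = p2+p4+p6).

**Discrete models (3–6)** are computed exactly:

* beta integral: generalized Gauss–Laguerre quadrature with exponent
  shape−1, which matches the Gamma weight function and converges spectrally
  (doubling from the default 64 nodes moves a log marginal by ~1e-9). A
  quantile-transformed Gauss–Legendre rule was tried first and rejected: the
  transform's tail singularity capped accuracy near 1e-5.
* weight sum: full enumeration; the marginal is the config-averaged beta
  integral. The MAP is an exhaustive scan over configurations on the
  quadrature grid, with a bounded 1-D refinement of beta for the top 10
  configurations; exact ties go to the lowest configuration index.
* cost: for binary-values models the per-trial value differences are
  integers in [−K, K], so the 3^K × 64 likelihood grid collapses to a
  histogram and is cheap. For model 3 the full grid is evaluated; grids
  beyond 10^6 entries use float32 (≤ ~1e-5 absolute error in a log marginal,
  negligible against typical between-model gaps of ≫ 1).

**Continuous models (1–2)**: MAP by L-BFGS-B with analytic gradients on
[−1, 1]^K × [1e-6, 50], 10 restarts (one informed start from the mean signed
attribute differences, the rest drawn from the prior), tolerance 1e-8. The
marginal likelihood uses importance sampling with a Laplace proposal at the
MAP: covariance = inflated (×1.5) inverse Hessian of the negative log
posterior, mixed with 5% prior draws as a defensive heavy tail, 4000 draws by
default, Monte-Carlo standard error reported (typically ≲ 0.05 nats). When
the Hessian has non-positive curvature directions — the likelihood depends on
beta·w only, so a ridge appears whenever the Gamma prior does not pin the
scale, and MAP weights often sit on the box boundary — the eigenvalues are
floored at 0.25 so the proposal still spans the box; pure prior sampling
remains as a fallback only if the Hessian itself is not finite. An MCMC +
bridge-sampling route would estimate the same integral; importance sampling
was preferred because it is deterministic given a seed, has no sampler
dependency, and is validated against brute-force prior Monte-Carlo oracles in
the test suite (agreement within 3 combined standard errors).

The scale degeneracy means continuous MAP weights are reported as-is, not
renormalized; the Pearson weight-correlation metric is scale-free and is the
primary weight-accuracy measure, while the absolute-error metric inherits the
scale sensitivity and should be read with that caveat.

## Model-averaged weights

Each model yields different best-fit weights, so weights and method are
interdependent. To de-couple them, fitted weights are model-averaged: the
posterior-probability-weighted mean of the six MAP weight vectors. The same
averaging applies to reports: participants report weights in three formats
(graded magnitudes with signs, a signed binary checklist, a single signed
attribute), and the model-averaged reported weights are
`(p1+p2)·graded + (p3+p4)·binary + (p5+p6)·single`.

## Accuracy metrics and chance levels

Per participant: Pearson correlation between the K model-averaged fitted and
reported weights (undefined for constant vectors — flagged, excluded from
cohort means, and counted); mean absolute weight difference; heuristic error
(mean |reported extent − family probability| over the three heuristics); the
reported model obtained by thresholding each extent at 0.5 (exactly 0.5 maps
to "not used"; a reported single-attribute + binary-weights conflict resolves
to single-attribute, the subsuming special case, and is logged); the reported
model's Bayes factor `p_reported / p_argmax ∈ [0, 1]`; and the binary
correct-method flag. Chance levels come from a permutation bootstrap that
re-pairs reports with other participants' fits (mean over 1000 re-pairings);
for correct-method the analytic chance under uniform guessing, exactly 1/6,
is reported alongside.

## Synthetic world

The generator emulates the task structure, not its surface: K = 9 attributes,
100 choice trials, values uniform on [0, 1] resampled until the two options
differ by ≥ 0.25 on every attribute ("substantially different" options; the
exact empirical rule is not public, and 0.25 on a unit scale keeps every
trial informative while precluding binary-value ties — fixed once,
configurable). Deciders are balanced across the six models, with continuous
weights uniform on [−1, 1], discrete weights uniform over the admissible
configurations, and beta ~ Gamma(4, 1) — the fitting prior, so simulations
are well-specified. Self-reports at noise 0 restate the truth (graded = w;
binary = sign of weights with |w| > 0.5; single = signed argmax; extents =
the model's heuristic flags). Report noise, when enabled, adds truncated
N(0, noise) to magnitudes and extents and flips graded signs with probability
min(0.5, noise/2), with binary/single re-derived from the noisy graded vector.

What a green recovery test does *not* establish: robustness to model
misspecification (real deciders may drift, lapse, or weight nonlinearly),
realistic self-report biases (noise here is unbiased and symmetric), or
anything about the empirical accuracy of real participants.

## Recovery scoring

A decider is heuristic-correct when, for each of the three heuristics, the
family probability exceeds 0.5 exactly when the generating model uses it; the
headline rate is the fraction fully correct, with per-heuristic rates, the
generating-vs-argmax confusion matrix, and the mean truth-vs-fitted weight
correlation reported alongside. At the default scale (60 deciders, seeds 1,
2, 3, 7, 42) the rate lands between 0.80 and 0.92 — deciders that are hard by
construction (near-zero effective beta·w, binary-weight vectors with almost
no active attributes) account for the misses, which concentrate in the
model 1 ↔ 3 confusion cells. At beta = 0 (a negative control) recovery
collapses toward chance, and recovery improves with trial count.

## Known limitations

* The continuous-model evidence is stochastic (reported with its standard
  error); borderline family probabilities near 0.5 can flip under a different
  seed.
* Absolute weight error for continuous deciders depends on the arbitrary
  posterior scale split between w and beta (see above).
* The permutation re-pairing is one defensible reading of "chance" — it holds
  the cohort's fit and report distributions fixed and breaks only their
  pairing.
* Enumeration limits binary-weights models to K ≤ 13 (3^K growth); the
  intended regime is K ≈ 9.
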