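# Methods

This note documents the models, the synthetic stimulus generators, the
numerical choices and the known limitations of `seqmem`.

## Models

### Single-layer temporal predictive coding (tPC)

A sequence of `P + 1` patterns `x^1 .. x^{P+1}` (dimension `N`) is
memorized by a single weight matrix `W` that minimizes the squared
temporal prediction error at each step,

    F_mu(W) = || x^mu - W f(x^{mu-1}) ||^2 ,

with `f` either the identity (default) or `tanh`.  Error neurons carry
`eps^mu = x^mu - W f(x^{mu-1})`; learning is the Hebbian gradient step
`dW = lr * eps^mu f(x^{mu-1})^T`, applied at every transition, for multiple
epochs until `W` stops changing.  Recall fixes `W` and runs leaky Euler
dynamics on the value neurons, `x_hat <- x_hat - lr_inf * (x_hat - W f(q))`,
whose fixed point is `W f(q)`.

Two recall protocols: **online** (each step queried with the ground-truth
previous pattern — real-time feedback) and **offline** (only `x^1` is cued;
each step is queried with the model's own previous retrieval, so errors can
accumulate).

*Linear theory.* With `f = identity` and zero weight initialization,
gradient descent converges to the minimum-norm least-squares transition map
`W = A C^+`, with `A = sum x^{mu+1} (x^mu)^T` and `C = sum x^mu (x^mu)^T`.
For zero-mean patterns this retrieval can be rewritten as a universal
Hopfield sum with a *whitened* dot-product similarity,

    R(q) = (1/P) * sum_mu x^{mu+1} (M x^mu)^T (M q),   M = (C/P)^{-1/2},

i.e. the classic asymmetric Hopfield network (AHN) with an implicit
statistical-whitening step.  `whitening.py` implements the closed forms
(symmetric/ZCA square root, so `M` is deterministic; the retrieval value
depends on `M` only through `M^T M`), and `verify_property1` checks the
three routes against each other numerically.  The `1/P` factor comes from
defining the empirical second moment as a mean over the `P` stored
patterns; it cancels between the two `M`-products and the materialized
`A C^+` form, and tests pin this convention.

### 2-layer tPC

Hidden value neurons `z` add a latent context state: `W_H` predicts the
next hidden state, `W_F` predicts the sensory layer top-down.  Memorizing
step `mu` minimizes

    || z - W_H f(zhat^{mu-1}) ||^2 + || x^mu - W_F f(z) ||^2

first over `z` (Euler relaxation with the sensory layer clamped), then
over the weights with one Hebbian update per presentation of the full
sequence (`update_every="step"` applies updates per time step instead; the
difference is second order in the learning rate).  The converged `z`
becomes `zhat^mu` for the next step; `zhat^0 = 0`.  Because `z` is pulled
both by the input and by the temporal prediction from the previous hidden
state, identical sensory inputs occurring at different positions acquire
different hidden representations — the hidden layer indexes *when*, the
sensory layer *what*.

Recall resets the hidden state to seeded Gaussian noise (memories may only
live in the weights), infers `zhat^1` from the clamped cue, then per step
jointly relaxes `(z, x_hat)` on the recall energy; the converged `x_hat`
is the retrieval.  Offline recall carries the converged `z` forward;
online recall re-infers the hidden state from the clamped ground-truth
pattern (with the temporal prior still coming from the previous hidden
state).

### Asymmetric Hopfield family

`hopfield.py` implements the universal-Hopfield factorization
`R(q) = sum_mu x^{mu+1} sep((x^mu)^T q)` with identity, polynomial-`d` and
softmax(`beta`) separation (the latter the "modern continuous" AHN, MCAHN;
`beta = 5` by default).  For identity separation the weight matrix
`W_AHN = sum x^{mu+1}(x^mu)^T` is materialized and retrieval is
`sgn(W_AHN q)` on binary patterns, with `sgn(0) = +1` fixed.  Real-valued
retrieval skips the sign.  A strong-attractor diagnostic flags offline
recall steps where the softmax puts weight above 0.9 on a transition whose
source is not the previous step — the signature of a stored pattern with
an outsized dot-product advantage hijacking retrieval.

## Synthetic stimuli

All generators are pure functions of their arguments including the seed.

- **Uncorrelated binary**: i.i.d. uniform {-1, +1} entries.
- **Correlated binary**: per pattern, a scalar latent sign `g`; feature
  `i` is `g * s_i` with `s_i = +1` w.p. `p = (1 + sqrt(b))/2`.  Marginals
  stay uniform and every feature pair has correlation `(2p-1)^2 = b`
  exactly in expectation.  Higher moments are not matched to any
  particular natural ensemble; at small `N` and large `b` the construction
  produces exact duplicate/anti-duplicate patterns with probability
  `~((1+sqrt(b))/2)^N` per pattern, which matters for the full-rank
  assumption below.
- **One-hot words**: sequences of one-hot "letter" vectors, by default
  sampled without repetition (a permutation prefix).
- **Moving bar**: deterministic 5x5 movie; a full-row bar visits rows
  1,2,3,2,1 (1-based), so steps 2/4 — and the endpoints 1/5 — are aliased
  while their successors differ.
- **Rotating shapes**: each sequence renders one base shape and rotates it
  by a fixed angle per step (bilinear resampling, clipped to [0, 1]).
  Train family: irregular filled polygons (3-10 vertices, random
  per-vertex radii, random center offset) — a deliberately
  high-dimensional family so that small training sets under-cover it.
  Held-out family: filled concave star polygons (alternating outer/inner
  radii).  The two families are disjoint classes with matched fill
  statistics, so held-out recall can only succeed by transferring the
  rotation itself.  Thin-stroke shapes were avoided: at 12-16 px they
  rotate with severe resampling artifacts that dominate the MSE.

What the generators do **not** emulate: natural-image pixel statistics
(1/f spectra, occlusion, texture), the high intrinsic dimensionality of
handwritten characters, and temporal noise within a sequence.  Passing
tests therefore show that the mechanisms (whitening, context indexing,
dynamics transfer) work as claimed on stimuli with the stated statistical
structure, not that the models reach any particular performance level on
natural video.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| `lr_weights` (single) | 1e-2, or `"auto"` = `1/N` | per-step Hebbian stability for ±1 patterns requires `lr < 2/N`; `1/N` is the fastest safely contracting choice |
| `lr_weights` (2-layer) | 1e-3 (model), 0.02-0.2 (experiment presets) | non-convex objective; presets documented per experiment |
| `lr_inference` | 0.1-0.5 | Euler step of the relaxations; energy descent requires small steps, 0.01 is used in the monotonicity tests |
| `n_inference_steps` / `inference_tol` | 100-200 / 1e-5..1e-7 | relaxations stop on update norm; contracts are on the fixed point |
| `hidden_init_scale` | 0.1 (0.01 for the moving bar) | recall-time hidden reset noise; small values keep the rollout near the training trajectory |
| weight init (2-layer) | Gaussian, scale `w_init_scale/sqrt(Nz)`, `w_init_scale = 0.05` | symmetry breaking; the moving-bar preset uses 1.0 for reliable escape from flat regions |
| whitening `eps`, pinv `rcond` | 1e-10 relative to the top eigenvalue | small enough that the ridge bias in whitened retrieval stays below 1e-6 even at condition number ~100 |
| MCAHN `beta` | 5 | separation strength used throughout |

## Experiment design choices

- **Capacity (`estimate_pmax`)**: `P_max` is the largest tested length
  whose mean bit-error probability over `n_trials` fresh model/sequence
  pairs is at most 0.01.  Bit error is scored on signed outputs, the cue
  step excluded.  The scan is incremental with early stop after 3
  consecutive failing lengths (error is not guaranteed monotone at small
  trial counts); a coarse-stride bracket followed by stride-1 refinement
  is available and uses identical per-(length, trial) sub-seeds, so it
  agrees with the exhaustive scan wherever both test a length.  Trials
  are vectorized across models.
- **Whitening-equivalence verification**: the equivalence presumes the
  stored patterns are numerically full rank (the whitening matrix must
  exist and iterative training must converge in finite time).  Draws whose
  predictor matrix has condition number above 100 — overwhelmingly caused
  by exact duplicate patterns from the correlated generator at small `N` —
  are deterministically redrawn from sub-seeds; the report records the
  condition number and number of draws.
- **Serial recall**: a fresh 2-layer model per word, offline recall cued
  by the first letter, argmax letter decoding (lowest index on ties),
  accuracy = fraction of words with every scored position correct.  The
  behavioral regime comes from a *capacity-limited* hidden layer: 6 hidden
  units against a 26-letter alphabet, trained to convergence.
  Undertraining instead produces a monotone positional decay with no
  recency, and large recall-reset noise produces the mirror image
  (errors early, none late); the capacity-limited model yields the
  U-shaped positional curve with both primacy and a slightly weaker
  recency, and its errors fall mostly on neighboring positions.
  Primacy/recency scalars are measured relative to the minimum
  correct-recall frequency over the middle scored positions.
- **Moving bar**: hidden size fixed at 5 so the context code is
  inspectable.  The objective at this size is non-convex with a
  substantial rate of poor local optima, so the driver trains 8 restarts
  in one vectorized batch and keeps the restart with the lowest offline
  recall MSE on the memorized sequence — model selection on the training
  objective itself, no held-out data involved.
- **Aliasing**: the same base binary sequence is recalled plain and with
  `ceil(0.2 L)` steps replaced by one repeated pattern; online recall; the
  reported quantity is the aliasing-induced MSE increase per model class.
- **Generalization**: problem sizes are 12x12 frames, 4 steps of 60°,
  training sizes {16, 64, 256}, 3 seeds — a scale at which 16 sequences
  genuinely under-determine the rotation operator (16 x 3 transitions x
  144 pixel constraints vs ~20k operator parameters) while 256 sequences
  over-determine it, which is what makes the held-out error fall with
  training size.  One model per size memorizes all training sequences
  (gradients averaged across sequences); evaluation cues first frames and
  recalls offline.

## Numerical notes

- All relaxations are explicit Euler with fixed step and update-norm
  stopping; energies are non-increasing along the path for small steps
  (asserted at step 0.01 in tests).
- Divergence (weight norm above 1e6 or non-finite) raises a
  `DivergenceError` naming the learning rate rather than propagating NaNs.
- `sgn(0) = +1` everywhere a sign is taken.
- Degenerate inputs: all-zero sequences leave single-layer weights at
  zero (zero gradient); recalling from an all-zero model warns and returns
  zeros; hidden-context separation reports 0 when hidden norms fall below
  1e-6 (no meaningful angle exists).
- Randomness: every experiment derives per-condition sub-seeds from its
  seed via `numpy.random.SeedSequence`, so runs are bitwise reproducible
  and trials are independent.

## Known limitations

- Offline recall of the 2-layer model is a deterministic rollout through
  the hidden dynamics; when training settles in a poor stationary point
  the rollout drifts even though clamped (online) recall looks fine.  The
  restart strategy mitigates but does not eliminate this.
- The whitening equivalence is exact only for centered data and a
  full-rank pattern set; the trained network does not itself subtract
  means, so on uncentered data the correspondence is approximate.
- Capacity estimates at `N = 100` near `P ≈ N` are sensitive to the
  training epoch budget (400 epochs by default in the capacity recipe);
  they are comparisons under a fixed budget, not asymptotic capacities.
- Models with three or more layers, Kalman-filter formulations, and
  spiking/interneuron-level implementations are out of scope.
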