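# seqmem — sequential memory with temporal predictive coding

`seqmem` is a research package for computational neuroscientists studying
how a biologically plausible network can memorize and recall *sequences*
of patterns — words, movies, trajectories — rather than static items.  It
implements **temporal predictive coding (tPC)** networks with local
Hebbian learning and iterative inference, the **asymmetric Hopfield
network (AHN)** family as baselines, the closed-form **whitening theory**
that links the two, seeded synthetic stimulus generators, and the
experiment drivers that compare the models.

## The models in brief

Given a sequence `x^1 … x^{P+1}` (each `x^μ ∈ ℝ^N`), the single-layer tPC
minimizes the squared temporal prediction error per step,

    F_μ(W) = ‖x^μ − W f(x^{μ−1})‖²,

learning by the Hebbian rule `ΔW ∝ ε^μ f(x^{μ−1})ᵀ` with error neurons
`ε^μ = x^μ − W f(x^{μ−1})`, and recalling by relaxing the value neurons,
`dx̂/dt ∝ −ε`, to the fixed point `W f(q)` for a query `q`.  A 2-layer
variant adds hidden value neurons `z` with temporal weights `W_H` and
top-down weights `W_F`, minimizing
`‖z^μ − W_H f(ẑ^{μ−1})‖² + ‖x^μ − W_F f(z^μ)‖²`; the hidden layer learns a
*context* code that disambiguates identical inputs occurring at different
times.

The classic AHN stores `W_AHN = Σ_μ x^{μ+1}(x^μ)ᵀ` and retrieves
`sgn(W_AHN q)` in one shot; polynomial and softmax separation variants are
included under the universal Hopfield form
`R(q) = Σ_μ x^{μ+1} sep((x^μ)ᵀ q)`.

The central analytical fact connecting them: for zero-mean patterns and
`f = identity`, trained tPC retrieval equals

    R(q) = (1/P) Σ_μ x^{μ+1} (M x^μ)ᵀ (M q),   M = (C/P)^{−1/2},

i.e. an AHN whose dot-product similarity is computed after **statistical
whitening** of stored patterns and query.  That implicit whitening is why
tPC recall is nearly insensitive to feature correlations that collapse
plain dot-product retrieval.  `seqmem` verifies this equivalence
numerically and explores its behavioral consequences (sequence capacity,
serial-recall primacy/recency, aliased-input disambiguation, and
generalization of shared dynamics).

## Worked example

```python
import seqmem as sm
from seqmem.experiments import estimate_pmax, tpc_single_recipe, ahn_recipe

# 1. The whitening equivalence, on strongly correlated patterns
report = sm.verify_property1(n_features=20, length=10, corr_b=0.6, seed=0)
print(report["err_trained_vs_closed"])    # 6.08e-06
print(report["err_closed_vs_whitened"])   # 5.21e-09
print(report["passed"])                   # True

# 2. Sequence capacity at N = 25 (longest length with bit-error <= 1%)
tpc = estimate_pmax(tpc_single_recipe(), 25, threshold=0.01, n_trials=5, seed=0)
ahn = estimate_pmax(ahn_recipe(), 25, threshold=0.01, n_trials=5, seed=0)
print(tpc.p_max, ahn.p_max)               # 25 5
```

The first block trains a linear single-layer tPC iteratively on a
centered, correlated binary sequence and compares its recall against two
closed forms — the least-squares transition map `A C⁺ q` and the whitened
Hopfield sum — showing all three agree to ~1e-6 relative error even at
correlation 0.6.  The second block shows the capacity gap that whitening
buys: the tPC recalls sequences as long as its pattern dimension
(`P_max = 25` at `N = 25`), five times the classic AHN's `P_max = 5` under
the same 1% bit-error criterion.

## Command line

Each experiment family has a subcommand writing a tidy CSV plus a JSON
manifest of the resolved configuration:

```bash
seqmem verify-property1 --n-features 20 --length 10 --corr-b 0.6
seqmem capacity --model tpc_single --n-features 50 --seeds 0,1,2
seqmem behavior --lengths 3,5,7,9,11 --n-repetitions 100
seqmem aliasing --lengths 5,10,15 --n-features 32
seqmem generalize --training-sizes 16,64,256
seqmem run --config my_run.yaml      # schema: seqmem.cli.RunConfig
```

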