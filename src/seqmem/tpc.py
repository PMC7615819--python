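"""Temporal predictive coding (tPC) networks for sequential memory.

Two models are implemented.

**Single-layer tPC.**  A single weight matrix ``W`` learns to predict each
pattern from its predecessor by minimizing the squared temporal prediction
error ``F = ||x^mu - W f(x^{mu-1})||^2`` per step.  Learning is Hebbian
gradient descent ``dW = eps f(x^{mu-1})^T`` with the error neuron activity
``eps = x^mu - W f(x^{mu-1})``; recall runs leaky inferential dynamics on
the value neurons, ``d x_hat / dt = -eps``, whose fixed point is
``W f(q)`` for a query ``q``.

**2-layer tPC.**  Hidden value neurons ``z`` carry a latent context state:
``W_H`` makes the temporal prediction in the hidden layer and ``W_F`` makes
the top-down prediction of the sensory layer.  Memorizing a step minimizes
``||z - W_H f(z_prev)||^2 + ||x - W_F f(z)||^2`` first over ``z``
(iterative relaxation, the sensory layer clamped to the input), then over
the weights (one Hebbian update per presentation of the full sequence).
Because ``z`` is inferred from both the input *and* the temporal prediction
from the previous hidden state, identical sensory inputs occurring at
different positions acquire different hidden representations — the model
learns *when* an input occurs, not only *what* it is.

Recall modes (both models): *online* recall cues every step with the
ground-truth previous pattern; *offline* recall cues only the first step
and feeds the model's own previous retrieval forward, so errors can
accumulate.

All inference dynamics are discretized as explicit Euler steps with a fixed
step size (``lr_inference``) and run until the update norm falls below
``inference_tol`` or ``n_inference_steps`` is exhausted; contracts are
stated on the converged fixed point, not on the path.

Internally every computation is written over a pair of leading batch axes
``(B, S, ...)`` — ``B`` independent models and ``S`` sequences per model —
so experiment drivers can train hundreds of small models (or one model on
hundreds of sequences) in vectorized numpy.  The public API wraps the
``B = S = 1`` case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .sequences import PatternSequence

__all__ = [
    "DivergenceError",
    "TPCSingleLayer",
    "TPCTwoLayer",
    "RecallResult",
    "train_single_layer",
    "recall_single_layer",
    "train_two_layer",
    "recall_two_layer",
]

_WEIGHT_NORM_LIMIT = 1e6


class DivergenceError(RuntimeError):
    """Raised when training weights explode instead of converging."""


def _nonlin(name: str) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    if name == "identity":
        return (lambda x: x, lambda x: np.ones_like(x))
    if name == "tanh":
        return (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2)
    raise ValueError(f"unknown nonlinearity {name!r}; use 'identity' or 'tanh'")


@dataclass
class RecallResult:
    """Outcome of recalling a sequence.

    ``recalled`` holds the converged value-neuron activities ``x_hat^mu``
    per step (the first step is the cue, returned verbatim);
    ``per_step_energy`` the final prediction-error energy at each recalled
    step; ``hidden_trajectory`` the converged hidden states ``z_hat^mu``
    (2-layer models only).
    """

    recalled: PatternSequence
    mode: Literal["online", "offline"]
    per_step_energy: list[float]
    hidden_trajectory: list[np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)


# ======================================================================
# single-layer model
# ======================================================================


@dataclass
class TPCSingleLayer:
    """Single-layer tPC: one ``N x N`` transition weight matrix.

    ``lr_weights`` may be the string ``"auto"``, which resolves to
    ``1 / n_features`` — a per-step gradient size that keeps the Hebbian
    update contraction stable for {-1, +1} patterns of any dimension.
    Weights start at zero: the single-layer objective with identity ``f``
    is convex, and the zero start makes gradient descent converge to the
    minimum-norm least-squares transition map.
    """

    n_features: int
    nonlinearity: Literal["identity", "tanh"] = "identity"
    lr_weights: float | str = 1e-2
    lr_inference: float = 0.1
    n_inference_steps: int = 200
    inference_tol: float = 1e-6
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.W is None:
            self.W = np.zeros((self.n_features, self.n_features))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (self.n_features, self.n_features):
            raise ValueError("W must be n_features x n_features")

    @property
    def resolved_lr_weights(self) -> float:
        if self.lr_weights == "auto":
            return 1.0 / self.n_features
        return float(self.lr_weights)


def _check_finite(W: np.ndarray, lr: float, what: str = "W") -> None:
    if not np.all(np.isfinite(W)) or np.linalg.norm(W) > _WEIGHT_NORM_LIMIT:
        raise DivergenceError(
            f"{what} diverged during training (norm > {_WEIGHT_NORM_LIMIT:g} or non-finite); "
            f"reduce lr_weights (currently {lr:g})"
        )


def train_single_layer(
    seq: PatternSequence,
    model: TPCSingleLayer,
    n_epochs: int = 200,
    weight_tol: float = 1e-5,
) -> TPCSingleLayer:
    """Memorize a sequence by per-step Hebbian gradient descent on ``W``.

    Each epoch presents the sequence once; at every transition the weight
    receives ``lr * eps f(x^{mu-1})^T``.  Training stops early when the
    relative Frobenius change of ``W`` over an epoch drops below
    ``weight_tol``.  Raises :class:`DivergenceError` if the weights explode.
    """
    if seq.length < 2:
        raise ValueError("need at least one transition to train on")
    f, _ = _nonlin(model.nonlinearity)
    lr = model.resolved_lr_weights
    W = model.W
    pats = seq.patterns
    fprev = f(pats[:-1])
    for _ in range(int(n_epochs)):
        W_before = W.copy()
        for mu in range(1, seq.length):
            pre = fprev[mu - 1]
            eps = pats[mu] - W @ pre
            W += lr * np.outer(eps, pre)
        _check_finite(W, lr)
        denom = max(np.linalg.norm(W), np.finfo(float).tiny)
        if np.linalg.norm(W - W_before) / denom < weight_tol:
            break
    model.W = W
    return model


def _relax_to_target(
    target: np.ndarray,
    lr: float,
    n_steps: int,
    tol: float,
    record_energy: bool = False,
) -> tuple[np.ndarray, list[np.ndarray] | None]:
    """Euler relaxation of ``d x_hat/dt = -(x_hat - target)`` from zero.

    Vectorized over leading axes of ``target``; returns the converged state
    and, optionally, the per-iteration energy ``||x_hat - target||^2``
    (summed over the feature axis).
    """
    x = np.zeros_like(target)
    energies = [] if record_energy else None
    for _ in range(int(n_steps)):
        eps = x - target
        if record_energy:
            energies.append(np.sum(eps**2, axis=-1))
        dx = -eps
        x += lr * dx
        if np.max(np.abs(lr * dx)) < tol:
            break
    if record_energy:
        energies.append(np.sum((x - target) ** 2, axis=-1))
    return x, energies


def recall_single_layer(
    model: TPCSingleLayer,
    seq: PatternSequence,
    mode: Literal["online", "offline"] = "online",
    record_energy: bool = False,
) -> RecallResult:
    """Recall a sequence with the trained single-layer model.

    The first step is the cue ``x^1``.  Online mode then queries every step
    ``mu`` with the ground-truth ``x^{mu-1}``; offline mode queries with the
    model's own previous retrieval.  Each step relaxes the value neurons to
    the fixed point ``W f(q)``.
    """
    if mode not in ("online", "offline"):
        raise ValueError(f"mode must be 'online' or 'offline'; got {mode!r}")
    if not model.W.any():
        warnings.warn("recall from an untrained (all-zero) model returns zeros", stacklevel=2)
    f, _ = _nonlin(model.nonlinearity)
    pats = seq.patterns
    out = np.empty_like(pats)
    out[0] = pats[0]
    energy_paths = []
    if mode == "online":
        # every query is ground truth, so all relaxations are independent
        targets = f(pats[:-1]) @ model.W.T
        xh, en = _relax_to_target(
            targets, model.lr_inference, model.n_inference_steps, model.inference_tol, record_energy
        )
        out[1:] = xh
        final_energy = np.sum((xh - targets) ** 2, axis=-1)
        if record_energy:
            energy_paths = [np.asarray([e[t] for e in en]) for t in range(targets.shape[0])]
    else:
        final_energy = np.empty(seq.length - 1)
        for t in range(1, seq.length):
            target = model.W @ f(out[t - 1])
            xh, en = _relax_to_target(
                target, model.lr_inference, model.n_inference_steps, model.inference_tol, record_energy
            )
            out[t] = xh
            final_energy[t - 1] = np.sum((xh - target) ** 2)
            if record_energy:
                energy_paths.append(np.asarray(en))
    recalled = PatternSequence(out, "real", seq.frame_shape)
    diagnostics = {"energy_trajectories": energy_paths} if record_energy else {}
    return RecallResult(recalled=recalled, mode=mode, per_step_energy=list(map(float, final_energy)),
                        diagnostics=diagnostics)


def _train_single_layer_batch(
    X: np.ndarray,
    nonlinearity: str,
    lr: float,
    n_epochs: int,
    weight_tol: float = 1e-6,
) -> np.ndarray:
    """Train ``B`` independent single-layer models, one per sequence.

    ``X`` has shape ``(B, T, N)``; returns weights ``(B, N, N)``.  Same
    per-step Hebbian updates as :func:`train_single_layer`, vectorized over
    the model/sequence axis; training stops when every model's per-epoch
    relative weight change is below ``weight_tol``.
    """
    f, _ = _nonlin(nonlinearity)
    B, T, N = X.shape
    W = np.zeros((B, N, N))
    fprev = f(X[:, :-1])
    for _ in range(int(n_epochs)):
        W_before = W.copy()
        for mu in range(1, T):
            pre = fprev[:, mu - 1]
            eps = X[:, mu] - np.einsum("bij,bj->bi", W, pre)
            W += lr * np.einsum("bi,bj->bij", eps, pre)
        _check_finite(W, lr)
        num = np.linalg.norm(W - W_before, axis=(1, 2))
        den = np.maximum(np.linalg.norm(W, axis=(1, 2)), np.finfo(float).tiny)
        if np.max(num / den) < weight_tol:
            break
    return W


def _online_recall_single_batch(
    W: np.ndarray, X: np.ndarray, nonlinearity: str, lr: float, n_steps: int, tol: float
) -> np.ndarray:
    """Vectorized online recall for ``B`` models: all queries are ground
    truth, so every step's relaxation is independent."""
    f, _ = _nonlin(nonlinearity)
    targets = np.einsum("bij,btj->bti", W, f(X[:, :-1]))
    xh, _ = _relax_to_target(targets, lr, n_steps, tol)
    out = X.copy()
    out[:, 1:] = xh
    return out


# ======================================================================
# 2-layer model
# ======================================================================


@dataclass
class TPCTwoLayer:
    """2-layer tPC with hidden context states.

    ``W_H`` (``Nz x Nz``) predicts the next hidden state; ``W_F``
    (``N x Nz``) predicts the sensory layer from the hidden layer.  Weights
    are initialized Gaussian with scale ``0.05 / sqrt(hidden_dim)`` (the
    objective is non-convex, so symmetry must be broken), seeded by
    ``seed``.  Hidden states are reset to seeded Gaussian noise of scale
    ``hidden_init_scale`` at the start of recall: memories can only be
    carried by the weights.
    """

    n_features: int
    hidden_dim: int
    nonlinearity: Literal["identity", "tanh"] = "tanh"
    lr_weights: float = 1e-3
    lr_inference: float = 0.1
    n_inference_steps: int = 200
    inference_tol: float = 1e-6
    hidden_init_scale: float = 0.1
    w_init_scale: float = 0.05
    seed: int = 0
    W_H: np.ndarray | None = None
    W_F: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.W_H is None or self.W_F is None:
            rng = np.random.default_rng(self.seed)
            scale = self.w_init_scale / np.sqrt(self.hidden_dim)
            self.W_H = rng.normal(0.0, scale, size=(self.hidden_dim, self.hidden_dim))
            self.W_F = rng.normal(0.0, scale, size=(self.n_features, self.hidden_dim))
        self.W_H = np.asarray(self.W_H, dtype=float)
        self.W_F = np.asarray(self.W_F, dtype=float)


# ---- batched primitives (leading axes: B models, S sequences) ---------


def _infer_hidden(
    WH: np.ndarray,
    WF: np.ndarray,
    zhat_prev: np.ndarray,
    x: np.ndarray,
    nonlinearity: str,
    lr: float,
    n_steps: int,
    tol: float,
    record_energy: bool = False,
):
    """Relax hidden states with the sensory layer clamped to ``x``.

    Minimizes ``||z - W_H f(zhat_prev)||^2 + ||x - W_F f(z)||^2`` over
    ``z`` by Euler steps on ``dz = -eps_z + f'(z) * (W_F^T eps_x)``.
    Shapes: ``WH (B,Nz,Nz)``, ``WF (B,N,Nz)``, ``zhat_prev (B,S,Nz)``,
    ``x (B,S,N)``.
    """
    f, fp = _nonlin(nonlinearity)
    pred = np.einsum("bij,bsj->bsi", WH, f(zhat_prev))
    z = pred.copy()
    energies = [] if record_energy else None
    eps_z = np.zeros_like(z)
    eps_x = x - np.einsum("bij,bsj->bsi", WF, f(z))
    for _ in range(int(n_steps)):
        eps_z = z - pred
        eps_x = x - np.einsum("bij,bsj->bsi", WF, f(z))
        if record_energy:
            energies.append(np.sum(eps_z**2, axis=-1) + np.sum(eps_x**2, axis=-1))
        dz = -eps_z + fp(z) * np.einsum("bsi,bij->bsj", eps_x, WF)
        z += lr * dz
        if np.max(np.abs(lr * dz)) < tol:
            break
    eps_z = z - pred
    eps_x = x - np.einsum("bij,bsj->bsi", WF, f(z))
    if record_energy:
        energies.append(np.sum(eps_z**2, axis=-1) + np.sum(eps_x**2, axis=-1))
    return z, eps_z, eps_x, energies


def _relax_joint(
    WH: np.ndarray,
    WF: np.ndarray,
    zhat_prev: np.ndarray,
    nonlinearity: str,
    lr: float,
    n_steps: int,
    tol: float,
    record_energy: bool = False,
):
    """Jointly relax hidden and sensory value neurons during recall.

    Both ``z`` and ``x_hat`` descend the recall energy
    ``||z - W_H f(zhat_prev)||^2 + ||x_hat - W_F f(z)||^2``; the converged
    ``x_hat`` is the retrieval for this step.
    """
    f, fp = _nonlin(nonlinearity)
    pred = np.einsum("bij,bsj->bsi", WH, f(zhat_prev))
    z = pred.copy()
    xh = np.zeros(pred.shape[:-1] + (WF.shape[1],))
    energies = [] if record_energy else None
    for _ in range(int(n_steps)):
        eps_z = z - pred
        eps_x = xh - np.einsum("bij,bsj->bsi", WF, f(z))
        if record_energy:
            energies.append(np.sum(eps_z**2, axis=-1) + np.sum(eps_x**2, axis=-1))
        dz = -eps_z + fp(z) * np.einsum("bsi,bij->bsj", eps_x, WF)
        dx = -eps_x
        z += lr * dz
        xh += lr * dx
        if max(np.max(np.abs(lr * dz)), np.max(np.abs(lr * dx))) < tol:
            break
    eps_z = z - pred
    eps_x = xh - np.einsum("bij,bsj->bsi", WF, f(z))
    if record_energy:
        energies.append(np.sum(eps_z**2, axis=-1) + np.sum(eps_x**2, axis=-1))
    final_energy = np.sum(eps_z**2, axis=-1) + np.sum(eps_x**2, axis=-1)
    return z, xh, final_energy, energies


def _train_two_layer_batch(
    WH: np.ndarray,
    WF: np.ndarray,
    X: np.ndarray,
    nonlinearity: str,
    lr_weights: float,
    lr_inference: float,
    n_inference_steps: int,
    inference_tol: float,
    n_epochs: int,
    weight_tol: float = 1e-5,
    update_every: str = "sequence",
) -> tuple[np.ndarray, np.ndarray]:
    """Train batched 2-layer tPC weights on data ``X (B, S, T, N)``.

    With ``update_every="sequence"`` (default) weight gradients are
    accumulated over all ``T`` steps (hidden states carried forward within
    each sequence, ``zhat^0 = 0``) and applied once per presentation of the
    full sequence; with ``"step"`` the Hebbian update is applied
    immediately at every time step, so transitions presented later in the
    sequence are learned on top of (and partially overwrite) earlier ones.
    Gradients are averaged over the ``S`` sequence axis so the learning
    rate is independent of how many sequences a model memorizes.
    """
    f, _ = _nonlin(nonlinearity)
    B, S, T, _ = X.shape
    Nz = WH.shape[-1]
    per_step = update_every == "step"
    for _ in range(int(n_epochs)):
        WH_before = WH.copy()
        WF_before = WF.copy()
        gWH = np.zeros_like(WH)
        gWF = np.zeros_like(WF)
        zhat = np.zeros((B, S, Nz))
        for t in range(T):
            z, eps_z, eps_x, _ = _infer_hidden(
                WH, WF, zhat, X[:, :, t], nonlinearity, lr_inference, n_inference_steps, inference_tol
            )
            if per_step:
                WH += lr_weights * np.einsum("bsi,bsj->bij", eps_z, f(zhat)) / S
                WF += lr_weights * np.einsum("bsi,bsj->bij", eps_x, f(z)) / S
            else:
                gWH += np.einsum("bsi,bsj->bij", eps_z, f(zhat)) / S
                gWF += np.einsum("bsi,bsj->bij", eps_x, f(z)) / S
            zhat = z
        WH += lr_weights * gWH
        WF += lr_weights * gWF
        _check_finite(WH, lr_weights, "W_H")
        _check_finite(WF, lr_weights, "W_F")
        num = np.linalg.norm(WH - WH_before) + np.linalg.norm(WF - WF_before)
        den = max(np.linalg.norm(WH) + np.linalg.norm(WF), np.finfo(float).tiny)
        if num / den < weight_tol:
            break
    return WH, WF


def _recall_two_layer_batch(
    WH: np.ndarray,
    WF: np.ndarray,
    X: np.ndarray,
    mode: str,
    rng: np.random.Generator,
    nonlinearity: str,
    lr_inference: float,
    n_inference_steps: int,
    inference_tol: float,
    hidden_init_scale: float,
    record_energy: bool = False,
):
    """Batched recall.  ``X (B, S, T, N)`` supplies the cue (and, online,
    the ground-truth queries).  Returns retrievals ``(B, S, T, N)``, the
    hidden trajectory ``(T, B, S, Nz)`` and per-step energies."""
    B, S, T, N = X.shape
    Nz = WH.shape[-1]
    out = np.empty_like(X)
    out[:, :, 0] = X[:, :, 0]
    z0 = rng.normal(0.0, hidden_init_scale, size=(B, S, Nz))
    zhat, *_ = _infer_hidden(
        WH, WF, z0, X[:, :, 0], nonlinearity, lr_inference, n_inference_steps, inference_tol
    )
    hidden = np.empty((T, B, S, Nz))
    hidden[0] = zhat
    energies = np.empty((T - 1, B, S))
    energy_paths = [] if record_energy else None
    for t in range(1, T):
        z, xh, final_e, epath = _relax_joint(
            WH, WF, zhat, nonlinearity, lr_inference, n_inference_steps, inference_tol, record_energy
        )
        out[:, :, t] = xh
        energies[t - 1] = final_e
        if record_energy:
            energy_paths.append(epath)
        if mode == "online":
            # re-infer the hidden state from the clamped ground-truth pattern,
            # with the temporal prior still coming from the previous hidden state
            zhat, *_ = _infer_hidden(
                WH, WF, zhat, X[:, :, t], nonlinearity, lr_inference, n_inference_steps, inference_tol
            )
        else:
            zhat = z
        hidden[t] = zhat
    return out, hidden, energies, energy_paths


# ---- public single-model API -----------------------------------------


def train_two_layer(
    seqs: PatternSequence | Sequence[PatternSequence],
    model: TPCTwoLayer,
    n_epochs: int = 200,
    weight_tol: float = 1e-5,
    update_every: str = "sequence",
) -> TPCTwoLayer:
    """Memorize one or more sequences with a 2-layer tPC model.

    Sequences of equal length are processed together (vectorized); by
    default weight updates are applied once per presentation of the full
    sequences (``update_every="step"`` applies them at every time step),
    with gradients averaged across sequences.
    """
    if isinstance(seqs, PatternSequence):
        seqs = [seqs]
    if not seqs:
        raise ValueError("need at least one sequence")
    if any(s.n_features != model.n_features for s in seqs):
        raise ValueError("all sequences must match the model's n_features")
    WH = model.W_H[None]
    WF = model.W_F[None]
    by_len: dict[int, list[PatternSequence]] = {}
    for s in seqs:
        by_len.setdefault(s.length, []).append(s)
    for length, group in sorted(by_len.items()):
        X = np.stack([s.patterns for s in group])[None]  # (1, S, T, N)
        WH, WF = _train_two_layer_batch(
            WH, WF, X, model.nonlinearity, model.lr_weights, model.lr_inference,
            model.n_inference_steps, model.inference_tol, n_epochs, weight_tol,
            update_every,
        )
    model.W_H = WH[0]
    model.W_F = WF[0]
    return model


def recall_two_layer(
    model: TPCTwoLayer,
    seq: PatternSequence,
    mode: Literal["online", "offline"] = "offline",
    seed: int | None = None,
    record_energy: bool = False,
) -> RecallResult:
    """Recall a sequence with a trained 2-layer model.

    Hidden states are reset to seeded Gaussian noise (they cannot store the
    memory themselves); the cue ``x^1`` is used to infer the first hidden
    state, after which each step jointly relaxes hidden and sensory value
    neurons.  Online mode re-infers the hidden state from the ground-truth
    pattern after each retrieval; offline mode carries the model's own
    converged hidden state forward.
    """
    if mode not in ("online", "offline"):
        raise ValueError(f"mode must be 'online' or 'offline'; got {mode!r}")
    rng = np.random.default_rng(model.seed + 1 if seed is None else seed)
    X = seq.patterns[None, None]  # (1, 1, T, N)
    out, hidden, energies, epaths = _recall_two_layer_batch(
        model.W_H[None], model.W_F[None], X, mode, rng, model.nonlinearity,
        model.lr_inference, model.n_inference_steps, model.inference_tol,
        model.hidden_init_scale, record_energy,
    )
    recalled = PatternSequence(out[0, 0], "real", seq.frame_shape)
    diagnostics = {"energy_trajectories": epaths} if record_energy else {}
    return RecallResult(
        recalled=recalled,
        mode=mode,
        per_step_energy=[float(e[0, 0]) for e in energies],
        hidden_trajectory=[hidden[t, 0, 0].copy() for t in range(seq.length)],
        diagnostics=diagnostics,
    )
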