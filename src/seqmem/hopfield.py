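"""Asymmetric Hopfield networks (AHN) under the universal Hopfield
retrieval abstraction.

The classic AHN stores the asymmetric cross-step outer-product sum
``W_AHN = sum_mu x^{mu+1} (x^mu)^T`` and retrieves the successor of a query
``q`` in a single shot, ``sgn(W_AHN q)``.  The universal Hopfield form
factors this into a dot-product *similarity* between ``q`` and each stored
predecessor, a *separation* function sharpening the similarity scores, and
a weighted sum of successors:

    R(q) = sum_mu x^{mu+1} sep( (x^mu)^T q ).

Separation choices implemented: identity (the classic AHN, equivalently
polynomial degree 1), polynomial of degree ``d``, and softmax with
temperature ``beta`` (the modern continuous AHN, MCAHN, the sequential
analogue of attention-style Hopfield retrieval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import softmax as _softmax

from .sequences import PatternSequence
from .tpc import RecallResult

__all__ = ["Separation", "identity_sep", "polynomial_sep", "softmax_sep",
           "AHNModel", "build_ahn", "retrieve", "recall_sequence_ahn"]


@dataclass(frozen=True)
class Separation:
    """Separation function spec: identity, polynomial(d) or softmax(beta)."""

    kind: Literal["identity", "polynomial", "softmax"] = "identity"
    degree: int = 1
    beta: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "polynomial", "softmax"):
            raise ValueError(f"unknown separation kind {self.kind!r}")
        if self.kind == "polynomial" and (self.degree < 1 or int(self.degree) != self.degree):
            raise ValueError("polynomial degree must be a positive integer")
        if self.kind == "softmax" and self.beta <= 0:
            raise ValueError("softmax temperature beta must be positive")

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        if self.kind == "identity":
            return scores
        if self.kind == "polynomial":
            return scores ** self.degree
        return _softmax(self.beta * scores)


def identity_sep() -> Separation:
    return Separation("identity")


def polynomial_sep(degree: int) -> Separation:
    return Separation("polynomial", degree=degree)


def softmax_sep(beta: float = 5.0) -> Separation:
    return Separation("softmax", beta=beta)


@dataclass(frozen=True)
class AHNModel:
    """Stored sequence plus separation spec; weight matrix materialized for
    the classic (identity-separation) case."""

    stored: PatternSequence
    separation: Separation = field(default_factory=identity_sep)
    W_AHN: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.stored.n_features


def build_ahn(seq: PatternSequence, separation: Separation | None = None) -> AHNModel:
    """Store a sequence for single-shot successor retrieval.

    For identity separation the cross-step sum ``W_AHN`` is materialized
    explicitly (retrieval is then the matrix-vector product ``W_AHN q``);
    other separations retrieve directly from the stored patterns.
    """
    separation = separation or identity_sep()
    W = None
    if separation.kind == "identity" or (separation.kind == "polynomial" and separation.degree == 1):
        X, Y = seq.patterns[:-1], seq.patterns[1:]
        W = Y.T @ X
    return AHNModel(stored=seq, separation=separation, W_AHN=W)


def retrieve(model: AHNModel, query: np.ndarray, binary_output: bool = False) -> np.ndarray:
    """Single-shot retrieval of the successor of ``query``.

    ``binary_output`` applies the sign function with the convention
    ``sgn(0) = +1`` (used for {-1, +1} patterns; real-valued retrieval skips
    it).
    """
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != model.n_features:
        raise ValueError("query dimension does not match the stored patterns")
    X, Y = model.stored.patterns[:-1], model.stored.patterns[1:]
    weights = model.separation(X @ query)
    ret = Y.T @ weights
    if binary_output:
        ret = np.where(ret >= 0, 1.0, -1.0)
    return ret


def recall_sequence_ahn(
    model: AHNModel,
    seq: PatternSequence,
    mode: Literal["online", "offline"] = "online",
    binary_output: bool | None = None,
    attractor_threshold: float = 0.9,
) -> RecallResult:
    """Chain single-shot retrievals over a sequence.

    Online mode queries every step with the ground-truth previous pattern;
    offline mode feeds each retrieval forward as the next query, starting
    from the true first pattern.  The first step is the cue and is returned
    verbatim.

    For softmax separation the result's ``diagnostics`` record a
    strong-attractor flag: a hit at step ``t`` means the softmax placed
    weight above ``attractor_threshold`` on a transition whose source index
    is not ``t - 1``, i.e. retrieval was hijacked by a stored pattern with
    an outsized dot-product advantage.
    """
    if mode not in ("online", "offline"):
        raise ValueError(f"mode must be 'online' or 'offline'; got {mode!r}")
    if binary_output is None:
        binary_output = seq.domain_tag == "binary"
    X = model.stored.patterns[:-1]
    out = np.empty_like(seq.patterns)
    out[0] = seq.patterns[0]
    energies = []
    hits: list[int] = []
    for t in range(1, seq.length):
        q = seq.patterns[t - 1] if mode == "online" else out[t - 1]
        if model.separation.kind == "softmax":
            w = model.separation(X @ q)
            top = int(np.argmax(w))
            if w[top] > attractor_threshold and top != t - 1:
                hits.append(t)
        out[t] = retrieve(model, q, binary_output=binary_output)
        energies.append(float(np.sum((out[t] - seq.patterns[t]) ** 2)))
    recalled = PatternSequence(out, seq.domain_tag if binary_output else "real", seq.frame_shape)
    return RecallResult(recalled=recalled, mode=mode, per_step_energy=energies,
                        diagnostics={"strong_attractor_steps": hits})
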