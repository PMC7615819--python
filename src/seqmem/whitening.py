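"""Closed-form machinery relating linear temporal predictive coding to
asymmetric Hopfield retrieval through statistical whitening.

For a sequence ``x^1 .. x^{P+1}`` define

* the asymmetric cross-step sum ``A = sum_mu x^{mu+1} (x^mu)^T`` (the AHN
  weight matrix),
* the second-moment matrix of the predictor patterns
  ``C = sum_{mu=1..P} x^mu (x^mu)^T``.

A linear temporal predictor trained by gradient descent from zero weights
converges to the minimum-norm least-squares transition map ``W = A C^+``.
Its retrieval of a query ``q`` can equivalently be written in the universal
Hopfield form with a *whitened* dot-product similarity,

    R(q) = sum_mu x^{mu+1} (M x^mu)^T (M q),

where ``M = (C/P)^{-1/2}`` (symmetric/ZCA square root) makes the stored
patterns have identity empirical second moment on their span.  Iterative
temporal predictive coding therefore behaves like an asymmetric Hopfield
network that decorrelates and normalizes the patterns before comparing them
with the query — which is why its recall is insensitive to feature
correlations that cripple the plain dot product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import PatternSequence

__all__ = ["WhiteningOperator", "closed_form_weights", "whitening_matrix", "whitened_retrieve"]


def _predictors_targets(seq: PatternSequence, center: bool) -> tuple[np.ndarray, np.ndarray]:
    pats = seq.patterns
    if center:
        pats = pats - pats.mean(axis=0)
    return pats[:-1], pats[1:]  # x^1..x^P, x^2..x^{P+1}


@dataclass(frozen=True)
class WhiteningOperator:
    """Symmetric (ZCA) whitening matrix for a stored pattern set.

    ``M = (C/P + eps*I)^{-1/2}`` with ``C`` the summed second-moment matrix
    of the predictor patterns ``x^1..x^P``.  ``eps`` is relative to the
    largest eigenvalue of ``C/P``, so rank-deficient pattern sets are
    handled without error; the identity-second-moment property then holds on
    the span of the patterns only.
    """

    M: np.ndarray
    C: np.ndarray
    regularization: float
    rank: int

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return v @ self.M.T if v.ndim == 2 else self.M @ v


def closed_form_weights(seq: PatternSequence, center: bool = True, rcond: float = 1e-10) -> np.ndarray:
    """Minimum-norm least-squares transition map ``W = A C^+``.

    This is the weight matrix minimizing ``sum_mu ||x^{mu+1} - W x^mu||^2``
    (with the minimum Frobenius norm among minimizers), i.e. the fixed point
    that iterative linear tPC training reaches from zero initial weights.
    ``center`` subtracts the sequence mean first, matching the zero-mean
    assumption under which the whitened-retrieval identity is exact.
    """
    X, Y = _predictors_targets(seq, center)
    A = Y.T @ X
    C = X.T @ X
    return A @ np.linalg.pinv(C, rcond=rcond, hermitian=True)


def whitening_matrix(seq: PatternSequence, center: bool = True, eps: float = 1e-10) -> WhiteningOperator:
    """Empirical ZCA whitener of the predictor patterns.

    Returns symmetric ``M`` with ``mean_mu (M x^mu)(M x^mu)^T = I`` on the
    span of the patterns, to a tolerance governed by ``eps`` (relative to
    the largest eigenvalue).
    """
    X, _ = _predictors_targets(seq, center)
    P = X.shape[0]
    C = X.T @ X
    Cn = C / P
    evals, evecs = np.linalg.eigh(Cn)
    reg = eps * max(float(evals[-1]), np.finfo(float).tiny)
    inv_sqrt = 1.0 / np.sqrt(np.clip(evals, 0.0, None) + reg)
    M = (evecs * inv_sqrt) @ evecs.T
    rank = int(np.sum(evals > reg))
    return WhiteningOperator(M=M, C=C, regularization=reg, rank=rank)


def whitened_retrieve(
    seq: PatternSequence, whitener: WhiteningOperator, query: np.ndarray, center: bool = True
) -> np.ndarray:
    """Universal-Hopfield retrieval with whitened dot-product similarity.

    Computes ``sum_mu x^{mu+1} (M x^mu)^T (M q)`` — identity separation, but
    similarity measured after both stored pattern and query are passed
    through ``M``.  On full-rank pattern sets this equals the least-squares
    map ``A C^+`` applied to ``q``; for a stored query ``x^k`` it returns
    ``x^{k+1}`` exactly even when the features are strongly correlated,
    because whitened patterns are orthonormal.
    """
    query = np.asarray(query, dtype=float).ravel()
    pats = seq.patterns
    mean = pats.mean(axis=0) if center else np.zeros(pats.shape[1])
    X = pats[:-1] - mean
    Y = pats[1:] - mean
    scores = (X @ whitener.M.T) @ (whitener.M @ (query - mean)) / X.shape[0]
    return Y.T @ scores + mean
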