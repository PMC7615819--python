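"""Pattern sequences and synthetic sequence generators.

A :class:`PatternSequence` is the unit of memorization throughout the
package: an ordered list of ``P + 1`` pattern vectors ``x^1 .. x^{P+1}`` of
shared dimension ``N``.  Sequential memory models learn the ``P``
transitions between consecutive patterns and are later cued with the first
pattern (or with ground-truth patterns, in online recall) to reproduce the
rest.

All generators here are pure functions of their arguments, including the
seed: calling one twice with identical arguments returns bitwise-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

DomainTag = Literal["binary", "real", "onehot", "image"]

__all__ = [
    "PatternSequence",
    "CorrelationSpec",
    "generate_binary_sequence",
    "generate_correlated_binary_sequence",
    "generate_onehot_word",
    "generate_moving_bar",
    "alias_sequence",
    "generate_rotating_shape_set",
    "to_bipolar",
    "to_unit_range",
]


def to_bipolar(seq: "PatternSequence", threshold: float = 0.5) -> "PatternSequence":
    """Convert a [0, 1]-valued sequence to {-1, +1} by thresholding."""
    return PatternSequence(np.where(seq.patterns >= threshold, 1.0, -1.0), "binary", seq.frame_shape)


def to_unit_range(seq: "PatternSequence") -> "PatternSequence":
    """Convert a {-1, +1}-valued sequence to {0, 1} pixel range."""
    return PatternSequence((seq.patterns + 1.0) / 2.0, "image" if seq.frame_shape else "real",
                           seq.frame_shape)


@dataclass(frozen=True)
class PatternSequence:
    """An ordered sequence of ``P + 1`` pattern vectors of dimension ``N``.

    Parameters
    ----------
    patterns
        Array of shape ``(P + 1, N)``; row ``mu`` holds pattern ``x^{mu+1}``
        (0-based row index).
    domain_tag
        One of ``binary`` (entries in {-1, +1}), ``real``, ``onehot``
        (exactly one entry 1, rest 0) or ``image`` (pixel values, usually
        in [0, 1]).
    frame_shape
        ``(rows, cols)`` for image-domain sequences whose vectors are
        flattened frames; ``None`` otherwise.
    """

    patterns: np.ndarray
    domain_tag: DomainTag = "real"
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.patterns, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"patterns must be 2-D (steps, features); got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 patterns (one transition)")
        if self.domain_tag == "binary" and not np.all(np.isin(arr, (-1.0, 1.0))):
            raise ValueError("binary-domain entries must be in {-1, +1}")
        if self.domain_tag == "onehot":
            if not (np.all(np.isin(arr, (0.0, 1.0))) and np.all(arr.sum(axis=1) == 1)):
                raise ValueError("onehot-domain patterns must have exactly one entry equal to 1")
        if self.frame_shape is not None and math.prod(self.frame_shape) != arr.shape[1]:
            raise ValueError("frame_shape does not match the feature dimension")
        object.__setattr__(self, "patterns", arr)

    @property
    def length(self) -> int:
        """Number of patterns, ``P + 1``."""
        return self.patterns.shape[0]

    @property
    def n_features(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_transitions(self) -> int:
        """``P``, the number of consecutive-pattern transitions."""
        return self.length - 1

    def __len__(self) -> int:
        return self.length

    def __getitem__(self, mu: int) -> np.ndarray:
        return self.patterns[mu]

    def with_patterns(self, patterns: np.ndarray, domain_tag: DomainTag | None = None) -> "PatternSequence":
        """Copy of this sequence with new pattern values (shape preserved)."""
        return replace(self, patterns=patterns, domain_tag=domain_tag or self.domain_tag)

    # -- serialization ----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write one row per time step with header ``t,f0..f{N-1}``."""
        import pandas as pd

        cols = [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.patterns, columns=cols)
        df.insert(0, "t", np.arange(self.length))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domain_tag: DomainTag = "real",
                 frame_shape: tuple[int, int] | None = None) -> "PatternSequence":
        import pandas as pd

        df = pd.read_csv(path).sort_values("t")
        return cls(df.drop(columns="t").to_numpy(float), domain_tag, frame_shape)

    def to_pgm_frames(self, directory, prefix: str = "frame") -> list[str]:
        """Dump an image-domain sequence as plain-text (P2) PGM files."""
        if self.frame_shape is None:
            raise ValueError("only image-domain sequences with a frame_shape can be dumped as PGM")
        import os

        paths = []
        for t, vec in enumerate(self.patterns):
            img = np.clip(vec.reshape(self.frame_shape), 0.0, 1.0)
            gray = np.rint(img * 255).astype(int)
            lines = [f"P2", f"{img.shape[1]} {img.shape[0]}", "255"]
            lines += [" ".join(str(v) for v in row) for row in gray]
            path = os.path.join(directory, f"{prefix}_{t:03d}.pgm")
            with open(path, "w") as fh:
                fh.write("\n".join(lines) + "\n")
            paths.append(path)
        return paths


@dataclass(frozen=True)
class CorrelationSpec:
    """Magnitude ``b`` of the pairwise feature correlation, ``0 <= b < 1``."""

    b: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b < 1.0):
            raise ValueError(f"correlation magnitude b must be in [0, 1); got {self.b}")


def _check_positive(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if int(value) != value or value <= 0:
            raise ValueError(f"{name} must be a positive integer; got {value!r}")


def generate_binary_sequence(n_features: int, length: int, seed: int) -> PatternSequence:
    """Sequence of i.i.d. uniform {-1, +1} patterns (uncorrelated features)."""
    _check_positive(n_features=n_features, length=length)
    rng = np.random.default_rng(seed)
    pats = rng.choice((-1.0, 1.0), size=(length, n_features))
    return PatternSequence(pats, "binary")


def generate_correlated_binary_sequence(
    n_features: int, length: int, corr: CorrelationSpec | float, seed: int
) -> PatternSequence:
    """Binary patterns whose features are pairwise correlated with magnitude ``b``.

    Each pattern draws a latent sign ``g`` uniform on {-1, +1}; feature ``i``
    is ``g * s_i`` where ``s_i = +1`` with probability ``p = (1 + sqrt(b))/2``
    and ``-1`` otherwise, independently per feature and pattern.  Marginals
    stay uniform on {-1, +1} and any two distinct features have correlation
    ``(2p - 1)^2 = b``.  ``b = 0`` reduces to the uncorrelated generator.
    """
    _check_positive(n_features=n_features, length=length)
    if not isinstance(corr, CorrelationSpec):
        corr = CorrelationSpec(float(corr))
    rng = np.random.default_rng(seed)
    p = (1.0 + math.sqrt(corr.b)) / 2.0
    latent = rng.choice((-1.0, 1.0), size=(length, 1))
    keep = rng.random(size=(length, n_features)) < p
    signs = np.where(keep, 1.0, -1.0)
    return PatternSequence(latent * signs, "binary")


def generate_onehot_word(
    alphabet_size: int, word_length: int, seed: int, distinct: bool = True
) -> PatternSequence:
    """A "word": a sequence of one-hot letter vectors of dimension ``alphabet_size``.

    With ``distinct`` (the default) letters never repeat within the word,
    which requires ``word_length <= alphabet_size``.
    """
    _check_positive(alphabet_size=alphabet_size, word_length=word_length)
    if distinct and word_length > alphabet_size:
        raise ValueError(
            f"distinct letters require word_length <= alphabet_size "
            f"({word_length} > {alphabet_size})"
        )
    rng = np.random.default_rng(seed)
    if distinct:
        letters = rng.permutation(alphabet_size)[:word_length]
    else:
        letters = rng.integers(0, alphabet_size, size=word_length)
    pats = np.zeros((word_length, alphabet_size))
    pats[np.arange(word_length), letters] = 1.0
    if word_length >= 2:
        return PatternSequence(pats, "onehot")
    # A single-letter "word" has no transition; bypass the length-2 contract,
    # which only binds for sequences that are actually memorized.
    seq = object.__new__(PatternSequence)
    object.__setattr__(seq, "patterns", pats)
    object.__setattr__(seq, "domain_tag", "onehot")
    object.__setattr__(seq, "frame_shape", None)
    return seq


def generate_moving_bar() -> PatternSequence:
    """The deterministic aliased moving-bar movie.

    A white horizontal bar (one full row of ones) moves down then up in a
    5x5 frame, visiting rows 1, 2, 3, 2, 1 (1-based) over five steps, so the
    frames at steps 2 and 4 are identical ("aliased") while their successors
    differ.  This is the minimal task on which a hidden context state is
    required for correct recall.
    """
    rows = (0, 1, 2, 1, 0)
    frames = np.zeros((5, 25))
    for t, r in enumerate(rows):
        frame = np.zeros((5, 5))
        frame[r, :] = 1.0
        frames[t] = frame.ravel()
    return PatternSequence(frames, "image", frame_shape=(5, 5))


def alias_sequence(
    seq: PatternSequence, fraction: float, repeated_pattern: np.ndarray, seed: int
) -> PatternSequence:
    """Replace ``ceil(fraction * length)`` randomly chosen steps with one pattern.

    The replacement positions are drawn uniformly without replacement and are
    reproducible under ``seed``; every other step is untouched.  The result
    contains aliased (repeated) patterns whenever two or more positions are
    replaced.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1); got {fraction}")
    repeated_pattern = np.asarray(repeated_pattern, dtype=float).ravel()
    if repeated_pattern.shape[0] != seq.n_features:
        raise ValueError("repeated_pattern dimension does not match the sequence")
    n_replace = math.ceil(fraction * seq.length)
    rng = np.random.default_rng(seed)
    positions = rng.choice(seq.length, size=n_replace, replace=False)
    pats = seq.patterns.copy()
    pats[positions] = repeated_pattern
    tag = seq.domain_tag
    if tag == "binary" and not np.all(np.isin(repeated_pattern, (-1.0, 1.0))):
        tag = "real"
    return PatternSequence(pats, tag, seq.frame_shape)


# -- rotating shapes ------------------------------------------------------

# train: filled irregular polygons (random per-vertex radii); heldout:
# filled concave star polygons (strictly alternating outer/inner radii).
# Disjoint shape classes with matched fill statistics and a genuinely
# high-dimensional training family (vertex count, per-vertex radii, phase
# and center offset all vary), so small training sets under-cover it and
# held-out recall can only succeed by transferring the rotation dynamics.
_TRAIN_VERTICES = (3, 4, 5, 6, 7, 8, 9, 10)
_HELDOUT_POINTS = (5, 6, 7)


def _fill_polygon(side: int, radii: np.ndarray, angles: np.ndarray,
                  offset: tuple[float, float]) -> np.ndarray:
    from skimage.draw import polygon

    c = (side - 1) / 2.0
    rr, cc = polygon(
        c + offset[0] + radii * np.sin(angles),
        c + offset[1] + radii * np.cos(angles),
        shape=(side, side),
    )
    img = np.zeros((side, side))
    img[rr, cc] = 1.0
    return img


def _base_shape(family: str, side: int, rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0, 2 * math.pi)
    offset = tuple(rng.uniform(-0.2, 0.2, size=2) * side)
    if family == "train":
        k = int(_TRAIN_VERTICES[rng.integers(len(_TRAIN_VERTICES))])
        angles = phase + 2 * math.pi * np.arange(k) / k
        radii = side * rng.uniform(0.12, 0.45, size=k)
    else:
        k = int(_HELDOUT_POINTS[rng.integers(len(_HELDOUT_POINTS))])
        angles = phase + 2 * math.pi * np.arange(2 * k) / (2 * k)
        outer = side * rng.uniform(0.34, 0.44)
        inner = outer * rng.uniform(0.35, 0.5)
        radii = np.where(np.arange(2 * k) % 2 == 0, outer, inner)
    return _fill_polygon(side, radii, angles, offset)


def generate_rotating_shape_set(
    n_sequences: int,
    frame_side: int = 16,
    n_steps: int = 8,
    angle_per_step: float = 45.0,
    shape_family: Literal["train", "heldout"] = "train",
    seed: int = 0,
) -> list[PatternSequence]:
    """Sequences of a base shape rotating by a fixed angle per step.

    Every sequence shares the same rotational dynamics: frame ``k`` is the
    base shape rotated by ``k * angle_per_step`` degrees (bilinear
    resampling, values clipped to [0, 1]).  The ``train`` family renders
    filled convex regular polygons and the ``heldout`` family filled
    concave star polygons, so the two families are disjoint shape classes
    for any seed: a model can only generalize to held-out shapes by
    learning the rotation itself.
    """
    _check_positive(n_sequences=n_sequences, frame_side=frame_side, n_steps=n_steps)
    if shape_family not in ("train", "heldout"):
        raise ValueError(f"unknown shape_family {shape_family!r}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sequences):
        base = _base_shape(shape_family, frame_side, rng)
        frames = np.empty((n_steps, frame_side * frame_side))
        for k in range(n_steps):
            if k == 0:
                rot = base
            else:
                rot = ndimage.rotate(base, k * angle_per_step, reshape=False, order=1)
            frames[k] = np.clip(rot, 0.0, 1.0).ravel()
        out.append(PatternSequence(frames, "image", frame_shape=(frame_side, frame_side)))
    return out
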