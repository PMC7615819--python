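"""Model and result persistence: portable ``.npz`` weight containers with a
JSON metadata sidecar (model kind, dimensions, nonlinearity, seed,
separation spec), so runs can be resumed or inspected without pickles."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hopfield import AHNModel, Separation
from .sequences import PatternSequence
from .tpc import TPCSingleLayer, TPCTwoLayer

__all__ = ["save_model", "load_model"]


def save_model(model, path: str | Path) -> Path:
    """Save a tPC or AHN model to ``<path>.npz`` + ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    if isinstance(model, TPCSingleLayer):
        meta = {
            "kind": "tpc_single",
            "n_features": model.n_features,
            "nonlinearity": model.nonlinearity,
            "lr_weights": model.lr_weights,
            "lr_inference": model.lr_inference,
            "n_inference_steps": model.n_inference_steps,
            "inference_tol": model.inference_tol,
        }
        arrays = {"W": model.W}
    elif isinstance(model, TPCTwoLayer):
        meta = {
            "kind": "tpc_two",
            "n_features": model.n_features,
            "hidden_dim": model.hidden_dim,
            "nonlinearity": model.nonlinearity,
            "lr_weights": model.lr_weights,
            "lr_inference": model.lr_inference,
            "n_inference_steps": model.n_inference_steps,
            "inference_tol": model.inference_tol,
            "hidden_init_scale": model.hidden_init_scale,
            "seed": model.seed,
        }
        arrays = {"W_H": model.W_H, "W_F": model.W_F}
    elif isinstance(model, AHNModel):
        meta = {
            "kind": "ahn",
            "n_features": model.n_features,
            "separation": {
                "kind": model.separation.kind,
                "degree": model.separation.degree,
                "beta": model.separation.beta,
            },
            "domain_tag": model.stored.domain_tag,
            "frame_shape": list(model.stored.frame_shape) if model.stored.frame_shape else None,
        }
        arrays = {"stored": model.stored.patterns}
        if model.W_AHN is not None:
            arrays["W_AHN"] = model.W_AHN
    else:
        raise TypeError(f"cannot persist model of type {type(model).__name__}")
    np.savez(base.with_suffix(".npz"), **arrays)
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return base.with_suffix(".npz")


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`."""
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    meta = json.loads(base.with_suffix(".json").read_text())
    arrays = np.load(base.with_suffix(".npz"))
    kind = meta.pop("kind")
    if kind == "tpc_single":
        return TPCSingleLayer(W=arrays["W"], **meta)
    if kind == "tpc_two":
        return TPCTwoLayer(W_H=arrays["W_H"], W_F=arrays["W_F"], **meta)
    if kind == "ahn":
        sep = Separation(meta["separation"]["kind"], meta["separation"]["degree"], meta["separation"]["beta"])
        frame_shape = tuple(meta["frame_shape"]) if meta["frame_shape"] else None
        stored = PatternSequence(arrays["stored"], meta["domain_tag"], frame_shape)
        W = arrays["W_AHN"] if "W_AHN" in arrays else None
        return AHNModel(stored=stored, separation=sep, W_AHN=W)
    raise ValueError(f"unknown model kind {kind!r}")
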