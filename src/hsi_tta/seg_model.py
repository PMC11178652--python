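"""Frozen pixel-wise segmentation models.

The augmentation method assumes a segmentation network trained on
well-perfused tissue and used strictly without fine-tuning. Here that
contract is filled by deliberately simple pixel-wise spectral classifiers:

* ``nearest_centroid`` (default): per-class mean of the L1-normalized
  training spectra; prediction assigns each pixel to the closest centroid.
* ``lda``: regularized linear discriminant analysis (lsqr solver, automatic
  shrinkage) from scikit-learn.

Both are pure functions of the input once trained, serialize losslessly to
HDF5, and expose the same adapter surface (``predict(model, cube)``) that an
external pretrained network could be plugged into.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DataError
from .spectral_db import HSICube

__all__ = ["FrozenModel", "train", "predict", "save_model", "load_model", "model_hash"]


@dataclass(frozen=True)
class FrozenModel:
    """Immutable pixel classifier: kind, ordered labels, fitted parameters."""

    kind: str
    class_labels: tuple[int, ...]
    weights: dict  # kind-specific arrays
    provenance: dict = field(default_factory=dict)
    frozen: bool = True

    def __post_init__(self):
        if self.kind not in ("nearest_centroid", "lda"):
            raise DataError(f"unknown model kind {self.kind!r}")


def _collect_pixels(scenes) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([s.cube.normalized_copy().flat() for s in scenes])
    y = np.concatenate([s.mask.ravel() for s in scenes])
    return X, y


def train(scenes, kind: str = "nearest_centroid", seed: int = 0) -> FrozenModel:
    """Fit a pixel-wise classifier on physiological scenes and freeze it.

    All scenes must be in the physiological state (the premise of the
    method is that the deployed network only ever saw healthy perfusion);
    every class in the scene masks must contribute at least one pixel.
    """
    scenes = list(scenes)
    if not scenes:
        raise DataError("no training scenes")
    for s in scenes:
        if s.state.name != "physiological":
            raise DataError(
                f"training scene {s.image_id!r} is {s.state.name}, "
                "but the frozen model must be trained on physiological tissue only"
            )
    X, y = _collect_pixels(scenes)
    labels = tuple(int(v) for v in np.unique(y))
    declared = set()
    for s in scenes:
        declared.update(int(v) for v in np.unique(s.mask))
    missing = declared - set(labels)
    if missing:
        raise DataError(f"classes {sorted(missing)} have no training pixels")

    if kind == "nearest_centroid":
        weights = {
            "centroids": np.stack([X[y == c].mean(axis=0) for c in labels])
        }
    elif kind == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X, y)
        weights = {
            "coef": clf.coef_,
            "intercept": clf.intercept_,
            "classes": clf.classes_.astype(np.int64),
        }
    else:
        raise DataError(f"unknown model kind {kind!r}")
    provenance = {
        "seed": int(seed),
        "kind": kind,
        "n_pixels": int(X.shape[0]),
        "scene_ids": [s.image_id for s in scenes],
    }
    return FrozenModel(kind, labels, weights, provenance)


def predict(model: FrozenModel, cube: HSICube) -> np.ndarray:
    """Per-pixel argmax labels; pure function of the (normalized) cube."""
    if not model.frozen:
        raise DataError("model is not frozen")
    cube = cube.normalized_copy()
    X = cube.flat()
    if model.kind == "nearest_centroid":
        C = model.weights["centroids"]
        if X.shape[1] != C.shape[1]:
            raise DataError(
                f"cube has {X.shape[1]} bands but model expects {C.shape[1]}"
            )
        d2 = (X**2).sum(1)[:, None] - 2.0 * X @ C.T + (C**2).sum(1)[None, :]
        lab = np.asarray(model.class_labels)[d2.argmin(axis=1)]
    else:
        coef, icpt = model.weights["coef"], model.weights["intercept"]
        if X.shape[1] != coef.shape[1]:
            raise DataError(
                f"cube has {X.shape[1]} bands but model expects {coef.shape[1]}"
            )
        scores = X @ coef.T + icpt
        if scores.ndim == 1 or scores.shape[1] == 1:
            lab = np.where(
                scores.ravel() > 0, model.weights["classes"][1], model.weights["classes"][0]
            )
        else:
            lab = model.weights["classes"][scores.argmax(axis=1)]
    return lab.reshape(cube.shape)


def save_model(model: FrozenModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = model.kind
        f.attrs["class_labels"] = list(model.class_labels)
        f.attrs["provenance"] = json.dumps(model.provenance)
        for k, v in model.weights.items():
            f.create_dataset(f"weights/{k}", data=v)


def load_model(path) -> FrozenModel:
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        labels = tuple(int(v) for v in f.attrs["class_labels"])
        provenance = json.loads(f.attrs["provenance"])
        weights = {k: f[f"weights/{k}"][...] for k in f["weights"]}
    return FrozenModel(kind, labels, weights, provenance)


def model_hash(model: FrozenModel) -> str:
    """SHA-256 over kind, labels and weight bytes; constant across a pipeline run."""
    h = hashlib.sha256()
    h.update(model.kind.encode())
    h.update(np.asarray(model.class_labels).tobytes())
    for k in sorted(model.weights):
        h.update(k.encode())
        h.update(np.ascontiguousarray(model.weights[k]).tobytes())
    return h.hexdigest()
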