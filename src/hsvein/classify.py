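"""Per-pixel vein classification with a linear-kernel SVM.

Training data is assembled by flattening each reduced training image
row-major and stacking the images vertically; labels come from the paired
ground-truth masks.  Features are z-scored with statistics learned from the
training stack (a linear SVM is scale-sensitive), and a soft-margin linear
SVM with balanced class weights is fitted — vein pixels are a minority class
and unweighted hinge loss tends toward the trivial all-skin solution.

The fitted :class:`VeinClassifier` keeps only the standardization vectors and
the decision hyperplane (w, b), so models serialize to plain JSON and predict
without sklearn solver state.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

from .dimred import ReducedCube

__all__ = [
    "TrainingSet",
    "VeinClassifier",
    "split_dataset",
    "assemble_training",
    "train_svm",
    "predict_mask",
    "save_classifier",
    "load_classifier",
]


@dataclass
class TrainingSet:
    """Stacked pixel features with labels and training standardization."""

    features: np.ndarray  # (n_pixels, k)
    labels: np.ndarray  # (n_pixels,) in {0, 1}
    feature_mean: np.ndarray  # (k,)
    feature_scale: np.ndarray  # (k,), zero-variance features get scale 1


def split_dataset(image_ids: list, train_fraction: float, seed: int) -> tuple[list, list]:
    """Image-level random split: round(fraction * N) train, rest test.

    Deterministic per seed; partitions are disjoint and exhaustive.  A
    fraction leaving either side empty is a configuration error.
    """
    ids = list(image_ids)
    if len(ids) < 2:
        raise ValueError("need at least two images to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = round(train_fraction * len(ids))
    if n_train == 0 or n_train == len(ids):
        raise ValueError(
            f"fraction {train_fraction} leaves an empty partition for {len(ids)} images"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def assemble_training(reduced_cubes: list[ReducedCube], masks: list[np.ndarray]) -> TrainingSet:
    """Vertically concatenate reduced training images into one pixel matrix.

    Each image is flattened row-major to (rows*cols) x k; images stack in the
    given order, with labels taken from the paired masks.  Standardization
    statistics (per-feature mean and standard deviation) are computed over
    the full stack.
    """
    if len(reduced_cubes) != len(masks) or not reduced_cubes:
        raise ValueError("need equal, non-zero numbers of cubes and masks")
    blocks, label_blocks = [], []
    k = reduced_cubes[0].n_features
    for cube, mask in zip(reduced_cubes, masks):
        mask = np.asarray(mask)
        if mask.shape != (cube.rows, cube.cols):
            raise ValueError(f"mask shape {mask.shape} does not match cube {cube.rows}x{cube.cols}")
        if cube.n_features != k:
            raise ValueError("all reduced cubes must share the same feature count")
        blocks.append(cube.pixels())
        label_blocks.append(mask.reshape(-1))
    features = np.vstack(blocks)
    labels = np.concatenate(label_blocks).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale[scale == 0] = 1.0
    return TrainingSet(features=features, labels=labels, feature_mean=mean, feature_scale=scale)


class VeinClassifier(ClassifierMixin, BaseEstimator):
    """Linear-kernel SVM pixel classifier with built-in standardization.

    Parameters
    ----------
    C : float
        Soft-margin penalty.
    class_weight : "balanced" or None
        Balanced reweighting counteracts the skin/vein class imbalance.
    tol : float
        Solver tolerance (fixed for reproducibility).
    max_iter : int
    random_state : int

    Attributes
    ----------
    coef_ : ndarray (k,)        hyperplane normal in standardized space
    intercept_ : float
    mean_, scale_ : ndarray (k,) standardization vectors
    """

    def __init__(
        self,
        C: float = 1.0,
        class_weight: str | None = "balanced",
        tol: float = 1e-4,
        max_iter: int = 10000,
        random_state: int = 0,
    ):
        self.C = C
        self.class_weight = class_weight
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        Xs = (X - self.mean_) / self.scale_
        svc = LinearSVC(
            C=self.C,
            class_weight=self.class_weight,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        svc.fit(Xs, y)
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got shape {X.shape}")
        return ((X - self.mean_) / self.scale_) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_svm(
    ts: TrainingSet,
    C: float = 1.0,
    class_weight: str | None = "balanced",
    tol: float = 1e-4,
    seed: int = 0,
) -> VeinClassifier:
    """Fit a :class:`VeinClassifier` on an assembled training set."""
    return VeinClassifier(
        C=C, class_weight=class_weight, tol=tol, random_state=seed
    ).fit(ts.features, ts.labels)


def predict_mask(model: VeinClassifier, reduced: ReducedCube) -> np.ndarray:
    """Predict a {0,1} vein mask for a reduced cube, pixel by pixel."""
    if reduced.n_features != model.n_features_in_:
        raise ValueError(
            f"cube has {reduced.n_features} features but model expects {model.n_features_in_}"
        )
    labels = model.predict(reduced.pixels())
    return labels.reshape(reduced.rows, reduced.cols).astype(np.uint8)


def save_classifier(model: VeinClassifier, path: str | os.PathLike, provenance: dict | None = None) -> None:
    """Serialize a fitted classifier (standardization + hyperplane) to JSON."""
    payload = {
        "params": model.get_params(),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "coef": model.coef_.tolist(),
        "intercept": model.intercept_,
        "n_features_in": int(model.n_features_in_),
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_classifier(path: str | os.PathLike) -> VeinClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    model = VeinClassifier(**payload["params"])
    model.mean_ = np.array(payload["mean"])
    model.scale_ = np.array(payload["scale"])
    model.coef_ = np.array(payload["coef"])
    model.intercept_ = float(payload["intercept"])
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = payload["n_features_in"]
    model.provenance = payload.get("provenance", {})
    return model
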