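"""Confusion-matrix evaluation and the band-count optimisation sweep.

The positive class is vein (1).  Rates are percentages:

    accuracy  = 100 (TP + TN) / (TP + FP + FN + TN)
    precision = 100 TP / (TP + FP)
    recall    = 100 TP / (TP + FN)
    FPR       = 100 FP / (FP + TN)
    FNR       = 100 FN / (TP + FN)        (so recall + FNR = 100 exactly)

Undefined ratios (zero denominator) are reported as NaN with a warning —
silent zeros would corrupt sweep curves on degenerate predictions.

The sweep refits the chosen reducer and the SVM for every candidate feature
count k, predicts every test image, pools the confusion counts over all test
pixels (micro-averaging) and picks the smallest k attaining the maximal
accuracy.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classify import assemble_training, predict_mask, train_svm
from .dimred import FoldedPCA, SpectralPCA, WaLuMIBandSelector, reduce_cube
from .envi import Hypercube

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SweepResult",
    "confusion",
    "metrics",
    "band_sweep",
    "default_band_grid",
    "make_reducer",
    "report",
]

METRIC_COLUMNS = ["Accuracy (%)", "Precision (%)", "Recall (%)", "FPR (%)", "FNR (%)"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel counts with vein = positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricsReport:
    """The five derived rates, as percentages in [0, 100] (NaN if undefined)."""

    accuracy: float
    precision: float
    recall: float
    fpr: float
    fnr: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Count TP/FP/FN/TN between a predicted and a ground-truth {0,1} mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", RuntimeWarning)
        return float("nan")
    return 100.0 * num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the five percentage rates from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        recall=_ratio(cm.tp, cm.tp + cm.fn, "recall"),
        fpr=_ratio(cm.fp, cm.fp + cm.tn, "FPR"),
        fnr=_ratio(cm.fn, cm.tp + cm.fn, "FNR"),
    )


def make_reducer(method: str, k: int, fold_height: int = 1, fold_width: int | None = None, bins: int = 64):
    """Instantiate the reducer named by ``method`` ("pca"/"fpca"/"walumi")."""
    if method == "pca":
        return SpectralPCA(n_components=k)
    if method == "fpca":
        return FoldedPCA(n_components=k, fold_height=fold_height, fold_width=fold_width)
    if method == "walumi":
        return WaLuMIBandSelector(n_bands=k, bins=bins)
    raise ValueError(f"unknown method {method!r}")


def default_band_grid(bands: int) -> list[int]:
    """The sweep grid 10, 20, ... in steps of 10, closed with the full band count."""
    ks = list(range(10, bands, 10))
    if not ks or ks[-1] != bands:
        ks.append(bands)
    return ks


@dataclass(frozen=True)
class SweepResult:
    """Accuracy-vs-k curve with its optimum (smallest k attaining the max)."""

    entries: tuple[tuple[int, float], ...]
    best_k: int = field(init=False)
    best_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("sweep produced no entries")
        ordered = tuple(sorted(self.entries))
        object.__setattr__(self, "entries", ordered)
        best_acc = max(acc for _k, acc in ordered)
        best_k = min(k for k, acc in ordered if acc == best_acc)
        object.__setattr__(self, "best_k", best_k)
        object.__setattr__(self, "best_accuracy", best_acc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["k", "accuracy"])


def evaluate_method(
    train_cubes: list[Hypercube],
    train_masks: list[np.ndarray],
    test_cubes: list[Hypercube],
    test_masks: list[np.ndarray],
    reducer,
    svm_params: dict | None = None,
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Fit reducer on train pixels, train the SVM, micro-average over test pixels."""
    svm_params = svm_params or {}
    train_pixels = np.vstack([c.data.reshape(-1, c.bands) for c in train_cubes])
    reducer.fit(train_pixels)
    reduced_train = [reduce_cube(c, reducer) for c in train_cubes]
    ts = assemble_training(reduced_train, train_masks)
    model = train_svm(ts, **svm_params)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for cube, mask in zip(test_cubes, test_masks):
        pred = predict_mask(model, reduce_cube(cube, reducer))
        pooled = pooled + confusion(pred, mask)
    return pooled, metrics(pooled)


def band_sweep(
    train_cubes: list[Hypercube],
    train_masks: list[np.ndarray],
    test_cubes: list[Hypercube],
    test_masks: list[np.ndarray],
    method: str,
    ks: list[int],
    svm_params: dict | None = None,
    fold_height: int = 1,
    fold_width: int | None = None,
    bins: int = 64,
) -> SweepResult:
    """Accuracy as a function of the retained feature count k.

    For each k the reducer is refitted on the training pixels only, the SVM
    retrained, and accuracy micro-averaged over all test pixels.
    """
    if not ks:
        raise ValueError("ks must be non-empty")
    entries = []
    for k in ks:
        try:
            reducer = make_reducer(method, k, fold_height=fold_height, fold_width=fold_width, bins=bins)
            _cm, rep = evaluate_method(
                train_cubes, train_masks, test_cubes, test_masks, reducer, svm_params
            )
        except Exception as exc:
            raise RuntimeError(f"sweep failed at k={k}: {exc}") from exc
        entries.append((int(k), rep.accuracy))
    return SweepResult(entries=tuple(entries))


def report(results: list[tuple[str, MetricsReport]], path: str | os.PathLike | None = None, provenance: dict | None = None) -> pd.DataFrame:
    """Render per-method metric rows in the standard column order.

    Writes CSV or JSON depending on the path suffix; returns the DataFrame.
    """
    if not results:
        raise ValueError("no results to report")
    rows = []
    for name, rep in results:
        rows.append(
            {
                "Method": name,
                "Accuracy (%)": round(rep.accuracy, 2),
                "Precision (%)": round(rep.precision, 2),
                "Recall (%)": round(rep.recall, 2),
                "FPR (%)": round(rep.fpr, 2),
                "FNR (%)": round(rep.fnr, 2),
                **(provenance or {}),
            }
        )
    frame = pd.DataFrame(rows, columns=["Method", *METRIC_COLUMNS, *(provenance or {})])
    if path is not None:
        suffix = os.path.splitext(os.fspath(path))[1].lower()
        if suffix == ".json":
            frame.to_json(path, orient="records", indent=2)
        else:
            frame.to_csv(path, index=False)
    return frame
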