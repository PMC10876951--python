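"""Spectral indices, leaf-on median composites, before/after delta stacks,
and the binary damage classifier with its single-pixel noise filter."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .raster_core import Grid, remove_single_pixels

__all__ = [
    "IndexStack",
    "DamageMask",
    "nbr",
    "ndvi",
    "tasseled_cap",
    "median_composite",
    "delta_composite",
    "train_damage_classifier",
    "predict_damage",
    "TCT_REFLECTANCE_COEFFS",
]

# Classical 6-band reflectance coefficients (brightness, greenness, wetness)
# for [blue, green, red, NIR, SWIR1, SWIR2]; overridable per call.
TCT_REFLECTANCE_COEFFS = np.array(
    [
        [0.3037, 0.2793, 0.4743, 0.5585, 0.5082, 0.1863],
        [-0.2848, -0.2435, -0.5436, 0.7243, 0.0840, -0.1800],
        [0.1509, 0.1973, 0.3279, 0.3406, -0.7112, -0.4572],
    ]
)


@dataclass
class IndexStack:
    """Per-epoch stacks of spectral-index layers sharing one geometry.

    ``layers`` maps layer name (e.g. ``"nbr"``) to an array of shape
    ``(n_epochs, rows, cols)``; ``epochs`` labels the leading axis. NaN is
    the in-stack nodata.
    """

    layers: dict[str, np.ndarray]
    epochs: list
    grid: Grid

    def __post_init__(self):
        if not self.layers:
            raise ValueError("IndexStack needs at least one layer")
        n = len(self.epochs)
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[0] != n or arr.shape[1:] != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} must have shape (n_epochs, rows, cols)"
                )
            self.layers[name] = arr
        for name in ("nbr", "ndvi"):
            if name in self.layers:
                vals = self.layers[name]
                finite = vals[np.isfinite(vals)]
                if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                    raise ValueError(f"{name} values must lie in [-1, 1]")

    @property
    def layer_names(self) -> list[str]:
        return sorted(self.layers)

    def epoch(self, label) -> "IndexStack":
        """Single-epoch view of one labeled epoch."""
        i = self.epochs.index(label)
        return IndexStack(
            {k: v[i : i + 1] for k, v in self.layers.items()}, [label], self.grid
        )

    def pixel_matrix(self) -> np.ndarray:
        """(n_pixels, n_layers * n_epochs) feature matrix, layers sorted."""
        mats = [
            self.layers[name].reshape(len(self.epochs), -1).T
            for name in self.layer_names
        ]
        return np.concatenate(mats, axis=1)


@dataclass
class DamageMask:
    """Binary 2022-damage mask restricted to the pre-war forest mask."""

    mask: Grid
    classifier_id: str = ""
    threshold: float = 0.5


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out = np.where(denom == 0, np.nan, out)
    return np.clip(out, -1.0, 1.0)


def nbr(nir, swir2) -> np.ndarray:
    """Normalized Burn Ratio ``(NIR - SWIR2)/(NIR + SWIR2)``, clamped to [-1, 1].

    Emits NaN where both bands are zero.
    """
    return _normalized_difference(nir, swir2)


def ndvi(nir, red) -> np.ndarray:
    """Normalized Difference Vegetation Index, clamped to [-1, 1]."""
    return _normalized_difference(nir, red)


def tasseled_cap(
    bands: np.ndarray, coeffs: np.ndarray = TCT_REFLECTANCE_COEFFS
) -> dict[str, np.ndarray]:
    """Brightness/greenness/wetness from a 6-band reflectance stack.

    ``bands`` has shape (6, ...); returns a dict of three arrays matching the
    trailing shape.
    """
    bands = np.asarray(bands, dtype=float)
    if bands.shape[0] != coeffs.shape[1]:
        raise ValueError("band count must match coefficient columns")
    out = np.tensordot(coeffs, bands, axes=(1, 0))
    return {"tcb": out[0], "tcg": out[1], "tcw": out[2]}


def median_composite(stack: IndexStack, epoch_window: Optional[tuple] = None) -> IndexStack:
    """Per-pixel, per-layer median over the scenes inside the window.

    NaN (nodata) scenes are excluded per pixel; pixels with no valid scene
    stay NaN. ``epoch_window=(lo, hi)`` selects epochs inclusively; ``None``
    uses all epochs.
    """
    if epoch_window is None:
        sel = list(range(len(stack.epochs)))
    else:
        lo, hi = epoch_window
        sel = [i for i, e in enumerate(stack.epochs) if lo <= e <= hi]
    if not sel:
        raise ValueError("empty epoch window")
    out = {}
    with np.errstate(all="ignore"):
        for name, arr in stack.layers.items():
            out[name] = np.nanmedian(arr[sel], axis=0)[None]
    label = stack.epochs[sel[0]] if len(sel) == 1 else (stack.epochs[sel[0]], stack.epochs[sel[-1]])
    return IndexStack(out, [label], stack.grid)


def delta_composite(before: IndexStack, after: IndexStack) -> IndexStack:
    """Per-layer, per-pixel ``after - before``; NaN propagates."""
    if before.grid.shape != after.grid.shape or set(before.layers) != set(after.layers):
        raise ValueError("before/after stacks must share geometry and layers")
    if len(before.epochs) != 1 or len(after.epochs) != 1:
        raise ValueError("delta_composite expects single-epoch composites")
    out = {
        name: after.layers[name] - before.layers[name] for name in before.layers
    }
    return IndexStack(out, [("delta", before.epochs[0], after.epochs[0])], before.grid)


def _sample_features(deltas: IndexStack, rows, cols) -> np.ndarray:
    feats = deltas.pixel_matrix()
    idx = np.asarray(rows) * deltas.grid.shape[1] + np.asarray(cols)
    return feats[idx]


def train_damage_classifier(
    deltas: IndexStack,
    labels: pd.DataFrame,
    seed: int,
    n_estimators: int = 500,
) -> tuple[RandomForestClassifier, dict]:
    """Fit the seeded ensemble on delta features at labeled pixels.

    ``labels`` needs columns row, col, label and split ("train"/"val").
    Works unchanged for the multiclass land-cover case. The report carries
    overall accuracy plus per-class user's and producer's accuracy on the
    held-out split.
    """
    train = labels[labels["split"] == "train"]
    val = labels[labels["split"] == "val"]
    if train["label"].nunique() < 2:
        raise ValueError("training set must contain at least two classes")
    overlap = set(map(tuple, train[["row", "col"]].values)) & set(
        map(tuple, val[["row", "col"]].values)
    )
    if overlap:
        raise ValueError("train and validation pixels overlap")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(_sample_features(deltas, train["row"], train["col"]), train["label"])
    report: dict = {"n_train": len(train), "n_val": len(val)}
    if len(val):
        pred = clf.predict(_sample_features(deltas, val["row"], val["col"]))
        truth = val["label"].to_numpy()
        report["overall_accuracy"] = float(np.mean(pred == truth))
        per_class = {}
        for cls in np.unique(np.concatenate([truth, pred])):
            predicted = pred == cls
            actual = truth == cls
            per_class[str(cls)] = {
                "users_accuracy": float(
                    (predicted & actual).sum() / predicted.sum()
                )
                if predicted.any()
                else float("nan"),
                "producers_accuracy": float(
                    (predicted & actual).sum() / actual.sum()
                )
                if actual.any()
                else float("nan"),
            }
        report["per_class"] = per_class
    return clf, report


def predict_damage(
    classifier: RandomForestClassifier,
    deltas: IndexStack,
    forest_mask: Grid,
    threshold: float = 0.5,
    connectivity: int = 8,
) -> DamageMask:
    """Classify per-pixel damage, keep forest pixels only, drop single pixels.

    Positive class is ``1``; the decision threshold applies to its predicted
    probability.
    """
    if not hasattr(classifier, "classes_"):
        raise ValueError("classifier is not fitted")
    if forest_mask.shape != deltas.grid.shape:
        raise ValueError("forest mask geometry mismatch")
    feats = deltas.pixel_matrix()
    valid = np.all(np.isfinite(feats), axis=1)
    positive = np.zeros(feats.shape[0], dtype=bool)
    if valid.any():
        proba = classifier.predict_proba(feats[valid])
        pos_col = list(classifier.classes_).index(1)
        positive[valid] = proba[:, pos_col] >= threshold
    mask = positive.reshape(deltas.grid.shape) & (forest_mask.values == 1)
    grid = deltas.grid.like(mask.astype(np.uint8), nodata=255)
    filtered = remove_single_pixels(grid, connectivity=connectivity)
    return DamageMask(
        mask=filtered,
        classifier_id=f"rf{getattr(classifier, 'n_estimators', '?')}-seed{getattr(classifier, 'random_state', '?')}",
        threshold=threshold,
    )
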