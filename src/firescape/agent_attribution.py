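"""Per-patch disturbance features and causal-agent classification.

Disturbance patches are connected pixels sharing one disturbance year
(8-connectivity by default). Each patch gets spectral-magnitude means,
pre-disturbance NBR, duration, rate, area and fractal shape index, and is
attributed to stand-replacing fire (SRF), stand-replacing harvest (SRH) or
a non-stand-replacing agent (NSR) by a seeded ensemble validated on a
stratified holdout.

Sign conventions: ``d_nbr`` and ``d_ndvi`` are decreases (pre minus post,
positive for disturbance); the tasseled-cap deltas ``d_tcb``/``d_tcg``/
``d_tcw`` are signed changes (post minus pre), so fresh clear-cuts carry a
positive brightness delta while burns go darker.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .raster_core import Grid, fractal_index, label_patches

__all__ = [
    "AGENTS",
    "FEATURE_COLUMNS",
    "NSR_MAX_DNBR",
    "compute_patch_features",
    "train_agent_classifier",
    "classify_agents",
    "disturbance_time_series",
]

AGENTS = ("SRF", "SRH", "NSR")

#: NSR training exemplars must have NBR magnitude strictly below this
NSR_MAX_DNBR = 0.25

FEATURE_COLUMNS = [
    "d_nbr",
    "d_ndvi",
    "d_tcb",
    "d_tcg",
    "d_tcw",
    "pre_nbr",
    "duration",
    "rate",
    "area_ha",
    "frac",
]

_SPECTRAL = ["d_nbr", "d_ndvi", "d_tcb", "d_tcg", "d_tcw", "pre_nbr"]


def compute_patch_features(
    year_grid: Grid,
    pixel_layers: dict[str, np.ndarray],
    connectivity: int = 8,
    stat: str = "mean",
) -> pd.DataFrame:
    """One feature row per same-year disturbance patch.

    Parameters
    ----------
    year_grid : Grid
        Per-pixel disturbance year; 0 / nodata = undisturbed.
    pixel_layers : dict
        Per-pixel arrays for ``d_nbr, d_ndvi, d_tcb, d_tcg, d_tcw, pre_nbr,
        duration``, each matching the grid shape.
    stat : {"mean", "median"}
        Patch summary statistic for the spectral layers.

    Rows touching NaN in any required layer are flagged ``complete=False``.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    required = set(_SPECTRAL) | {"duration"}
    missing = required - set(pixel_layers)
    if missing:
        raise ValueError(f"missing pixel layers: {sorted(missing)}")
    for name, arr in pixel_layers.items():
        if np.asarray(arr).shape != year_grid.shape:
            raise ValueError(f"layer {name!r} shape mismatch")
    agg = np.nanmean if stat == "mean" else np.nanmedian
    years = np.unique(year_grid.values)
    years = years[(years != 0) & (years != year_grid.nodata)]
    rows = []
    for year in years:
        for patch in label_patches(year_grid, int(year), connectivity=connectivity):
            rr = np.array([p[0] for p in patch.pixels])
            cc = np.array([p[1] for p in patch.pixels])
            row: dict = {
                "patch_id": f"{int(year)}_{patch.id}",
                "year": int(year),
                "n_pixels": len(patch.pixels),
                "area_ha": patch.area_ha,
                "frac": fractal_index(patch),
            }
            complete = True
            for name in _SPECTRAL:
                vals = np.asarray(pixel_layers[name], dtype=float)[rr, cc]
                if np.isnan(vals).any():
                    complete = False
                row[name] = float(agg(vals)) if np.isfinite(vals).any() else np.nan
            dur = np.asarray(pixel_layers["duration"], dtype=float)[rr, cc]
            if np.isnan(dur).any():
                complete = False
            dur_val = float(np.round(agg(dur))) if np.isfinite(dur).any() else np.nan
            row["duration"] = dur_val
            row["rate"] = row["d_nbr"] / dur_val if dur_val and np.isfinite(dur_val) else np.nan
            row["complete"] = complete
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["patch_id", "year", "n_pixels", "complete"] + FEATURE_COLUMNS,
    )


def train_agent_classifier(
    features: pd.DataFrame,
    labels: Sequence[str],
    holdout_fraction: float = 0.2,
    seed: int = 0,
    n_estimators: int = 500,
    enforce_nsr_rule: bool = True,
) -> tuple[RandomForestClassifier, dict]:
    """Fit the agent classifier with a per-class stratified holdout.

    Returns the fitted model and a validation report with the 3x3 confusion
    matrix (rows = reference, columns = predicted), overall accuracy and
    per-class user's/producer's accuracies on the holdout.
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels and features must align")
    present = set(np.unique(labels))
    if not set(AGENTS) <= present:
        raise ValueError(f"all agent classes required, got {sorted(present)}")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 exemplars")
    if enforce_nsr_rule:
        nsr_dnbr = features.loc[labels == "NSR", "d_nbr"]
        if (nsr_dnbr >= NSR_MAX_DNBR).any():
            raise ValueError(
                f"NSR training exemplars must have d_nbr < {NSR_MAX_DNBR}"
            )
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X,
        labels,
        test_size=holdout_fraction,
        random_state=seed,
        stratify=labels,
    )
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_val)
    cm = pd.DataFrame(0, index=list(AGENTS), columns=list(AGENTS))
    for truth, p in zip(y_val, pred):
        cm.loc[truth, p] += 1
    per_class = {}
    for agent in AGENTS:
        ref = int(cm.loc[agent].sum())
        mapped = int(cm[agent].sum())
        correct = int(cm.loc[agent, agent])
        per_class[agent] = {
            "producers_accuracy": correct / ref if ref else float("nan"),
            "users_accuracy": correct / mapped if mapped else float("nan"),
        }
    report = {
        "confusion_matrix": cm,
        "overall_accuracy": float(np.mean(pred == y_val)),
        "per_class": per_class,
        "n_train": len(y_tr),
        "n_holdout": len(y_val),
    }
    return model, report


def classify_agents(
    model: RandomForestClassifier, features: pd.DataFrame
) -> list[str]:
    """Label each patch; incomplete feature rows get ``"unknown"``."""
    if not hasattr(model, "classes_"):
        raise ValueError("model is not fitted")
    if features.empty:
        return []
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch, missing {missing}")
    complete = (
        features["complete"].to_numpy(dtype=bool)
        if "complete" in features.columns
        else np.ones(len(features), dtype=bool)
    )
    complete &= np.all(
        np.isfinite(features[FEATURE_COLUMNS].to_numpy(dtype=float)), axis=1
    )
    out = np.array(["unknown"] * len(features), dtype=object)
    if complete.any():
        out[complete] = model.predict(
            features.loc[complete, FEATURE_COLUMNS].to_numpy(dtype=float)
        )
    return out.tolist()


def disturbance_time_series(
    labels: Sequence[str], patches: pd.DataFrame
) -> pd.DataFrame:
    """Annual disturbed area (ha) per agent; total area is conserved.

    ``unknown`` labels are reported in their own column, excluded from the
    agent columns.
    """
    labels = np.asarray(labels)
    if len(labels) != len(patches):
        raise ValueError("labels and patches must align")
    df = patches[["year", "area_ha"]].copy()
    df["agent"] = labels
    table = (
        df.pivot_table(
            index="year", columns="agent", values="area_ha", aggfunc="sum", fill_value=0.0
        )
        .sort_index()
    )
    for agent in AGENTS:
        if agent not in table.columns:
            table[agent] = 0.0
    ordered = [a for a in AGENTS if a in table.columns]
    extras = [c for c in table.columns if c not in AGENTS]
    return table[ordered + extras]
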