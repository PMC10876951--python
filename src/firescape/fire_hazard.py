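"""Elevated-fire-hazard analysis by land-cover adjacency.

Land cover is reclassified into fire-supporting vs fire-inhibiting groups;
supporting patches below 1 ha are discarded; each damaged forest patch gets
its minimum Euclidean edge distance to the nearest surviving supporting
patch and is flagged elevated when that distance is within the adjacency
cutoff. Proportions of elevated damage are summarized for patches above
0.09 ha and above 1 ha, both as patch-count and patch-area shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landcover as lc
from .raster_core import Grid, label_patches

__all__ = [
    "HazardConfig",
    "HazardAssessment",
    "classify_fire_support",
    "assess_hazard",
    "hazard_report",
    "DEFAULT_SUPPORTING",
    "DEFAULT_INHIBITING",
]

DEFAULT_SUPPORTING = frozenset(
    {lc.CROPLAND, lc.GRASSLAND, lc.WOODLAND, lc.BURNED_FOREST}
)
DEFAULT_INHIBITING = frozenset(
    {lc.BARE_SOIL, lc.BUILT_UP, lc.WATER, lc.WETLAND, lc.FOREST}
)


@dataclass(frozen=True)
class HazardConfig:
    supporting_classes: frozenset = DEFAULT_SUPPORTING
    inhibiting_classes: frozenset = DEFAULT_INHIBITING
    min_supporting_patch_ha: float = 1.0
    damaged_patch_thresholds_ha: tuple[float, ...] = (0.09, 1.0)
    adjacency_distance_m: float = 30.0
    connectivity: int = 8

    def __post_init__(self):
        if self.supporting_classes & self.inhibiting_classes:
            raise ValueError("supporting and inhibiting classes overlap")
        covered = self.supporting_classes | self.inhibiting_classes
        if not lc.ALL_CLASSES <= covered:
            missing = sorted(lc.ALL_CLASSES - covered)
            raise ValueError(f"classes in neither group: {missing}")
        if self.adjacency_distance_m < 0 or self.min_supporting_patch_ha < 0:
            raise ValueError("distances and areas must be non-negative")


@dataclass
class HazardAssessment:
    """Per-patch flags plus elevated-share summaries at each threshold."""

    patches: pd.DataFrame  # id, area_ha, min_edge_distance_m, elevated
    summary: dict  # threshold -> {count_share, area_share, n_patches} | None
    config: HazardConfig


def classify_fire_support(
    landcover_grid: Grid, damaged_mask: Grid, config: HazardConfig = HazardConfig()
) -> Grid:
    """Binary fire-supporting (1) vs fire-inhibiting (0) raster.

    Damaged forest pixels are the analysis subject, not a neighbor, and are
    set to nodata; so are nodata land-cover cells.
    """
    vals = landcover_grid.values
    present = set(np.unique(vals).tolist()) - {landcover_grid.nodata}
    unknown = present - set(config.supporting_classes) - set(config.inhibiting_classes)
    if unknown:
        raise ValueError(f"land-cover codes in neither group: {sorted(unknown)}")
    out = np.full(vals.shape, 255, dtype=np.uint8)
    out[np.isin(vals, list(config.inhibiting_classes))] = 0
    out[np.isin(vals, list(config.supporting_classes))] = 1
    out[damaged_mask.values == 1] = 255
    return landcover_grid.like(out, nodata=255)


def assess_hazard(
    damaged_mask: Grid,
    support: Grid,
    config: HazardConfig = HazardConfig(),
) -> HazardAssessment:
    """Flag damaged patches adjacent to a qualifying supporting patch.

    Supporting patches smaller than ``min_supporting_patch_ha`` are removed
    before the distance computation. Distances are Euclidean, pixel-center
    to pixel-center, between patch edges (the minimum over all pixel pairs).
    """
    if not damaged_mask.same_geometry(support):
        raise ValueError("damaged mask and support raster geometry mismatch")
    support_patches = label_patches(support, 1, connectivity=config.connectivity)
    qualifying = np.zeros(support.shape, dtype=bool)
    for patch in support_patches:
        if patch.area_ha >= config.min_supporting_patch_ha:
            rr = [p[0] for p in patch.pixels]
            cc = [p[1] for p in patch.pixels]
            qualifying[rr, cc] = True
    if qualifying.any():
        dist = ndimage.distance_transform_edt(
            ~qualifying, sampling=damaged_mask.resolution_m
        )
    else:
        dist = np.full(support.shape, np.inf)
    damaged_patches = label_patches(damaged_mask, 1, connectivity=config.connectivity)
    rows = []
    for patch in damaged_patches:
        rr = [p[0] for p in patch.pixels]
        cc = [p[1] for p in patch.pixels]
        d = float(np.min(dist[rr, cc]))
        rows.append(
            {
                "id": patch.id,
                "area_ha": patch.area_ha,
                "min_edge_distance_m": d,
                "elevated": d <= config.adjacency_distance_m,
            }
        )
    patches = pd.DataFrame(
        rows, columns=["id", "area_ha", "min_edge_distance_m", "elevated"]
    )
    summary = {
        thr: _share(patches, thr) for thr in config.damaged_patch_thresholds_ha
    }
    return HazardAssessment(patches=patches, summary=summary, config=config)


def _share(patches: pd.DataFrame, threshold_ha: float) -> Optional[dict]:
    sel = patches[patches["area_ha"] >= threshold_ha]
    if sel.empty:
        return None  # proportions undefined
    elevated = sel[sel["elevated"]]
    return {
        "n_patches": int(len(sel)),
        "count_share": float(len(elevated) / len(sel)),
        "area_share": float(elevated["area_ha"].sum() / sel["area_ha"].sum()),
    }


def hazard_report(assessments: dict[str, HazardAssessment]) -> pd.DataFrame:
    """Per-AOI elevated-hazard proportions at every threshold, CSV-ready."""
    if not assessments:
        raise ValueError("need at least one assessment")
    rows = []
    for aoi, assessment in assessments.items():
        for threshold, share in assessment.summary.items():
            rows.append(
                {
                    "aoi": aoi,
                    "threshold_ha": threshold,
                    "n_patches": share["n_patches"] if share else 0,
                    "elevated_count_share": share["count_share"] if share else np.nan,
                    "elevated_area_share": share["area_share"] if share else np.nan,
                    "defined": share is not None,
                }
            )
    return pd.DataFrame(rows)
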