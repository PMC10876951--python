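"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is deliberately naive: flood fills over Python sets,
all-pairs distance minima, per-edge perimeter counts. Nothing imports the
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGHBORS_8 = NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean mask by flood fill."""
    offsets = NEIGHBORS_4 if connectivity == 4 else NEIGHBORS_8
    seen = set()
    comps = []
    nrows, ncols = mask.shape
    for r in range(nrows):
        for c in range(ncols):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = set()
            stack = [(r, c)]
            while stack:
                rr, cc = stack.pop()
                if (rr, cc) in comp:
                    continue
                comp.add((rr, cc))
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < nrows and 0 <= nc < ncols and mask[nr, nc]:
                        if (nr, nc) not in comp:
                            stack.append((nr, nc))
            seen |= comp
            comps.append(comp)
    return comps


def perimeter_m(pixels: set, resolution_m: float) -> float:
    """Count exposed 4-neighbor edges of a pixel set."""
    exposed = 0
    for r, c in pixels:
        for dr, dc in NEIGHBORS_4:
            if (r + dr, c + dc) not in pixels:
                exposed += 1
    return exposed * resolution_m


def fractal_from_pixels(pixels: set, resolution_m: float) -> float:
    p = perimeter_m(pixels, resolution_m)
    a = len(pixels) * resolution_m**2
    return 2.0 * math.log(0.25 * p) / math.log(a)


def all_pairs_distance(mask: np.ndarray, resolution_m: float) -> np.ndarray:
    """Per-pixel min center-to-center distance to any True pixel."""
    targets = np.argwhere(mask)
    nrows, ncols = mask.shape
    out = np.full((nrows, ncols), np.inf)
    for r in range(nrows):
        for c in range(ncols):
            d2 = (targets[:, 0] - r) ** 2 + (targets[:, 1] - c) ** 2
            out[r, c] = math.sqrt(d2.min()) * resolution_m
    return out


def min_set_distance(a: set, b: set, resolution_m: float) -> float:
    best = math.inf
    for r1, c1 in a:
        for r2, c2 in b:
            d = math.hypot(r1 - r2, c1 - c2)
            if d < best:
                best = d
    return best * resolution_m


def hazard_flags(
    damaged: np.ndarray,
    support: np.ndarray,
    resolution_m: float,
    min_supporting_patch_ha: float,
    adjacency_distance_m: float,
    connectivity: int = 8,
) -> list[dict]:
    """Per-damaged-patch elevated flags by exhaustive pair enumeration."""
    px_ha = resolution_m**2 / 10_000.0
    support_patches = [
        p
        for p in components(support, connectivity)
        if len(p) * px_ha >= min_supporting_patch_ha
    ]
    out = []
    for patch in components(damaged, connectivity):
        dist = math.inf
        for sp in support_patches:
            dist = min(dist, min_set_distance(patch, sp, resolution_m))
        out.append(
            {
                "pixels": frozenset(patch),
                "area_ha": len(patch) * px_ha,
                "min_edge_distance_m": dist,
                "elevated": dist <= adjacency_distance_m,
            }
        )
    return out


def best_subset_vertices(
    years: np.ndarray, values: np.ndarray, n_interior: int
) -> tuple[tuple[int, ...], float]:
    """Exhaustive best anchored piecewise-linear fit with n interior vertices.

    Returns (vertex years, SSE) minimizing the sum of squared residuals of
    linear interpolation through the chosen observations.
    """
    from itertools import combinations

    n = len(years)
    best: tuple[tuple[int, ...], float] = ((), math.inf)
    for interior in combinations(range(1, n - 1), n_interior):
        vidx = (0,) + interior + (n - 1,)
        fit = np.interp(years, years[list(vidx)], values[list(vidx)])
        sse = float(np.sum((values - fit) ** 2))
        if sse < best[1]:
            best = (tuple(int(years[i]) for i in vidx), sse)
    return best
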