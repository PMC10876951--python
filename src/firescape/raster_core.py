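"""Geometry-aware raster primitives.

Patch labeling, area/perimeter/shape metrics, Euclidean distance transform,
categorical majority resampling, single-pixel noise filtering and hexagonal
aggregation, all on a plain in-memory :class:`Grid`.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; the georeferenced origin is
  the upper-left corner of the upper-left pixel, with y decreasing downward.
* Patch perimeter counts exposed cell edges times the resolution; nodata and
  the grid border both count as exposed.
* Distances are pixel-center to pixel-center, in meters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label

__all__ = [
    "Grid",
    "Patch",
    "label_patches",
    "fractal_index",
    "distance_to_class",
    "resample_majority",
    "remove_single_pixels",
    "hex_aggregate",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_geotiff",
    "read_geotiff",
    "hexagons_to_geojson",
]


@dataclass
class Grid:
    """A georeferenced 2D raster (categorical codes or continuous values).

    Parameters
    ----------
    values : numpy.ndarray
        2D array of cell values.
    resolution_m : float
        Cell edge length in meters; must be positive.
    origin : tuple of float
        ``(x, y)`` of the upper-left corner of the upper-left cell.
    nodata : int or float
        Sentinel marking missing cells.
    """

    values: np.ndarray
    resolution_m: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("Grid requires a non-empty 2D array")
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_ha(self) -> float:
        return self.resolution_m**2 / 10_000.0

    def like(self, values: np.ndarray, **kw) -> "Grid":
        """New grid sharing this grid's geometry."""
        g = replace(self, values=values)
        for k, v in kw.items():
            setattr(g, k, v)
        return g

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World ``(x, y)`` coordinates of every pixel center."""
        rows, cols = np.indices(self.shape)
        x = self.origin[0] + (cols + 0.5) * self.resolution_m
        y = self.origin[1] - (rows + 0.5) * self.resolution_m
        return x, y

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.resolution_m == other.resolution_m
            and self.origin == other.origin
        )


@dataclass
class Patch:
    """A maximal connected component of one class."""

    id: int
    class_code: int
    pixels: tuple[tuple[int, int], ...]
    area_ha: float
    perimeter_m: float

    def __len__(self) -> int:
        return len(self.pixels)


def _connectivity_struct(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _perimeter_m(mask: np.ndarray, resolution_m: float) -> float:
    """Exposed 4-neighbor cell edges times resolution."""
    padded = np.pad(mask.astype(np.int8), 1)
    exposed = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        exposed += int(np.sum((padded == 1) & (np.roll(padded, shift, axis=axis) == 0)))
    return exposed * resolution_m


def label_patches(
    grid: Grid, target_class: int, connectivity: int = 8
) -> list[Patch]:
    """Delineate maximal connected patches of ``target_class``.

    Every target-class pixel belongs to exactly one returned patch. Patch ids
    are 1-based in raster scan order of the patch's first pixel.
    """
    mask = grid.values == target_class
    if not mask.any() and not np.isin(target_class, grid.values).any():
        # class absent is fine; an unregistered nodata-ish code is the
        # caller's responsibility — but reject obviously bogus queries
        if target_class == grid.nodata:
            raise ValueError("target_class equals the nodata sentinel")
    lab = _sk_label(mask, connectivity=_connectivity_struct(connectivity))
    patches: list[Patch] = []
    for pid in range(1, lab.max() + 1):
        component = lab == pid
        rr, cc = np.nonzero(component)
        patches.append(
            Patch(
                id=pid,
                class_code=int(target_class),
                pixels=tuple(zip(rr.tolist(), cc.tolist())),
                area_ha=len(rr) * grid.pixel_area_ha,
                perimeter_m=_perimeter_m(component, grid.resolution_m),
            )
        )
    return patches


def fractal_index(patch: Patch) -> float:
    """Patch shape complexity: ``2 ln(0.25 P) / ln(A)``.

    ``P`` is the perimeter in meters and ``A`` the area in square meters.
    Squares score exactly 1; elongated or ragged patches score higher,
    approaching 2.
    """
    area_m2 = patch.area_ha * 10_000.0
    if area_m2 <= 1.0:
        raise ValueError("fractal index undefined for patches of area <= 1 m^2")
    return 2.0 * np.log(0.25 * patch.perimeter_m) / np.log(area_m2)


def distance_to_class(grid: Grid, target_class: int) -> Grid:
    """Per-pixel Euclidean distance (m) to the nearest target-class pixel.

    Distances are pixel-center to pixel-center; target pixels score 0.

    Raises
    ------
    ValueError
        If no pixel carries ``target_class`` (distance undefined).
    """
    mask = grid.values == target_class
    if not mask.any():
        raise ValueError("distance undefined: grid has no target-class pixel")
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.resolution_m)
    return grid.like(dist.astype(float), nodata=float("nan"))


def resample_majority(grid: Grid, factor: int) -> Grid:
    """Aggregate a categorical grid by the modal class of each block.

    Output resolution is ``factor`` times the input. Grids whose dimensions
    are not divisible by ``factor`` are padded with nodata; nodata never wins
    a block unless the block is entirely nodata. Ties break to the smallest
    class code (deterministic).
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    vals = grid.values
    nr, nc = vals.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        vals = np.pad(vals, ((0, pr), (0, pc)), constant_values=grid.nodata)
    nr, nc = vals.shape
    blocks = vals.reshape(nr // factor, factor, nc // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nr // factor, nc // factor, -1)
    out = np.empty(blocks.shape[:2], dtype=vals.dtype)
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            cells = blocks[i, j]
            cells = cells[cells != grid.nodata]
            if cells.size == 0:
                out[i, j] = grid.nodata
                continue
            codes, counts = np.unique(cells, return_counts=True)
            out[i, j] = codes[np.argmax(counts)]  # unique() sorts -> smallest code wins ties
    return Grid(
        out,
        resolution_m=grid.resolution_m * factor,
        origin=grid.origin,
        nodata=grid.nodata,
    )


def remove_single_pixels(mask: Grid, connectivity: int = 8) -> Grid:
    """Clear positive pixels whose connected component has size 1."""
    m = mask.values.astype(bool)
    lab = _sk_label(m, connectivity=_connectivity_struct(connectivity))
    if lab.max():
        sizes = np.bincount(lab.ravel())
        single_ids = [i for i in range(1, sizes.size) if sizes[i] == 1]
        if single_ids:
            m = m & ~np.isin(lab, single_ids)
    return mask.like(m.astype(mask.values.dtype))


# -- hexagonal aggregation ---------------------------------------------------

_SQRT3 = np.sqrt(3.0)


def _hex_side_for_area(hex_area_km2: float) -> float:
    """Side length (m) of a regular hexagon with the given area."""
    if hex_area_km2 <= 0:
        raise ValueError("hex_area_km2 must be positive")
    return float(np.sqrt(hex_area_km2 * 1e6 * 2.0 / (3.0 * _SQRT3)))


def _points_to_hex(x: np.ndarray, y: np.ndarray, side: float) -> tuple[np.ndarray, np.ndarray]:
    """Axial (q, r) of the flat-topped hexagon containing each point.

    Fractional axial coordinates followed by cube rounding; the hexagon with
    axial (0, 0) is centered on the world origin of the lattice.
    """
    qf = (2.0 / 3.0) * x / side
    rf = (-x / 3.0 + _SQRT3 / 3.0 * y) / side
    sf = -qf - rf
    q = np.rint(qf)
    r = np.rint(rf)
    s = np.rint(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return q.astype(np.int64), r.astype(np.int64)


def _hex_center(q: np.ndarray, r: np.ndarray, side: float) -> tuple[np.ndarray, np.ndarray]:
    x = side * 1.5 * q
    y = side * _SQRT3 * (r + q / 2.0)
    return x, y


def hex_aggregate(mask: Grid, hex_area_km2: float = 3.0) -> list[dict]:
    """Summarize positive-pixel area over a regular hexagonal tessellation.

    Flat-topped hexagons of area ``hex_area_km2`` anchored at the raster
    origin; each pixel center falls in exactly one hexagon. Returns one record
    per hexagon intersecting the grid: ``{"hex_id", "center", "damaged_ha"}``.
    """
    side = _hex_side_for_area(hex_area_km2)
    px, py = mask.pixel_centers()
    # lattice anchored at raster origin
    q, r = _points_to_hex(px.ravel() - mask.origin[0], py.ravel() - mask.origin[1], side)
    positive = (mask.values.ravel() != 0) & (mask.values.ravel() != mask.nodata)
    area = mask.pixel_area_ha
    keys = np.stack([q, r], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    damaged = np.bincount(inverse, weights=positive.astype(float), minlength=len(uniq)) * area
    records = []
    for idx, (qq, rr) in enumerate(uniq):
        cx, cy = _hex_center(np.array([qq]), np.array([rr]), side)
        records.append(
            {
                "hex_id": f"{qq}_{rr}",
                "center": (float(cx[0] + mask.origin[0]), float(cy[0] + mask.origin[1])),
                "damaged_ha": float(damaged[idx]),
            }
        )
    return records


def hexagons_to_geojson(records: Sequence[dict], hex_area_km2: float = 3.0) -> str:
    """GeoJSON FeatureCollection of hexagon polygons with damaged_ha."""
    side = _hex_side_for_area(hex_area_km2)
    feats = []
    for rec in records:
        cx, cy = rec["center"]
        ring = [
            [cx + side * np.cos(a), cy + side * np.sin(a)]
            for a in np.arange(6) * np.pi / 3.0
        ]
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"hex_id": rec["hex_id"], "damaged_ha": rec["damaged_ha"]},
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})


# -- plain-text and TIFF raster I/O ------------------------------------------


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a Grid as an Esri ASCII grid (plain text)."""
    nr, nc = grid.shape
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1] - nr * grid.resolution_m}\n"
        f"cellsize {grid.resolution_m}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%g")


def read_ascii_grid(path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    res = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + header["nrows"] * res)
    return Grid(values, resolution_m=res, origin=origin, nodata=header["nodata_value"])


def write_geotiff(grid: Grid, path) -> None:
    """Write grid values as a TIFF with geometry in the image description."""
    import tifffile

    meta = {
        "resolution_m": grid.resolution_m,
        "origin": list(grid.origin),
        "nodata": grid.nodata,
    }
    tifffile.imwrite(path, np.asarray(grid.values), description=json.dumps(meta))


def read_geotiff(path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        try:
            meta = json.loads(tif.pages[0].description)
        except (ValueError, TypeError):
            meta = {}
    return Grid(
        values,
        resolution_m=meta.get("resolution_m", 10.0),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=meta.get("nodata", -9999),
    )
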