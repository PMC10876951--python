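"""Self-contained synthetic landscapes for the full analysis chain.

Generates nine-class land-cover mosaics with spatially coherent patches,
schedules disturbance events of three agent types (stand-replacing fire,
stand-replacing harvest, non-stand-replacing) with distinct spectral and
geometric signatures, derives annual NBR/NDVI/tasseled-cap trajectories,
five-yearly forest masks, daily fire-weather series with injectable anomaly
years, and reference samples — all bit-reproducible from one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landcover as lc
from .raster_core import Grid
from .spectral_composites import IndexStack

__all__ = [
    "DisturbanceSpec",
    "ScenarioConfig",
    "Event",
    "SyntheticTruth",
    "generate_scenario",
    "generate_weather",
    "generate_reference_sample",
    "generate_agent_training_set",
    "nbr_trajectory",
    "DEFAULT_CLASS_PROPORTIONS",
    "SIM_YEARS",
    "CLASS_BASELINES",
]

SIM_START, SIM_END = 1986, 2022
SIM_YEARS = list(range(SIM_START, SIM_END + 1))
FOREST_MASK_YEARS = [1986, 1990, 1995, 2000, 2005, 2010, 2015, 2020]
RECOVERY_YEARS = 15

DEFAULT_CLASS_PROPORTIONS = {
    lc.BARE_SOIL: 0.04,
    lc.BUILT_UP: 0.04,
    lc.BURNED_FOREST: 0.03,
    lc.CROPLAND: 0.30,
    lc.FOREST: 0.35,
    lc.GRASSLAND: 0.12,
    lc.WATER: 0.04,
    lc.WETLAND: 0.03,
    lc.WOODLAND: 0.05,
}

# per-class baseline (nbr, ndvi, tcb, tcg, tcw)
CLASS_BASELINES = {
    lc.BARE_SOIL: (0.05, 0.10, 0.35, 0.10, -0.05),
    lc.BUILT_UP: (0.00, 0.10, 0.30, 0.10, -0.10),
    lc.BURNED_FOREST: (0.15, 0.25, 0.20, 0.20, -0.05),
    lc.CROPLAND: (0.30, 0.50, 0.30, 0.45, 0.00),
    lc.FOREST: (0.70, 0.85, 0.22, 0.55, 0.12),
    lc.GRASSLAND: (0.35, 0.55, 0.30, 0.40, 0.00),
    lc.WATER: (-0.20, -0.10, 0.05, -0.05, 0.30),
    lc.WETLAND: (0.40, 0.50, 0.15, 0.35, 0.20),
    lc.WOODLAND: (0.55, 0.70, 0.25, 0.50, 0.08),
}
_LAYERS = ("nbr", "ndvi", "tcb", "tcg", "tcw")

# post-event land cover by agent
_POST_CLASS = {"SRF": lc.BURNED_FOREST, "SRH": lc.GRASSLAND, "NSR": lc.FOREST}


@dataclass(frozen=True)
class DisturbanceSpec:
    """One scheduled batch of same-agent events."""

    year: int
    agent: str  # SRF | SRH | NSR
    count: int
    severity: tuple[float, float] = (0.3, 0.6)  # dNBR range
    geometry: Optional[str] = None  # rectangle | irregular (default by agent)
    size_px: tuple[int, int] = (8, 60)
    duration: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.agent not in _POST_CLASS:
            raise ValueError(f"unknown agent {self.agent!r}")
        lo, hi = self.severity
        if not (0.1 <= lo <= hi):
            raise ValueError("severity range must satisfy 0.1 <= lo <= hi")
        if self.agent == "NSR" and hi >= 0.25:
            raise ValueError("NSR severity must stay below 0.25 dNBR")
        if self.agent == "SRF" and lo < 0.25:
            raise ValueError("SRF severity must be at least 0.25 dNBR")
        if not (1 <= self.duration[0] <= self.duration[1] <= 3):
            raise ValueError("duration range must lie within 1-3 years")

    @property
    def shape_family(self) -> str:
        if self.geometry is not None:
            return self.geometry
        return "rectangle" if self.agent == "SRH" else "irregular"


@dataclass(frozen=True)
class ScenarioConfig:
    grid_rows: int = 120
    grid_cols: int = 120
    resolution_m: float = 10.0
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    disturbance_schedule: tuple[DisturbanceSpec, ...] = ()
    trajectory_noise_sd: float = 0.02
    weather_noise_sd: float = 0.5
    weather_anomaly_years: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be non-empty")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if set(self.class_proportions) != set(lc.ALL_CLASSES):
            raise ValueError("proportions must cover exactly the nine classes")
        for spec in self.disturbance_schedule:
            if not (SIM_START <= spec.year <= SIM_END):
                raise ValueError(
                    f"scheduled year {spec.year} outside {SIM_START}-{SIM_END}"
                )
        for year in self.weather_anomaly_years:
            if not (SIM_START <= year <= SIM_END):
                raise ValueError(f"anomaly year {year} outside simulated period")


@dataclass(frozen=True)
class Event:
    """Ground-truth disturbance: footprint, timing, agent and severity."""

    pixels: tuple[tuple[int, int], ...]
    year: int
    agent: str
    d_nbr: float
    duration: int


@dataclass
class SyntheticTruth:
    config: ScenarioConfig
    landcover_by_year: dict[int, Grid]
    events: list[Event]
    forest_masks_5yr: dict[int, Grid]
    index_stack: IndexStack  # annual nbr/ndvi/tcb/tcg/tcw over SIM_YEARS
    weather: pd.DataFrame

    @property
    def grid(self) -> Grid:
        return self.landcover_by_year[SIM_START]


# ---------------------------------------------------------------------------
# land-cover mosaic


def _mosaic(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Nine-class mosaic from multi-scale smoothed noise cut at quantiles."""
    shape = (config.grid_rows, config.grid_cols)
    fld = np.zeros(shape)
    for sigma, weight in ((2.0, 0.4), (6.0, 0.35), (12.0, 0.25)):
        fld += weight * ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    codes = sorted(config.class_proportions)
    cum = np.cumsum([config.class_proportions[c] for c in codes])
    thresholds = np.quantile(fld, cum[:-1])
    out = np.full(shape, codes[-1], dtype=np.int16)
    binned = np.digitize(fld, thresholds)
    for i, code in enumerate(codes):
        out[binned == i] = code
    return out


# ---------------------------------------------------------------------------
# footprints


def _rectangle_footprint(
    available: np.ndarray, n_target: int, rng: np.random.Generator
) -> Optional[list[tuple[int, int]]]:
    """A ~n_target-pixel rectangle fully inside the available mask."""
    nrows, ncols = available.shape
    shapes = []
    for h in range(1, int(math.sqrt(n_target) * 2) + 2):
        w = max(1, round(n_target / h))
        if h <= nrows and w <= ncols:
            shapes.append((h, w))
    rng.shuffle(shapes)
    avail = available.astype(float)
    for h, w in shapes:
        # box filter finds placements whose h x w block is fully available
        ok = ndimage.uniform_filter(avail, size=(h, w), mode="constant") > 1 - 1e-9
        rr, cc = np.nonzero(ok)
        r0s, c0s = rr - (h - 1) // 2, cc - (w - 1) // 2
        inside = (r0s >= 0) & (r0s + h <= nrows) & (c0s >= 0) & (c0s + w <= ncols)
        r0s, c0s = r0s[inside], c0s[inside]
        keep = [
            i
            for i in range(len(r0s))
            if available[r0s[i] : r0s[i] + h, c0s[i] : c0s[i] + w].all()
        ]
        if not keep:
            continue
        k = keep[int(rng.integers(len(keep)))]
        r0, c0 = int(r0s[k]), int(c0s[k])
        return [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]
    return None


def _irregular_footprint(
    available: np.ndarray, n_target: int, rng: np.random.Generator
) -> Optional[list[tuple[int, int]]]:
    """Region-grown blob: random accretion from an ignition cell."""
    rr, cc = np.nonzero(available)
    if rr.size == 0:
        return None
    k = int(rng.integers(rr.size))
    seed = (int(rr[k]), int(cc[k]))
    patch = {seed}
    frontier = [seed]
    nrows, ncols = available.shape
    while len(patch) < n_target and frontier:
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        neighbors = [
            (r + dr, c + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= r + dr < nrows
            and 0 <= c + dc < ncols
            and (r + dr, c + dc) not in patch
            and available[r + dr, c + dc]
        ]
        if not neighbors:
            frontier.pop(idx)
            continue
        nxt = neighbors[int(rng.integers(len(neighbors)))]
        patch.add(nxt)
        frontier.append(nxt)
    if len(patch) < max(2, n_target // 2):
        return None
    return sorted(patch)


def _place_events(
    config: ScenarioConfig, base: np.ndarray, rng: np.random.Generator
) -> list[Event]:
    available = base == lc.FOREST
    events: list[Event] = []
    for spec in sorted(config.disturbance_schedule, key=lambda s: (s.year, s.agent)):
        for _ in range(spec.count):
            n_target = int(rng.integers(spec.size_px[0], spec.size_px[1] + 1))
            if available.sum() < n_target:
                raise ValueError(
                    f"scheduled {spec.agent} event of {n_target} px exceeds "
                    f"available forest ({int(available.sum())} px)"
                )
            pixels = None
            want = n_target
            while pixels is None and want >= max(2, spec.size_px[0] // 2):
                if spec.shape_family == "rectangle":
                    pixels = _rectangle_footprint(available, want, rng)
                else:
                    pixels = _irregular_footprint(available, want, rng)
                if pixels is None:
                    want = int(want * 0.8)
            if pixels is None:
                raise ValueError(
                    f"could not place a {spec.agent} footprint of {n_target} px"
                )
            sev = float(rng.uniform(*spec.severity))
            dur = int(rng.integers(spec.duration[0], spec.duration[1] + 1))
            events.append(
                Event(
                    pixels=tuple(pixels),
                    year=spec.year,
                    agent=spec.agent,
                    d_nbr=sev,
                    duration=dur,
                )
            )
            for r, c in pixels:
                available[r, c] = False
    return events


# ---------------------------------------------------------------------------
# trajectories

# agent -> per-layer drop as a multiple of the event d_nbr
# (negative = the layer increases; harvests get brighter)
_AGENT_LAYER_SCALE = {
    "SRF": {"nbr": 1.0, "ndvi": 0.8, "tcb": 0.15, "tcg": 0.7, "tcw": 0.3},
    "SRH": {"nbr": 1.0, "ndvi": 0.7, "tcb": -0.5, "tcg": 0.6, "tcw": 0.25},
    "NSR": {"nbr": 1.0, "ndvi": 0.8, "tcb": 0.05, "tcg": 0.5, "tcw": 0.2},
}


def _trajectories(
    config: ScenarioConfig,
    base: np.ndarray,
    events: list[Event],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n_years = len(SIM_YEARS)
    shape = (n_years, config.grid_rows, config.grid_cols)
    stacks = {name: np.empty(shape) for name in _LAYERS}
    for i, name in enumerate(_LAYERS):
        lut = np.zeros(max(lc.ALL_CLASSES) + 1)
        for code, baseline in CLASS_BASELINES.items():
            lut[code] = baseline[i]
        stacks[name][:] = lut[base][None]
    for ev in events:
        pre = CLASS_BASELINES[lc.FOREST]
        post_class = _POST_CLASS[ev.agent]
        post = CLASS_BASELINES[post_class]
        scales = _AGENT_LAYER_SCALE[ev.agent]
        rr = np.array([p[0] for p in ev.pixels])
        cc = np.array([p[1] for p in ev.pixels])
        for i, name in enumerate(_LAYERS):
            drop = scales[name] * ev.d_nbr
            low = pre[i] - drop
            target = post[i] if ev.agent != "NSR" else pre[i]
            series = np.empty(n_years)
            for t, year in enumerate(SIM_YEARS):
                if year < ev.year:
                    series[t] = pre[i]
                elif year < ev.year + ev.duration:
                    frac = (year - ev.year + 1) / ev.duration
                    series[t] = pre[i] - drop * frac
                else:
                    since = year - (ev.year + ev.duration - 1)
                    series[t] = low + (target - low) * min(
                        1.0, since / RECOVERY_YEARS
                    )
            stacks[name][:, rr, cc] = series[:, None]
    if config.trajectory_noise_sd > 0:
        for name in _LAYERS:
            stacks[name] += rng.normal(
                0.0, config.trajectory_noise_sd, size=shape
            )
    for name in ("nbr", "ndvi"):
        np.clip(stacks[name], -1.0, 1.0, out=stacks[name])
    return stacks


# ---------------------------------------------------------------------------
# public generators


def generate_scenario(config: ScenarioConfig) -> SyntheticTruth:
    """Build the full ground truth for one seeded scenario.

    Land cover evolves only where events occur: stand-replacing fire turns
    forest into pre-2022-burned forest, harvest into grassland, and
    non-stand-replacing events leave the class unchanged.
    """
    rng = np.random.default_rng(config.seed)
    base = _mosaic(config, rng)
    events = _place_events(config, base, rng)
    landcover_by_year: dict[int, Grid] = {}
    current = base.copy()
    events_by_year: dict[int, list[Event]] = {}
    for ev in events:
        events_by_year.setdefault(ev.year, []).append(ev)
    for year in SIM_YEARS:
        for ev in events_by_year.get(year, []):
            post = _POST_CLASS[ev.agent]
            if post != lc.FOREST:
                for r, c in ev.pixels:
                    current[r, c] = post
        landcover_by_year[year] = Grid(
            current.copy(), resolution_m=config.resolution_m, nodata=-1
        )
    forest_masks = {
        y: landcover_by_year[y].like(
            (landcover_by_year[y].values == lc.FOREST).astype(np.uint8), nodata=255
        )
        for y in FOREST_MASK_YEARS
    }
    stacks = _trajectories(config, base, events, rng)
    index_stack = IndexStack(
        stacks, list(SIM_YEARS), landcover_by_year[SIM_START]
    )
    weather = generate_weather(config)
    return SyntheticTruth(
        config=config,
        landcover_by_year=landcover_by_year,
        events=events,
        forest_masks_5yr=forest_masks,
        index_stack=index_stack,
        weather=weather,
    )


def _season_shape(doy: np.ndarray) -> np.ndarray:
    return np.exp(-(((doy - 166.0) / 80.0) ** 2))


def generate_weather(config: ScenarioConfig) -> pd.DataFrame:
    """Daily FWI/ISI/DC for 1986–2022 on a non-leap 365-day calendar.

    Each index follows a smooth seasonal cycle plus Gaussian noise. Years in
    ``weather_anomaly_years`` receive an additive March–September shift of
    2.5 within-year standard deviations of the seasonal-window values.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    dates = pd.date_range(f"{SIM_START}-01-01", f"{SIM_END}-12-31", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    # day-of-year on the non-leap calendar
    doy = np.array(
        [
            pd.Timestamp(2001, d.month, d.day).dayofyear
            for d in dates
        ]
    )
    season = _season_shape(doy)
    base = {
        "fwi": 5.0 + 15.0 * season,
        "isi": 3.0 + 8.0 * season,
        "dc": 80.0 + 350.0 * season,
    }
    noise_scale = {"fwi": 1.0, "isi": 0.6, "dc": 20.0}
    cols = {}
    for name, series in base.items():
        vals = series.copy()
        if config.weather_noise_sd > 0:
            vals = vals + rng.normal(
                0.0, config.weather_noise_sd * noise_scale[name], size=len(vals)
            )
        cols[name] = vals
    in_window = (doy >= 60) & (doy <= 273)  # 1 Mar - 30 Sep, non-leap
    years = dates.year.to_numpy()
    for anomaly_year in config.weather_anomaly_years:
        sel = (years == anomaly_year) & in_window
        for name in cols:
            shift = 2.5 * float(np.std(cols[name][sel], ddof=1))
            cols[name][sel] = cols[name][sel] + shift
    out = pd.DataFrame({"date": dates, **cols})
    for name in ("fwi", "isi", "dc"):
        out[name] = out[name].clip(lower=0.0)
    return out


def generate_reference_sample(
    truth_grid: Grid,
    map_grid: Grid,
    n: int,
    seed: int,
    stratified: bool = False,
    with_replacement: bool = False,
) -> pd.DataFrame:
    """Reference locations with mapped and true labels attached.

    Uniform random sampling by default; with ``stratified=True`` the total
    ``n`` is split evenly across mapped classes (strata), and empty mapped
    classes contribute zero samples — they are reported in
    ``df.attrs["empty_strata"]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if truth_grid.shape != map_grid.shape:
        raise ValueError("map and truth must share geometry")
    rng = np.random.default_rng(seed)
    nrows, ncols = map_grid.shape
    n_pixels = nrows * ncols
    empty_strata: list = []
    capped_strata: list = []
    if stratified:
        strata = [
            int(c)
            for c in np.unique(map_grid.values)
            if c != map_grid.nodata
        ]
        per = {s: n // len(strata) for s in strata}
        for i, s in enumerate(strata[: n % len(strata)]):
            per[s] += 1
        picks = []
        for stratum in strata:
            flat = np.nonzero(map_grid.values.ravel() == stratum)[0]
            want = per[stratum]
            if flat.size == 0:
                empty_strata.append(stratum)
                continue
            if not with_replacement and want > flat.size:
                capped_strata.append(stratum)
                want = flat.size  # small stratum: take a census of it
            picks.append(rng.choice(flat, size=want, replace=with_replacement))
        idx = np.concatenate(picks) if picks else np.array([], dtype=int)
    else:
        if not with_replacement and n > n_pixels:
            raise ValueError("n exceeds pixel count without replacement")
        idx = rng.choice(n_pixels, size=n, replace=with_replacement)
    rows, cols = np.unravel_index(idx.astype(int), (nrows, ncols))
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "mapped_class": map_grid.values[rows, cols].astype(int),
            "reference_class": truth_grid.values[rows, cols].astype(int),
        }
    )
    df["stratum"] = df["mapped_class"]
    df.attrs["empty_strata"] = empty_strata
    df.attrs["capped_strata"] = capped_strata
    return df


def nbr_trajectory(
    years: Sequence[int],
    base: float,
    event_year: int,
    magnitude: float,
    duration: int = 1,
    recovery_per_year: float = 0.03,
) -> np.ndarray:
    """Clean single-event NBR trajectory: flat, linear drop, slow recovery."""
    years = np.asarray(years, dtype=int)
    nbr = np.full(len(years), base, dtype=float)
    low = base - magnitude
    for i, yy in enumerate(years):
        if yy >= event_year:
            if yy < event_year + duration:
                nbr[i] = base - magnitude * (yy - event_year + 1) / duration
            else:
                since = yy - (event_year + duration - 1)
                nbr[i] = min(base, low + recovery_per_year * since)
    return nbr


# ---------------------------------------------------------------------------
# designed agent-attribution training scenario


def generate_agent_training_set(
    n_per_class: int, seed: int, resolution_m: float = 30.0
) -> tuple[pd.DataFrame, list[str]]:
    """Patch features with the designed between-agent contrasts.

    Geometry is built honestly: harvest patches are rectangles, fire and
    non-stand-replacing patches are region-grown blobs, and the fractal
    index is computed from the realized raster footprint. Severities follow
    the agent rules (SRF >= 0.25, NSR < 0.25 dNBR).
    """
    from .agent_attribution import FEATURE_COLUMNS  # avoid cycle at import
    from .raster_core import fractal_index, label_patches

    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    specs = {
        "SRF": dict(severity=(0.3, 0.75), size=(30, 220), dur=(1, 1)),
        "SRH": dict(severity=(0.35, 0.7), size=(8, 60), dur=(1, 1)),
        "NSR": dict(severity=(0.1, 0.24), size=(4, 40), dur=(1, 3)),
    }
    for agent, spec in specs.items():
        for _ in range(n_per_class):
            n_target = int(rng.integers(spec["size"][0], spec["size"][1] + 1))
            side = int(math.ceil(math.sqrt(n_target) * 3)) + 4
            canvas = np.ones((side, side), dtype=bool)
            if agent == "SRH":
                pixels = _rectangle_footprint(canvas, n_target, rng)
            else:
                pixels = _irregular_footprint(canvas, n_target, rng)
            mask = np.zeros((side, side), dtype=np.int16)
            for r, c in pixels:
                mask[r, c] = 1
            patch = label_patches(
                Grid(mask, resolution_m=resolution_m, nodata=-1), 1
            )[0]
            sev = float(rng.uniform(*spec["severity"]))
            dur = int(rng.integers(spec["dur"][0], spec["dur"][1] + 1))
            scales = _AGENT_LAYER_SCALE[agent]
            noise = rng.normal(0.0, 0.02, size=6)
            d_nbr = sev + noise[0]
            if agent == "NSR":
                d_nbr = min(d_nbr, 0.2499)  # keep exemplars inside the NSR rule
            elif agent == "SRF":
                d_nbr = max(d_nbr, 0.25)
            rows.append(
                {
                    "patch_id": f"{agent}_{len(rows)}",
                    "year": int(rng.integers(SIM_START + 1, SIM_END + 1)),
                    "n_pixels": len(patch.pixels),
                    "complete": True,
                    "d_nbr": d_nbr,
                    "d_ndvi": scales["ndvi"] * sev + noise[1],
                    # tasseled-cap deltas are signed post-minus-pre changes
                    "d_tcb": -scales["tcb"] * sev + noise[2],
                    "d_tcg": -scales["tcg"] * sev + noise[3],
                    "d_tcw": -scales["tcw"] * sev + noise[4],
                    "pre_nbr": CLASS_BASELINES[lc.FOREST][0] + noise[5],
                    "duration": dur,
                    "rate": d_nbr / dur,
                    "area_ha": patch.area_ha,
                    "frac": fractal_index(patch),
                }
            )
            labels.append(agent)
    features = pd.DataFrame(rows)
    features = features[
        ["patch_id", "year", "n_pixels", "complete"] + FEATURE_COLUMNS
    ]
    return features, labels
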