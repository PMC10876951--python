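"""Temporal segmentation of annual NBR trajectories into loss segments.

A pixel's yearly NBR series is approximated by a continuous piecewise-linear
fit. Candidate vertex sets come from an exact dynamic program over anchored
segment costs; the winning set is re-scored by least squares (so single noisy
observations cannot anchor the fit) and refined locally. Fitted decreases of
at least 0.1 NBR lasting 1-3 years become loss segments; their boundaries are
sharpened by comparing small local disturbance templates against the raw
series, and candidate episodes whose best-fitting template is longer than
3 years are rejected as slow declines. The largest and second-largest
segments per pixel are ranked primary and secondary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "LossSegment",
    "fit_vertices",
    "fitted_values",
    "extract_loss_segments",
    "rank_disturbances",
    "year_assignment",
    "segment_stack",
    "MIN_LOSS_DELTA",
    "MAX_LOSS_DURATION",
]

#: minimum fitted NBR decrease that counts as spectral loss
MIN_LOSS_DELTA = 0.1
#: longest admissible loss-segment duration, years
MAX_LOSS_DURATION = 3
#: default cap on fitted segments over the 37-year record
DEFAULT_MAX_SEGMENTS = 6
#: default RMSE-improvement tolerance for choosing the segment count
DEFAULT_RMSE_TOL = 0.001


@dataclass
class Trajectory:
    """Annual NBR series for one pixel."""

    years: np.ndarray
    nbr: np.ndarray
    pixel: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.nbr = np.asarray(self.nbr, dtype=float)
        if self.years.shape != self.nbr.shape:
            raise ValueError("years and nbr must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")


@dataclass(frozen=True)
class LossSegment:
    """A dated spectral-loss episode (fitted NBR decrease)."""

    start_year: int
    end_year: int
    magnitude: float
    duration: int
    rate: float
    pre_nbr: float
    rank: Optional[str] = None  # "primary" | "secondary" | None

    def __post_init__(self):
        if self.duration != self.end_year - self.start_year:
            raise ValueError("duration must equal end_year - start_year")
        if not (1 <= self.duration <= MAX_LOSS_DURATION):
            raise ValueError("duration must be 1-3 years")
        if self.magnitude < MIN_LOSS_DELTA:
            raise ValueError(f"magnitude below detection threshold {MIN_LOSS_DELTA}")
        if abs(self.rate * self.duration - self.magnitude) > 1e-9:
            raise ValueError("rate x duration must equal magnitude")

    @property
    def disturbance_year(self) -> int:
        """First year at which the fitted decline is visible."""
        return self.start_year + 1


def _despike(nbr: np.ndarray) -> np.ndarray:
    """Damp single-year spikes that fully recover (1-step median filter)."""
    out = nbr.copy()
    if len(nbr) >= 3:
        out[1:-1] = np.median(np.stack([nbr[:-2], nbr[1:-1], nbr[2:]]), axis=0)
    return out


# ---------------------------------------------------------------------------
# piecewise-linear machinery


def _anchored_cost_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSE of linear interpolation through (i, j) over interior points."""
    n = len(x)
    C = np.full((n, n), np.inf)
    for i in range(n - 1):
        for j in range(i + 1, n):
            t = slice(i, j + 1)
            yhat = y[i] + (y[j] - y[i]) * (x[t] - x[i]) / (x[j] - x[i])
            C[i, j] = float(np.sum((y[t] - yhat) ** 2))
    return C


def _dp_vertex_sets(x: np.ndarray, y: np.ndarray, max_segments: int) -> list[list[int]]:
    """Globally optimal anchored vertex sets for 1..max_segments segments."""
    n = len(x)
    C = _anchored_cost_table(x, y)
    K = max_segments
    dp = np.full((K + 1, n), np.inf)
    parent = np.zeros((K + 1, n), dtype=int)
    dp[1] = C[0]
    for k in range(2, K + 1):
        tot = dp[k - 1][:, None] + C
        parent[k] = np.argmin(tot, axis=0)
        dp[k] = np.min(tot, axis=0)
    sets = []
    for k in range(1, K + 1):
        vid = [n - 1]
        kk = k
        while kk > 1:
            vid.append(int(parent[kk][vid[-1]]))
            kk -= 1
        vid.append(0)
        sets.append(sorted(set(vid)))
    return sets


def _hat_matrix(x: np.ndarray, vidx: Sequence[int]) -> np.ndarray:
    xv = x[list(vidx)]
    A = np.zeros((len(x), len(vidx)))
    for k in range(len(vidx)):
        hk = np.zeros(len(vidx))
        hk[k] = 1.0
        A[:, k] = np.interp(x, xv, hk)
    return A


def _lsq_fit(x: np.ndarray, y: np.ndarray, vidx: Sequence[int]):
    """Least-squares continuous piecewise-linear fit with knots at vidx."""
    A = _hat_matrix(x, vidx)
    c, *_ = np.linalg.lstsq(A, y, rcond=None)
    rmse = float(np.sqrt(np.mean((y - A @ c) ** 2)))
    return rmse, c


def _refine_vertices(
    x: np.ndarray,
    y: np.ndarray,
    vidx: list[int],
    rmse: float,
    c: np.ndarray,
    max_segments: int,
    insert_tol: float = 1e-6,
):
    """Local search: shift knots by one year / insert knots in declines."""
    n = len(x)
    for _ in range(40):
        best = None
        for v in [v for v in vidx if v not in (0, n - 1)]:
            for nv in (v - 1, v + 1):
                if 0 < nv < n - 1 and nv not in vidx:
                    trial = sorted(set(vidx) - {v} | {nv})
                    tr, tc = _lsq_fit(x, y, trial)
                    if tr < rmse - 1e-12 and (best is None or tr < best[0]):
                        best = (tr, trial, tc)
        if len(vidx) - 1 < max_segments:
            for a, b in zip(vidx[:-1], vidx[1:]):
                ka, kb = vidx.index(a), vidx.index(b)
                if c[ka] - c[kb] <= 0:
                    continue
                for nv in range(a + 1, b):
                    trial = sorted(vidx + [nv])
                    tr, tc = _lsq_fit(x, y, trial)
                    if rmse - tr >= insert_tol and (best is None or tr < best[0]):
                        best = (tr, trial, tc)
        if best is None:
            break
        rmse, vidx, c = best
    return vidx, rmse, c


def fit_vertices(
    traj: Trajectory,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
    rmse_improvement_tol: float = DEFAULT_RMSE_TOL,
    despike: bool = False,
) -> list[int]:
    """Choose vertex years for the piecewise-linear fit of the NBR series.

    Candidate vertex sets for 1..max_segments segments come from an exact
    dynamic program over anchored interpolation costs; the segment count is
    the smallest whose least-squares RMSE improvement over the next count
    falls below ``rmse_improvement_tol``; the winner is refined by one-year
    knot shifts and knot insertions inside declining stretches.

    Returns the chosen vertex years, ascending. Endpoints are always
    vertices.
    """
    if len(traj.years) < 4:
        raise ValueError("need at least 4 observations to fit")
    y = _despike(traj.nbr) if despike else traj.nbr
    x = traj.years.astype(float)
    sets = _dp_vertex_sets(x, y, max_segments)
    scored = [_lsq_fit(x, y, s) for s in sets]
    k = 0
    while k < len(sets) - 1 and scored[k][0] - scored[k + 1][0] >= rmse_improvement_tol:
        k += 1
    v1, r1, c1 = _refine_vertices(
        x, y, sets[k], scored[k][0], scored[k][1], max_segments
    )
    if k + 1 < len(sets):
        v2, r2, c2 = _refine_vertices(
            x, y, sets[k + 1], scored[k + 1][0], scored[k + 1][1], max_segments
        )
        if r1 - r2 >= rmse_improvement_tol:
            v1 = v2
    return [int(traj.years[i]) for i in v1]


def fitted_values(traj: Trajectory, vertex_years: Sequence[int]) -> np.ndarray:
    """Least-squares piecewise-linear fitted NBR at every observation year."""
    vidx = [int(np.nonzero(traj.years == vy)[0][0]) for vy in sorted(vertex_years)]
    x = traj.years.astype(float)
    _, c = _lsq_fit(x, traj.nbr, vidx)
    return np.interp(x, x[vidx], c)


def _vertex_values(traj: Trajectory, vertex_years: Sequence[int]) -> np.ndarray:
    vidx = [int(np.nonzero(traj.years == vy)[0][0]) for vy in sorted(vertex_years)]
    _, c = _lsq_fit(traj.years.astype(float), traj.nbr, vidx)
    return c


def _local_boundary_refine(
    traj: Trajectory,
    start_year: int,
    end_year: int,
    min_delta: float,
    max_duration: int,
    long_duration: int = 6,
    pre_win: int = 6,
    post_win: int = 3,
) -> Optional[tuple[int, int, float, float]]:
    """Sharpen a candidate episode against the raw series.

    Compares 3-parameter templates (flat pre-level, linear decline from
    onset ``o`` to end ``e``, linear recovery after) over a common window
    for all (o, e) near the candidate, including durations up to
    ``long_duration``. Returns (start, end, magnitude, pre_level), or None
    when the winner is longer than ``max_duration`` (a slow decline, not a
    1-3 yr disturbance) or below the detection threshold.
    """
    years = traj.years
    y = traj.nbr
    n = len(years)
    ia = int(np.nonzero(years == start_year)[0][0])
    ib = int(np.nonzero(years == end_year)[0][0])
    w0 = max(0, ia - 2 - pre_win)
    w1 = min(n - 1, ib + 2 + post_win)
    idx = np.arange(w0, w1 + 1)
    best = None
    for o in range(max(0, ia - 2), min(n - 2, ia + 3)):
        for e in range(o + 1, min(n - 1, o + long_duration) + 1):
            if e - ib > 2:
                continue
            A = np.zeros((len(idx), 3))
            for ii, t in enumerate(idx):
                if t <= o:
                    A[ii, 0] = 1.0
                elif t < e:
                    f = (t - o) / (e - o)
                    A[ii, 0] = 1 - f
                    A[ii, 1] = f
                else:
                    A[ii, 1] = 1.0
                    A[ii, 2] = t - e
            coef, *_ = np.linalg.lstsq(A, y[idx], rcond=None)
            sse = float(np.sum((y[idx] - A @ coef) ** 2))
            if best is None or sse < best[0]:
                best = (sse, o, e, float(coef[0] - coef[1]), float(coef[0]))
    if best is None:
        return None
    _, o, e, mag, pre = best
    if mag < min_delta or e - o > max_duration:
        return None
    return int(years[o]), int(years[e]), mag, pre


def extract_loss_segments(
    vertex_years: Sequence[int],
    traj: Trajectory,
    min_delta: float = MIN_LOSS_DELTA,
    max_duration: int = MAX_LOSS_DURATION,
    refine_boundaries: bool = True,
) -> list[LossSegment]:
    """Turn fitted decreases into dated loss segments.

    Consecutive declining inter-vertex pieces form one loss episode;
    noise-level boundary pieces are trimmed, the contiguous window of
    admissible duration with the largest fitted drop is selected, and (by
    default) its boundaries are re-estimated against the raw series. A
    window qualifies when the decrease reaches ``min_delta`` within
    ``max_duration`` years; genuinely slower declines are discarded.
    Returned segments never overlap.
    """
    vs = sorted(vertex_years)
    c = _vertex_values(traj, vs)
    pieces = [
        (vs[k], vs[k + 1], float(c[k] - c[k + 1])) for k in range(len(vs) - 1)
    ]
    candidates: list[tuple[int, int, float, float]] = []
    i = 0
    while i < len(pieces):
        if pieces[i][2] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < len(pieces) and pieces[j + 1][2] > 0:
            j += 1
        run = pieces[i : j + 1]
        rates = [p[2] / (p[1] - p[0]) for p in run]
        floor = max(rates) / 3.0
        while len(run) > 1 and run[0][2] / (run[0][1] - run[0][0]) < floor:
            run = run[1:]
        while len(run) > 1 and run[-1][2] / (run[-1][1] - run[-1][0]) < floor:
            run = run[:-1]
        window = None
        for a in range(len(run)):
            for b in range(a, len(run)):
                if run[b][1] - run[a][0] > max_duration:
                    continue
                drop = sum(p[2] for p in run[a : b + 1])
                if window is None or drop > window[2]:
                    window = (run[a][0], run[b][1], drop)
        if window is not None and window[2] >= min_delta:
            start, end, drop = window
            pre = float(c[vs.index(start)])
            if refine_boundaries:
                refined = _local_boundary_refine(
                    traj, start, end, min_delta, max_duration
                )
                if refined is None:
                    i = j + 1
                    continue
                start, end, drop, pre = refined
            candidates.append((start, end, drop, pre))
        i = j + 1
    # boundary refinement may move neighbors onto each other: keep the
    # largest-magnitude non-overlapping subset
    candidates.sort(key=lambda s: -s[2])
    chosen: list[tuple[int, int, float, float]] = []
    for cand in candidates:
        if all(cand[1] <= s[0] or cand[0] >= s[1] for s in chosen):
            chosen.append(cand)
    segments = [
        LossSegment(
            start_year=int(s),
            end_year=int(e),
            magnitude=float(m),
            duration=int(e - s),
            rate=float(m / (e - s)),
            pre_nbr=float(p),
        )
        for s, e, m, p in sorted(chosen)
    ]
    return segments


def rank_disturbances(
    segments: Sequence[LossSegment],
) -> tuple[Optional[LossSegment], Optional[LossSegment]]:
    """Primary = largest magnitude, secondary = second largest.

    Ties break to the earlier start year, then the larger rate.
    """
    if not segments:
        return None, None
    ordered = sorted(segments, key=lambda s: (-s.magnitude, s.start_year, -s.rate))
    primary = LossSegment(**{**_seg_dict(ordered[0]), "rank": "primary"})
    secondary = None
    if len(ordered) > 1:
        secondary = LossSegment(**{**_seg_dict(ordered[1]), "rank": "secondary"})
    return primary, secondary


def _seg_dict(s: LossSegment) -> dict:
    return {
        "start_year": s.start_year,
        "end_year": s.end_year,
        "magnitude": s.magnitude,
        "duration": s.duration,
        "rate": s.rate,
        "pre_nbr": s.pre_nbr,
        "rank": s.rank,
    }


def year_assignment(
    segment: LossSegment,
    onset_doy: Optional[int] = None,
    detection_doy_cutoff: int = 236,
) -> int:
    """Reported disturbance year, reproducing the late-season one-year shift.

    Events whose within-year onset falls after ``detection_doy_cutoff``
    (default: day 236 ~ late August) are reported in the following year.
    Annual series carry no day-of-year, so ``onset_doy=None`` reports the
    disturbance year unshifted.
    """
    year = segment.disturbance_year
    if onset_doy is not None and onset_doy > detection_doy_cutoff:
        return year + 1
    return year


def _max_running_decline(y: np.ndarray) -> float:
    """Largest peak-to-later-trough decrease in the raw series."""
    running_max = np.maximum.accumulate(y)
    return float(np.max(running_max - y))


def segment_stack(
    nbr_stack: np.ndarray,
    years: Sequence[int],
    forest_masks_5yr: Optional[dict[int, np.ndarray]] = None,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
    rmse_improvement_tol: float = DEFAULT_RMSE_TOL,
) -> pd.DataFrame:
    """Segment every pixel of an annual NBR stack.

    Pixels whose raw series never declines by ``MIN_LOSS_DELTA`` cannot host
    a loss segment and are skipped outright.

    Parameters
    ----------
    nbr_stack : ndarray, shape (n_years, rows, cols)
    years : sequence of int
    forest_masks_5yr : dict year -> bool ndarray, optional
        When given, a segment is kept only where the latest mask at or
        before its start year is forest (pre-disturbance masking).

    Returns
    -------
    DataFrame
        Columns: row, col, rank, start_year, end_year, disturbance_year,
        magnitude, duration, rate, pre_nbr.
    """
    years = np.asarray(years, dtype=int)
    n_years, nrows, ncols = nbr_stack.shape
    if n_years != len(years):
        raise ValueError("stack depth must match the year list")
    mask_years = sorted(forest_masks_5yr) if forest_masks_5yr else []
    rows = []
    for r in range(nrows):
        for col in range(ncols):
            series = nbr_stack[:, r, col]
            if _max_running_decline(series) < MIN_LOSS_DELTA:
                continue
            traj = Trajectory(years, series, pixel=(r, col))
            verts = fit_vertices(traj, max_segments, rmse_improvement_tol)
            segments = extract_loss_segments(verts, traj)
            if forest_masks_5yr:
                segments = [
                    s
                    for s in segments
                    if _forest_before(
                        forest_masks_5yr, mask_years, s.start_year, r, col
                    )
                ]
            primary, secondary = rank_disturbances(segments)
            for seg in (primary, secondary):
                if seg is None:
                    continue
                rows.append(
                    {
                        "row": r,
                        "col": col,
                        "rank": seg.rank,
                        "start_year": seg.start_year,
                        "end_year": seg.end_year,
                        "disturbance_year": seg.disturbance_year,
                        "magnitude": seg.magnitude,
                        "duration": seg.duration,
                        "rate": seg.rate,
                        "pre_nbr": seg.pre_nbr,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "row",
            "col",
            "rank",
            "start_year",
            "end_year",
            "disturbance_year",
            "magnitude",
            "duration",
            "rate",
            "pre_nbr",
        ],
    )


def _forest_before(
    masks: dict[int, np.ndarray], mask_years: list[int], year: int, r: int, c: int
) -> bool:
    eligible = [y for y in mask_years if y <= year]
    if not eligible:
        return True
    return bool(masks[eligible[-1]][r, c])
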