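"""Optic-disc-anchored vessel path tracing on binary skeletons.

Skeleton pixels form an undirected graph with 8-connected edges.  Start
candidates are skeleton pixels in a thin annulus just outside the optic
disc circle (r_OD < d <= r_OD + delta); endpoints are skeleton pixels with
exactly one foreground neighbor.  Each endpoint outside the disc is
validated by a breadth-first search that must reach a start point without
entering the closed disc; validated pairs are then traced start-to-end
with a second BFS whose predecessor map reconstructs the shortest pixel
path.  BFS on a unit-weight graph yields a shortest path, and with a FIFO
queue and a fixed neighbor visiting order the traced path is fully
deterministic.

Arc length is the number of pixels on the path (paper-faithful pixel-count
mode); a geometric mode measures the path as a polyline subsampled every
few pixels, which suppresses the +5-8% staircase bias of per-step chain
sums and guarantees tortuosity >= 1 against the exact chord.
"""

from __future__ import annotations

import logging
import math
import re
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .av_separation import Skeleton
from .optic_disc import OpticDisc

logger = logging.getLogger(__name__)

__all__ = [
    "PathPair",
    "TracedPath",
    "extract_skeleton_pixels",
    "distance_to_od",
    "candidate_starts",
    "detect_endpoints",
    "validate_pairs",
    "curve_length",
    "straight_length",
    "polyline_length",
    "write_pair_table",
    "read_pair_table",
]

# Fixed row-major neighbor visiting order over the 8-neighborhood (dr, dc).
N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

Pixel = tuple[int, int]  # (x, y) = (column, row)


@dataclass(frozen=True)
class PathPair:
    """A validated (start, end) skeleton pixel pair for one vessel."""

    start_xy: Pixel
    end_xy: Pixel
    vessel_class: str = "artery"


@dataclass
class TracedPath:
    """A traced vessel path: ordered 8-connected pixel chain plus lengths."""

    pair: PathPair
    pixels: list[Pixel]  # ordered start -> end
    l_curve: int | None  # pixel count along the path (None if unreachable)
    l_straight: int  # rounded Euclidean start-end distance

    @property
    def chord(self) -> float:
        """Exact (unrounded) Euclidean start-end distance."""
        (xs, ys), (xe, ye) = self.pair.start_xy, self.pair.end_xy
        return math.hypot(xe - xs, ye - ys)

    def geometric_length(self, stride: int = 5) -> float:
        """Polyline arc length of the traced path (see :func:`polyline_length`)."""
        return polyline_length(self.pixels, stride=stride)


def extract_skeleton_pixels(skel: Skeleton) -> set[Pixel]:
    """All foreground centerline coordinates as (x, y) pairs."""
    rows, cols = np.nonzero(skel.grid)
    return {(int(c), int(r)) for r, c in zip(rows, cols)}


def distance_to_od(p: Pixel, od: OpticDisc) -> float:
    """Euclidean distance from a pixel to the optic disc center."""
    return math.hypot(p[0] - od.center_xy[0], p[1] - od.center_xy[1])


def candidate_starts(pixels: set[Pixel], od: OpticDisc, delta: float = 5.0) -> set[Pixel]:
    """Skeleton pixels in the start annulus r_OD < d <= r_OD + delta."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    r = od.radius_px
    return {p for p in pixels if r < distance_to_od(p, od) <= r + delta}


def detect_endpoints(skel: Skeleton) -> set[Pixel]:
    """Skeleton pixels with exactly one foreground 8-neighbor.

    Isolated pixels (zero neighbors) are not endpoints.
    """
    grid = skel.grid.astype(np.uint8)
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    neighbor_count = ndimage.convolve(grid, kernel, mode="constant", cval=0)
    ends = skel.grid & (neighbor_count == 1)
    rows, cols = np.nonzero(ends)
    return {(int(c), int(r)) for r, c in zip(rows, cols)}


def _od_blocked(shape: tuple[int, int], od: OpticDisc) -> np.ndarray:
    """Closed-disk exclusion mask {p : dist(p, OD) <= r_OD}."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    cx, cy = od.center_xy
    return (cc - cx) ** 2 + (rr - cy) ** 2 <= od.radius_px**2


def _bfs(grid: np.ndarray, source: Pixel, targets: set[Pixel],
         blocked: np.ndarray | None = None) -> tuple[Pixel | None, dict[Pixel, Pixel | None]]:
    """FIFO BFS over skeleton pixels; returns first target reached and the
    predecessor map.  Neighbor visiting order is fixed (row-major over N8)
    so ties break deterministically."""
    h, w = grid.shape
    prev: dict[Pixel, Pixel | None] = {source: None}
    if source in targets:
        return source, prev
    queue: deque[Pixel] = deque([source])
    while queue:
        x, y = queue.popleft()
        for dr, dc in N8:
            vy, vx = y + dr, x + dc
            if 0 <= vy < h and 0 <= vx < w and grid[vy, vx]:
                v = (vx, vy)
                if v in prev:
                    continue
                if blocked is not None and blocked[vy, vx]:
                    continue
                prev[v] = (x, y)
                if v in targets:
                    return v, prev
                queue.append(v)
    return None, prev


def validate_pairs(
    skel: Skeleton,
    starts: set[Pixel],
    endpoints: set[Pixel],
    od: OpticDisc,
    delta: float = 5.0,
) -> list[PathPair]:
    """Validate endpoints by BFS connectivity to the start annulus.

    For each endpoint strictly beyond the start band (d > r_OD + delta; an
    endpoint inside the band is a vessel origin, not a distal terminus),
    BFS explores the skeleton while avoiding the closed optic disc and
    emits a pair with the first start reached.  Endpoints with no
    admissible path are dropped.  Starts are reusable across endpoints.
    """
    if not starts:
        logger.warning("validate_pairs: no start candidates; all endpoints dropped")
        return []
    blocked = _od_blocked(skel.grid.shape, od)
    pairs: list[PathPair] = []
    for e in sorted(endpoints, key=lambda p: (p[1], p[0])):
        d = distance_to_od(e, od)
        if d <= od.radius_px + delta:
            continue
        hit, _ = _bfs(skel.grid, e, starts - {e}, blocked=blocked)
        if hit is not None:
            pairs.append(PathPair(start_xy=hit, end_xy=e, vessel_class=skel.vessel_class))
    logger.info("validate_pairs: %d/%d endpoints validated", len(pairs), len(endpoints))
    return pairs


def curve_length(skel: Skeleton, pair: PathPair) -> TracedPath:
    """Trace the BFS shortest pixel path for a validated pair.

    BFS runs from the start point; the path is reconstructed end-to-start
    through the predecessor map and stored start-to-end.  ``l_curve`` is
    the number of pixels on the path, inclusive of both ends (None when the
    pair is unreachable, which the caller should flag as missing).
    """
    h, w = skel.grid.shape
    for p in (pair.start_xy, pair.end_xy):
        x, y = p
        if not (0 <= y < h and 0 <= x < w and skel.grid[y, x]):
            raise ValueError(f"pair point {p} is not a skeleton pixel")
    hit, prev = _bfs(skel.grid, pair.start_xy, {pair.end_xy})
    l_straight = straight_length(pair)
    if hit is None:
        return TracedPath(pair=pair, pixels=[], l_curve=None, l_straight=l_straight)
    path = [pair.end_xy]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()
    return TracedPath(pair=pair, pixels=path, l_curve=len(path), l_straight=l_straight)


def straight_length(pair: PathPair) -> int:
    """Rounded Euclidean distance between the start and end points.

    Coincident points give 0; the downstream tortuosity ratio flags such
    records invalid (division guard).
    """
    (xs, ys), (xe, ye) = pair.start_xy, pair.end_xy
    return int(math.floor(math.hypot(xe - xs, ye - ys) + 0.5))


def polyline_length(pixels: list[Pixel], stride: int = 5) -> float:
    """Arc length of a pixel chain measured as a subsampled polyline.

    Summing raw per-step lengths (1 axial, sqrt(2) diagonal) overestimates
    the length of a digitized smooth curve by up to ~8% because of
    staircase quantization; sampling every ``stride`` pixels (always
    keeping the last) and summing segment chords removes almost all of
    that bias while, by the triangle inequality, never dropping below the
    straight start-end chord.
    """
    if len(pixels) < 2:
        return 0.0
    pts = np.asarray(pixels, dtype=np.float64)
    sub = pts[::stride]
    if (len(pts) - 1) % stride:
        sub = np.vstack([sub, pts[-1]])
    d = np.diff(sub, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


# ---------------------------------------------------------------------------
# Pair tables: "(x, y)" string cells in CSV/XLSX

_POINT_RE = re.compile(r"\(\s*(-?\d+)\s*,\s*(-?\d+)\s*\)")


def _format_point(p: Pixel) -> str:
    return f"({p[0]}, {p[1]})"


def _parse_point(cell: str) -> Pixel:
    m = _POINT_RE.search(str(cell))
    if m is None:
        raise ValueError(f"cannot parse point cell: {cell!r}")
    return (int(m.group(1)), int(m.group(2)))


def write_pair_table(pairs: list[PathPair], path) -> None:
    """Write pairs as a table with "(x, y)" string cells (CSV or XLSX)."""
    df = pd.DataFrame(
        {
            "Start (x,y)": [_format_point(p.start_xy) for p in pairs],
            "End (x,y)": [_format_point(p.end_xy) for p in pairs],
            "Class": [p.vessel_class for p in pairs],
        }
    )
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_pair_table(path) -> list[PathPair]:
    """Read a pair table written by :func:`write_pair_table`."""
    path = str(path)
    df = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    classes = df["Class"] if "Class" in df.columns else ["artery"] * len(df)
    return [
        PathPair(
            start_xy=_parse_point(s), end_xy=_parse_point(e), vessel_class=str(c)
        )
        for s, e, c in zip(df["Start (x,y)"], df["End (x,y)"], classes)
    ]
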