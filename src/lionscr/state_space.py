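"""Discretized state-space, trap grid, and effort rasterization.

Everything is planar, in kilometres.  The state-space is a regular lattice
of equal-area pixels (default 0.5 km^2) covering the survey extent plus a
buffer; each pixel is a potential activity-center location.  "Traps" are
1 km^2 grid cells that received search-encounter or playback effort on at
least one daily occasion -- there is no physical device.

Projected coordinates are assumed.  If field data arrive in lon/lat they
should be pre-projected to a local metric system (e.g. a transverse
Mercator centred on the study area); geodesy is deliberately out of scope
here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPoint, Polygon  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpace",
    "TrapGrid",
    "EffortArray",
    "build_state_space",
    "rasterize_effort",
    "distance_matrix",
]


@dataclass(frozen=True)
class StateSpace:
    """Buffered, habitat-masked pixel lattice of potential activity centers.

    ``centroids`` holds every lattice pixel whose centroid falls inside the
    buffered extent (pre-mask); ``habitat`` flags the pixels that remain
    after masking out unsuitable areas.  Latent activity centers index into
    the *habitat* subset (see :meth:`habitat_centroids`).
    """

    centroids: np.ndarray          # (P, 2) km, all in-extent pixels
    pixel_area: float              # km^2
    habitat: np.ndarray            # (P,) bool
    buffer_km: float
    origin: tuple[float, float]    # lower-left corner of the lattice
    shape: tuple[int, int]         # (ny, nx) of the covering lattice
    ij: np.ndarray                 # (P, 2) integer lattice coords (ix, iy)

    @property
    def spacing(self) -> float:
        return math.sqrt(self.pixel_area)

    @property
    def n_pixels(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_habitat(self) -> int:
        return int(self.habitat.sum())

    @property
    def total_area(self) -> float:
        """State-space area before masking (pixel count x pixel area)."""
        return self.n_pixels * self.pixel_area

    @property
    def habitat_area(self) -> float:
        return self.n_habitat * self.pixel_area

    @property
    def habitat_centroids(self) -> np.ndarray:
        return self.centroids[self.habitat]

    def habitat_lattice(self) -> np.ndarray:
        """(ny, nx) lookup: habitat-pixel index at each lattice node, -1 elsewhere.

        Used by the discretized random-walk proposal for activity centers.
        """
        ny, nx = self.shape
        grid = np.full((ny, nx), -1, dtype=np.int64)
        hab_ij = self.ij[self.habitat]
        grid[hab_ij[:, 1], hab_ij[:, 0]] = np.arange(hab_ij.shape[0])
        return grid

    def habitat_ij(self) -> np.ndarray:
        return self.ij[self.habitat]

    def contains_traps(self, traps: "TrapGrid") -> bool:
        """True when every trap-cell centroid lies in the unbuffered interior.

        The buffer must surround the trap array: a trap centroid closer than
        ``buffer_km`` to the lattice edge indicates a mis-built state-space.
        """
        x0, y0 = self.origin
        ny, nx = self.shape
        x1 = x0 + nx * self.spacing
        y1 = y0 + ny * self.spacing
        c = traps.cell_centroids
        b = self.buffer_km
        return bool(
            np.all(c[:, 0] >= x0 + b) and np.all(c[:, 0] <= x1 - b)
            and np.all(c[:, 1] >= y0 + b) and np.all(c[:, 1] <= y1 - b)
        )


@dataclass(frozen=True)
class TrapGrid:
    """Grid cells (default 1 km^2) that received effort on >=1 occasion."""

    cell_centroids: np.ndarray   # (J, 2) km
    cell_area: float             # km^2
    cell_ids: np.ndarray         # (J,) str identifiers
    cell_ij: np.ndarray          # (J, 2) integer grid coords (ix, iy)

    @property
    def n_traps(self) -> int:
        return self.cell_centroids.shape[0]


@dataclass
class EffortArray:
    """Per trap-cell, per daily-occasion effort covariates.

    ``search_km[j, k]`` is kilometres of search track driven in cell ``j``
    on occasion ``k`` (0-based column for occasion ``k + 1``);
    ``playback[j, k]`` is a 0/1 indicator of a playback event.
    """

    search_km: np.ndarray   # (J, K) float
    playback: np.ndarray    # (J, K) int8
    n_occasions: int

    def __post_init__(self) -> None:
        if np.any(self.search_km < 0):
            raise ValueError("search_km must be non-negative")
        if not np.isin(self.playback, (0, 1)).all():
            raise ValueError("playback must be a 0/1 indicator")

    @property
    def active(self) -> np.ndarray:
        """(J, K) bool: cell-occasions with any effort (search or playback)."""
        return (self.search_km > 0) | (self.playback == 1)

    @property
    def total_search_km(self) -> float:
        return float(self.search_km.sum())

    @property
    def n_playback_events(self) -> int:
        return int(self.playback.sum())

    def to_dataframe(self, traps: TrapGrid):
        """Long-format table (trap_id, occasion, search_km, playback)."""
        import pandas as pd

        j, k = np.nonzero(self.active)
        return pd.DataFrame(
            {
                "trap_id": traps.cell_ids[j],
                "occasion": k + 1,
                "search_km": self.search_km[j, k],
                "playback": self.playback[j, k],
            }
        )


def _as_polygon(extent) -> Polygon:
    if isinstance(extent, Polygon):
        return extent
    if isinstance(extent, TrapGrid):
        pts = extent.cell_centroids
    else:
        pts = np.asarray(extent, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("extent must be a Polygon or an (N, 2) point array")
    hull = MultiPoint(pts).convex_hull
    if hull.area == 0:
        # Degenerate hull (point / collinear traps); the buffer gives it area.
        return hull
    return hull


def build_state_space(
    extent,
    buffer_km: float = 15.0,
    pixel_area_km2: float = 0.5,
    habitat_mask=None,
) -> StateSpace:
    """Build the pixel lattice of potential activity centers.

    Parameters
    ----------
    extent
        Survey extent: a shapely ``Polygon``, an (N, 2) array of points, or a
        :class:`TrapGrid`.  When points or traps are given, the buffer is
        applied to their convex hull (the buffer surrounds the sampled traps).
    buffer_km
        Width of the buffer added around the extent (>= 0).
    pixel_area_km2
        Area of each state-space pixel; lattice spacing is its square root.
    habitat_mask
        Areas masked *out* as non-habitat (agriculture, open water ...):
        a shapely (Multi)Polygon, a sequence of polygons, or an on/off raster
        given as ``(grid, xllcorner, yllcorner, cellsize)`` with 0 marking
        non-habitat.  A pixel is non-habitat when its centroid falls inside a
        mask polygon (or on a 0 raster cell).
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    if pixel_area_km2 <= 0:
        raise ValueError("pixel_area_km2 must be > 0")
    poly = _as_polygon(extent)
    region = poly.buffer(buffer_km) if buffer_km > 0 else poly
    if region.is_empty or region.area == 0:
        raise ValueError("empty extent: the buffered survey region has no area")

    s = math.sqrt(pixel_area_km2)
    minx, miny, maxx, maxy = region.bounds
    nx = max(1, math.ceil((maxx - minx) / s - 1e-9))
    ny = max(1, math.ceil((maxy - miny) / s - 1e-9))
    xs = minx + (np.arange(nx) + 0.5) * s
    ys = miny + (np.arange(ny) + 0.5) * s
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    inside = shapely.intersects_xy(region, gx, gy)
    if not inside.any():
        raise ValueError("empty extent: no lattice centroid falls in the region")
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
    ij = np.column_stack([ii.ravel()[inside], jj.ravel()[inside]])
    centroids = np.column_stack([gx[inside], gy[inside]])

    habitat = np.ones(centroids.shape[0], dtype=bool)
    if habitat_mask is not None:
        habitat = ~_in_mask(centroids, habitat_mask)
    if not habitat.any():
        raise ValueError(
            "habitat mask covers the entire state-space: zero habitat pixels remain"
        )

    return StateSpace(
        centroids=centroids,
        pixel_area=pixel_area_km2,
        habitat=habitat,
        buffer_km=buffer_km,
        origin=(minx, miny),
        shape=(ny, nx),
        ij=ij,
    )


def _in_mask(points: np.ndarray, mask) -> np.ndarray:
    """True where a point falls inside the masked-out (non-habitat) area."""
    if isinstance(mask, tuple) and len(mask) == 4:
        grid, xll, yll, cellsize = mask
        grid = np.asarray(grid)
        iy = np.floor((points[:, 1] - yll) / cellsize).astype(int)
        ix = np.floor((points[:, 0] - xll) / cellsize).astype(int)
        out = np.ones(points.shape[0], dtype=bool)
        ok = (ix >= 0) & (ix < grid.shape[1]) & (iy >= 0) & (iy < grid.shape[0])
        # ESRI ASCII rasters store row 0 at the top (north).
        out[ok] = grid[grid.shape[0] - 1 - iy[ok], ix[ok]] == 0
        return out
    if isinstance(mask, (Polygon,)) or hasattr(mask, "geoms"):
        polys = [mask]
    else:
        polys = list(mask)
    hit = np.zeros(points.shape[0], dtype=bool)
    for p in polys:
        hit |= shapely.contains_xy(p, points[:, 0], points[:, 1])
    return hit


# ---------------------------------------------------------------------------
# Effort rasterization


def _segment_cells(p: np.ndarray, q: np.ndarray, w: float, origin):
    """Clip the segment p->q against a square grid of width ``w``.

    Returns (cells, lengths): the (ix, iy) cell of each traversed portion and
    its length.  Cells are found by slicing the segment at every grid-line
    crossing; a midpoint then identifies each portion's cell, so a point on a
    shared edge belongs to the higher-index cell (half-open [x, x+w) cells).
    """
    x0, y0 = origin
    d = q - p
    length = math.hypot(d[0], d[1])
    if length == 0:
        return [], []
    ts = [0.0, 1.0]
    for axis in range(2):
        if d[axis] != 0:
            lo = (p[axis] - (x0 if axis == 0 else y0)) / w
            hi = (q[axis] - (x0 if axis == 0 else y0)) / w
            a, b = min(lo, hi), max(lo, hi)
            for line in range(math.floor(a) + 1, math.ceil(b)):
                t = (line * w + (x0 if axis == 0 else y0) - p[axis]) / d[axis]
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = sorted(set(ts))
    cells, lengths = [], []
    for a, b in zip(ts[:-1], ts[1:]):
        mid = p + 0.5 * (a + b) * d
        ix = math.floor((mid[0] - x0) / w)
        iy = math.floor((mid[1] - y0) / w)
        cells.append((ix, iy))
        lengths.append((b - a) * length)
    return cells, lengths


def rasterize_effort(
    track_segments,
    playback_events,
    grid_cell_km2: float = 1.0,
    n_occasions: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[TrapGrid, EffortArray]:
    """Convert raw effort logs into trap x occasion covariate arrays.

    Parameters
    ----------
    track_segments
        Sequence of ``(vertices, occasion)`` where ``vertices`` is an
        ordered (V, 2) array of a search-track polyline and ``occasion`` is
        the 1-based survey day.
    playback_events
        Sequence of ``(point, occasion)`` with ``point`` an (x, y) pair.
    grid_cell_km2
        Trap-cell area; cell width is its square root.
    n_occasions
        Number of survey days; inferred from the data when omitted.

    A grid cell becomes a trap iff it received search or playback effort on
    at least one occasion.  Several playbacks in the same cell-occasion
    collapse to a single indicator (logged).
    """
    w = math.sqrt(grid_cell_km2)
    occs = [occ for _, occ in track_segments] + [occ for _, occ in playback_events]
    if n_occasions is None:
        n_occasions = max(occs) if occs else 0
    for occ in occs:
        if not (1 <= occ <= n_occasions):
            raise ValueError(f"occasion {occ} outside [1, {n_occasions}]")

    search: dict[tuple[int, int], dict[int, float]] = {}
    for vertices, occ in track_segments:
        vertices = np.asarray(vertices, dtype=float)
        for a, b in zip(vertices[:-1], vertices[1:]):
            cells, lengths = _segment_cells(a, b, w, origin)
            for cell, ln in zip(cells, lengths):
                search.setdefault(cell, {}).setdefault(occ, 0.0)
                search[cell][occ] += ln

    pb: dict[tuple[int, int], set[int]] = {}
    for point, occ in playback_events:
        x, y = float(point[0]), float(point[1])
        cell = (math.floor((x - origin[0]) / w), math.floor((y - origin[1]) / w))
        pb.setdefault(cell, set())
        if occ in pb[cell]:
            logger.info(
                "duplicate playback in cell %s occasion %d collapsed to one indicator",
                cell, occ,
            )
        pb[cell].add(occ)

    cells = sorted(set(search) | set(pb), key=lambda c: (c[1], c[0]))
    if not cells:
        logger.warning("no effort recorded: returning an empty trap grid")
    J = len(cells)
    search_km = np.zeros((J, n_occasions))
    playback = np.zeros((J, n_occasions), dtype=np.int8)
    for j, cell in enumerate(cells):
        for occ, ln in search.get(cell, {}).items():
            search_km[j, occ - 1] = ln
        for occ in pb.get(cell, ()):
            playback[j, occ - 1] = 1

    ij = np.array(cells, dtype=np.int64).reshape(J, 2)
    centroids = origin + (ij + 0.5) * w
    ids = np.array([f"c{ix}_{iy}" for ix, iy in cells], dtype=object)
    traps = TrapGrid(
        cell_centroids=centroids.reshape(J, 2),
        cell_area=grid_cell_km2,
        cell_ids=ids,
        cell_ij=ij,
    )
    return traps, EffortArray(search_km=search_km, playback=playback,
                              n_occasions=n_occasions)


def distance_matrix(state_space: StateSpace, traps: TrapGrid) -> np.ndarray:
    """Euclidean pixel x trap centroid distances in km, shape (P, J)."""
    if state_space.n_pixels == 0 or traps.n_traps == 0:
        raise ValueError("state-space and trap grid must be non-empty")
    return cdist(state_space.centroids, traps.cell_centroids)
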