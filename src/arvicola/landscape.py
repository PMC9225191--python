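"""Graph-based landscape resistance model.

A land-cover grid (nine categories: meadow, orchard, pasture/grassland,
annual crop, shrub, eucalyptus, deciduous woodlot, settlement/road, water)
is turned into a resistance surface by a category -> cost-value (CV) map.
Between deme pairs the module computes

* the least-cost path (LCP) on the 8-neighbour lattice, where the cost of a
  move between adjacent cells is ``cell_size * d * (CV_i + CV_j) / 2`` with
  ``d = 1`` for rook moves and ``sqrt(2)`` for diagonal moves,
* the *effective distance*: the metric length of that path in metres,
  optionally inflated by elevation differences from a DEM,
* the *resistance distance*: ``sum_i m_i * CV_i`` where ``m_i`` is the
  length (in kilometres) of the path segment crossing a patch of category
  ``i``,
* the straight-line (Euclidean) deme distance, and
* the *landscape suitability* of a pair: the fraction of suitable-habitat
  cells inside the lens-shaped intersection of two discs (each centred on
  one deme with radius equal to the pair's Euclidean distance), divided by
  that distance in km.

Grids are stored in file order (row 0 = northern edge) with the
georeference origin at the lower-left corner, ESRI ASCII convention.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import DemeInfo

__all__ = [
    "CATEGORIES",
    "DEFAULT_COST_VALUES",
    "SUITABLE_CATEGORIES",
    "CategoryGrid",
    "ElevationGrid",
    "Path8",
    "DistanceBundle",
    "read_ascii_grid",
    "write_ascii_grid",
    "build_resistance",
    "least_cost_path",
    "effective_distance",
    "resistance_distance",
    "euclidean_matrix",
    "suitability",
    "distance_bundle",
]

log = logging.getLogger(__name__)

#: land-cover category codes
CATEGORIES = {
    1: "meadow",
    2: "orchard",
    3: "pasture_grassland",
    4: "annual_crop",
    5: "shrub",
    6: "eucalyptus",
    7: "deciduous_woodlot",
    8: "settlement_road",
    9: "water",
}

#: movement cost per category: 1 for favourable grass habitats, 25 for
#: crops/shrubs, 50 for built surfaces, 1000 for woods and water
DEFAULT_COST_VALUES = {1: 1.0, 2: 1.0, 3: 1.0, 4: 25.0, 5: 25.0, 6: 1000.0, 7: 1000.0, 8: 50.0, 9: 1000.0}

#: categories counted as suitable habitat in the SH/TL ratio
SUITABLE_CATEGORIES = frozenset({1, 2, 3})

SQRT2 = math.sqrt(2.0)


@dataclass
class CategoryGrid:
    """Rectangular grid of land-cover category codes (row 0 = north edge)."""

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)  # (easting, northing) lower-left corner

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def validate_categories(self) -> None:
        bad = set(np.unique(self.data)) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown category code(s): {sorted(bad)}")

    # georeferencing helpers -------------------------------------------------
    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        nrows = self.data.shape[0]
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 + (nrows - 1 - row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of every cell centre, grid-shaped."""
        x0, y0 = self.origin
        nrows, ncols = self.data.shape
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - 1 - np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def nearest_cell(self, easting: float, northing: float) -> tuple[int, int]:
        """Snap a point to the nearest cell centre (ties toward smaller indices)."""
        x0, y0 = self.origin
        nrows, ncols = self.data.shape
        col = int(np.clip(np.floor((easting - x0) / self.cell_size), 0, ncols - 1))
        row_from_bottom = int(
            np.clip(np.floor((northing - y0) / self.cell_size), 0, nrows - 1)
        )
        return nrows - 1 - row_from_bottom, col


@dataclass
class ElevationGrid(CategoryGrid):
    """Digital elevation model on the same lattice convention (metres)."""

    def validate_categories(self) -> None:  # pragma: no cover - not categorical
        raise NotImplementedError("elevation grids have no categories")


ResistanceGrid = CategoryGrid  # same container, float CV payload


@dataclass
class Path8:
    """An 8-connected lattice path with its accumulated Dijkstra cost."""

    cells: list[tuple[int, int]]
    accumulated_cost: float
    cell_size: float

    def __post_init__(self) -> None:
        for (r1, c1), (r2, c2) in zip(self.cells, self.cells[1:]):
            if max(abs(r1 - r2), abs(c1 - c2)) != 1:
                raise ValueError("consecutive path cells must be 8-neighbours")

    @property
    def step_lengths(self) -> np.ndarray:
        """Metric length of each move (cell_size or cell_size*sqrt(2))."""
        if len(self.cells) < 2:
            return np.empty(0)
        cells = np.asarray(self.cells)
        diag = (np.abs(np.diff(cells, axis=0)) == 1).all(axis=1)
        return self.cell_size * np.where(diag, SQRT2, 1.0)

    @property
    def metric_length(self) -> float:
        return float(self.step_lengths.sum())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------


def read_ascii_grid(path: str | Path, as_elevation: bool = False) -> CategoryGrid:
    """Read an ESRI ASCII (.asc) grid.

    Category grids must not contain NODATA cells; elevation grids may.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"missing ASCII grid header field {key!r}")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    cls = ElevationGrid if as_elevation else CategoryGrid
    if not as_elevation:
        if nodata is not None and (data == nodata).any():
            raise ValueError("NODATA cells are not supported in category grids")
        data = data.astype(np.int64)
    grid = cls(
        data=data,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )
    return grid


def write_ascii_grid(grid: CategoryGrid, path: str | Path, nodata: float = -9999) -> None:
    nrows, ncols = grid.data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    body = "\n".join(
        " ".join(
            str(int(v)) if float(v).is_integer() else repr(float(v))
            for v in row
        )
        for row in grid.data
    )
    Path(path).write_text(header + body + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Resistance surface and least-cost paths
# ---------------------------------------------------------------------------


def build_resistance(grid: CategoryGrid, cv: dict[int, float] | None = None) -> ResistanceGrid:
    """Elementwise category -> cost-value lookup."""
    cv = DEFAULT_COST_VALUES if cv is None else cv
    if any(v < 1 for v in cv.values()):
        raise ValueError("cost values must be >= 1")
    cats = np.unique(grid.data)
    unmapped = [int(c) for c in cats if int(c) not in cv]
    if unmapped:
        raise KeyError(f"no cost value for category code(s) {unmapped}")
    lut = np.zeros(int(cats.max()) + 1)
    for c, v in cv.items():
        if c <= cats.max():
            lut[c] = v
    return CategoryGrid(
        data=lut[grid.data.astype(np.int64)],
        cell_size=grid.cell_size,
        origin=grid.origin,
    )


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _dijkstra(res: ResistanceGrid, src: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Single-source Dijkstra over the 8-neighbour lattice.

    Returns (cost, predecessor) flat arrays.  Ties in the priority queue are
    broken toward the lexicographically smaller cell, making the recovered
    path deterministic.
    """
    cvv = res.data
    nrows, ncols = cvv.shape
    n = nrows * ncols
    cost = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=np.int64)
    s = src[0] * ncols + src[1]
    cost[s] = 0.0
    heap: list[tuple[float, int]] = [(0.0, s)]
    done = np.zeros(n, dtype=bool)
    half = res.cell_size * 0.5
    while heap:
        c, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        ur, uc = divmod(u, ncols)
        cv_u = cvv[ur, uc]
        for dr, dc in _NBRS:
            vr, vc = ur + dr, uc + dc
            if not (0 <= vr < nrows and 0 <= vc < ncols):
                continue
            v = vr * ncols + vc
            if done[v]:
                continue
            d = SQRT2 if dr and dc else 1.0
            w = d * half * (cv_u + cvv[vr, vc])
            nc = c + w
            if nc < cost[v] - 1e-12 or (
                abs(nc - cost[v]) <= 1e-12 and u < pred[v]
            ):
                cost[v] = nc
                pred[v] = u
                heapq.heappush(heap, (nc, v))
    return cost, pred


def _extract_path(
    pred: np.ndarray, src: tuple[int, int], dst: tuple[int, int], ncols: int
) -> list[tuple[int, int]]:
    s = src[0] * ncols + src[1]
    d = dst[0] * ncols + dst[1]
    cells = [d]
    while cells[-1] != s:
        p = int(pred[cells[-1]])
        if p < 0:
            raise RuntimeError("destination unreachable")
        cells.append(p)
    return [divmod(c, ncols) for c in reversed(cells)]


def least_cost_path(
    res: ResistanceGrid, src_cell: tuple[int, int], dst_cell: tuple[int, int]
) -> Path8:
    """Least-cost path between two cells on the resistance surface."""
    nrows, ncols = res.data.shape
    for r, c in (src_cell, dst_cell):
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise IndexError(f"cell {(r, c)} outside {res.data.shape} grid")
    if src_cell == dst_cell:
        return Path8(cells=[tuple(src_cell)], accumulated_cost=0.0, cell_size=res.cell_size)
    cost, pred = _dijkstra(res, tuple(src_cell))
    d = dst_cell[0] * ncols + dst_cell[1]
    if not np.isfinite(cost[d]):
        raise RuntimeError("destination unreachable")
    cells = _extract_path(pred, tuple(src_cell), tuple(dst_cell), ncols)
    return Path8(cells=cells, accumulated_cost=float(cost[d]), cell_size=res.cell_size)


def effective_distance(path: Path8, dem: ElevationGrid | None = None) -> float:
    """Metric path length in metres; with a DEM each step is the 3-D hypotenuse."""
    steps = path.step_lengths
    if dem is None:
        return float(steps.sum())
    cells = np.asarray(path.cells)
    elev = dem.data[cells[:, 0], cells[:, 1]]
    dz = np.diff(elev)
    return float(np.sqrt(steps**2 + dz**2).sum())


def resistance_distance(
    path: Path8,
    grid: CategoryGrid,
    cv: dict[int, float] | None = None,
    dem: ElevationGrid | None = None,
) -> float:
    """Sum of (patch length in km) x (patch cost value) along the path.

    Each move's length is split half-and-half between the categories of its
    two endpoint cells, so the per-patch lengths ``m_i`` add up exactly to
    the path's metric length.
    """
    cv = DEFAULT_COST_VALUES if cv is None else cv
    if len(path.cells) < 2:
        return 0.0
    cells = np.asarray(path.cells)
    cats = grid.data[cells[:, 0], cells[:, 1]]
    steps = path.step_lengths
    if dem is not None:
        elev = dem.data[cells[:, 0], cells[:, 1]]
        steps = np.sqrt(steps**2 + np.diff(elev) ** 2)
    cell_len_m = np.zeros(len(cells))
    cell_len_m[:-1] += steps / 2.0
    cell_len_m[1:] += steps / 2.0
    cvs = np.array([cv[int(c)] for c in cats])
    return float((cell_len_m / 1000.0 * cvs).sum())


# ---------------------------------------------------------------------------
# Deme-level distance matrices
# ---------------------------------------------------------------------------


def euclidean_matrix(demes: list[DemeInfo]) -> pd.DataFrame:
    """Pairwise straight-line deme distances in kilometres."""
    if len(demes) < 2:
        raise ValueError("need at least 2 demes")
    xy = np.array([[d.easting, d.northing] for d in demes])
    diff = xy[:, None, :] - xy[None, :, :]
    km = np.sqrt((diff**2).sum(-1)) / 1000.0
    names = [d.name for d in demes]
    return pd.DataFrame(km, index=names, columns=names)


def suitability(
    deme_a: DemeInfo,
    deme_b: DemeInfo,
    grid: CategoryGrid,
    suitable: frozenset[int] | set[int] = SUITABLE_CATEGORIES,
) -> float:
    """Suitable-habitat fraction in the two-disc lens, per km of separation.

    Both discs are centred on a deme with radius equal to the pair's
    Euclidean distance; a cell belongs to the lens when its centre is within
    both discs.  Returns ``(SH/TL) / d_km``; NaN when the lens misses the
    grid entirely.
    """
    ax, ay = deme_a.easting, deme_a.northing
    bx, by = deme_b.easting, deme_b.northing
    r = math.hypot(ax - bx, ay - by)
    if r == 0:
        raise ValueError("demes must be distinct")
    X, Y = grid.cell_centers()
    in_lens = ((X - ax) ** 2 + (Y - ay) ** 2 <= r**2) & (
        (X - bx) ** 2 + (Y - by) ** 2 <= r**2
    )
    total = int(in_lens.sum())
    if total == 0:
        return float("nan")
    sh = int(np.isin(grid.data, list(suitable))[in_lens].sum())
    return (sh / total) / (r / 1000.0)


@dataclass
class DistanceBundle:
    """The four pairwise deme matrices driving the Mantel analyses."""

    euclidean_km: pd.DataFrame
    effective_km: pd.DataFrame
    resistance: pd.DataFrame
    suitability_per_km: pd.DataFrame

    def to_tsv(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        for name in ("euclidean_km", "effective_km", "resistance", "suitability_per_km"):
            p = directory / f"distance_{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", lineterminator="\n")
            out[name] = p
        return out


def distance_bundle(
    demes: list[DemeInfo],
    grid: CategoryGrid,
    cv: dict[int, float] | None = None,
    dem: ElevationGrid | None = None,
    suitable: frozenset[int] | set[int] = SUITABLE_CATEGORIES,
) -> DistanceBundle:
    """All four deme x deme matrices (deme locations snapped to cell centres)."""
    cv = DEFAULT_COST_VALUES if cv is None else cv
    if dem is not None and dem.data.shape != grid.data.shape:
        raise ValueError("DEM shape does not match category grid")
    names = [d.name for d in demes]
    D = len(demes)
    res = build_resistance(grid, cv)
    cells = [grid.nearest_cell(d.easting, d.northing) for d in demes]
    eff = np.zeros((D, D))
    rst = np.zeros((D, D))
    suit = np.full((D, D), np.nan)
    ncols = grid.data.shape[1]
    for i in range(D):
        cost, pred = _dijkstra(res, cells[i])
        for j in range(D):
            if j == i:
                continue
            try:
                path_cells = _extract_path(pred, cells[i], cells[j], ncols)
                path = Path8(
                    cells=path_cells,
                    accumulated_cost=float(cost[cells[j][0] * ncols + cells[j][1]]),
                    cell_size=grid.cell_size,
                )
                eff[i, j] = effective_distance(path, dem) / 1000.0
                rst[i, j] = resistance_distance(path, grid, cv, dem)
            except RuntimeError as exc:  # masked / unreachable
                log.warning("no path %s -> %s: %s", names[i], names[j], exc)
                eff[i, j] = rst[i, j] = np.nan
    # symmetrise LCP results (Dijkstra is symmetric up to tie-breaks)
    eff = (eff + eff.T) / 2.0
    rst = (rst + rst.T) / 2.0
    for i in range(D):
        for j in range(i + 1, D):
            s = suitability(demes[i], demes[j], grid, suitable)
            suit[i, j] = suit[j, i] = s
    return DistanceBundle(
        euclidean_km=euclidean_matrix(demes),
        effective_km=pd.DataFrame(eff, index=names, columns=names),
        resistance=pd.DataFrame(rst, index=names, columns=names),
        suitability_per_km=pd.DataFrame(suit, index=names, columns=names),
    )
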