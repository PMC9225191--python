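"""Resistance surfaces, least-cost paths, distances and the lens suitability."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from arvicola import landscape as ls
from arvicola.genio import DemeInfo
from arvicola.synthdata import study_demes

SQRT2 = math.sqrt(2.0)


# ---------------------------------------------------------------------------
# ASCII grid I/O
# ---------------------------------------------------------------------------


def test_ascii_grid_roundtrip(tmp_path):
    grid = ls.CategoryGrid(
        np.array([[1, 2, 9], [4, 5, 1]]), cell_size=5.0, origin=(100.0, 200.0)
    )
    p = tmp_path / "g.asc"
    ls.write_ascii_grid(grid, p)
    back = ls.read_ascii_grid(p)
    assert np.array_equal(back.data, grid.data)
    assert back.cell_size == 5.0 and back.origin == (100.0, 200.0)


def test_ascii_grid_header_mismatch_raises(tmp_path):
    p = tmp_path / "bad.asc"
    p.write_text("ncols 3\nnrows 2\ncellsize 5\n1 2 3\n")
    with pytest.raises(ValueError):
        ls.read_ascii_grid(p)


def test_category_grid_nodata_rejected(tmp_path):
    p = tmp_path / "nd.asc"
    p.write_text("ncols 2\nnrows 1\ncellsize 5\nNODATA_value -9999\n1 -9999\n")
    with pytest.raises(ValueError):
        ls.read_ascii_grid(p)


# ---------------------------------------------------------------------------
# resistance surface
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("cat, cv", [(1, 1.0), (9, 1000.0)])
def test_uniform_grid_maps_to_uniform_cost(cat, cv):
    grid = ls.CategoryGrid(np.full((4, 4), cat), cell_size=5.0)
    res = ls.build_resistance(grid)
    assert (res.data == cv).all()


def test_mixed_grid_elementwise_lookup():
    grid = ls.CategoryGrid(np.array([[1, 4], [8, 9]]), cell_size=5.0)
    res = ls.build_resistance(grid)
    assert res.data.tolist() == [[1.0, 25.0], [50.0, 1000.0]]


def test_unmapped_category_raises():
    grid = ls.CategoryGrid(np.array([[1, 2]]), cell_size=5.0)
    with pytest.raises(KeyError):
        ls.build_resistance(grid, cv={1: 1.0})


# ---------------------------------------------------------------------------
# least-cost paths
# ---------------------------------------------------------------------------


def test_uniform_surface_diagonal_path():
    res = ls.CategoryGrid(np.ones((5, 5)), cell_size=1.0)
    path = ls.least_cost_path(res, (0, 0), (4, 4))
    assert path.accumulated_cost == pytest.approx(4 * SQRT2)
    assert path.cells[0] == (0, 0) and path.cells[-1] == (4, 4)
    assert len(path.cells) == 5  # pure diagonal


def test_single_cell_path_zero_cost():
    res = ls.CategoryGrid(np.ones((3, 3)), cell_size=1.0)
    path = ls.least_cost_path(res, (1, 1), (1, 1))
    assert path.cells == [(1, 1)] and path.accumulated_cost == 0.0


def _nx_cost(cv: np.ndarray, cell_size: float, src, dst) -> float:
    g = nx.Graph()
    nrows, ncols = cv.shape
    for i in range(nrows):
        for j in range(ncols):
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < nrows and 0 <= nj < ncols:
                        d = SQRT2 if di and dj else 1.0
                        g.add_edge(
                            (i, j), (ni, nj),
                            w=cell_size * d * (cv[i, j] + cv[ni, nj]) / 2.0,
                        )
    return nx.shortest_path_length(g, src, dst, weight="w")


def test_wall_with_gap_matches_dijkstra_oracle():
    cv = np.ones((7, 7))
    cv[:, 3] = 1000.0
    cv[3, 3] = 1.0
    res = ls.CategoryGrid(cv, cell_size=1.0)
    path = ls.least_cost_path(res, (0, 0), (0, 6))
    assert (3, 3) in path.cells
    assert path.accumulated_cost == pytest.approx(_nx_cost(cv, 1.0, (0, 0), (0, 6)))


def test_random_grids_match_oracle(rng):
    """Accumulated cost equals an independent shortest-path oracle."""
    for _ in range(60):
        n = int(rng.integers(4, 11))
        cv = rng.choice([1.0, 25.0, 50.0, 1000.0], size=(n, n))
        res = ls.CategoryGrid(cv, cell_size=5.0)
        src = (int(rng.integers(n)), int(rng.integers(n)))
        dst = (int(rng.integers(n)), int(rng.integers(n)))
        got = ls.least_cost_path(res, src, dst).accumulated_cost
        want = 0.0 if src == dst else _nx_cost(cv, 5.0, src, dst)
        assert got == pytest.approx(want)


def test_raising_cost_never_shortens_paths(rng):
    cv = rng.choice([1.0, 25.0], size=(8, 8))
    res = ls.CategoryGrid(cv.copy(), cell_size=1.0)
    base = ls.least_cost_path(res, (0, 0), (7, 7)).accumulated_cost
    cv2 = cv.copy()
    cv2[cv2 == 25.0] = 1000.0
    res2 = ls.CategoryGrid(cv2, cell_size=1.0)
    raised = ls.least_cost_path(res2, (0, 0), (7, 7)).accumulated_cost
    assert raised >= base - 1e-9


# ---------------------------------------------------------------------------
# effective and resistance distance
# ---------------------------------------------------------------------------


@pytest.fixture
def rook_path():
    return ls.Path8(
        cells=[(0, 0), (0, 1), (0, 2), (0, 3), (0, 4)],
        accumulated_cost=0.0,
        cell_size=5.0,
    )


def test_effective_distance_flat(rook_path):
    assert ls.effective_distance(rook_path) == pytest.approx(20.0)


def test_effective_distance_with_slope(rook_path):
    dem = ls.ElevationGrid(np.tile(np.arange(5) * 5.0, (5, 1)), cell_size=5.0)
    assert ls.effective_distance(rook_path, dem) == pytest.approx(4 * math.sqrt(50))


def test_flat_dem_equals_no_dem(rook_path):
    dem = ls.ElevationGrid(np.full((5, 5), 42.0), cell_size=5.0)
    assert ls.effective_distance(rook_path, dem) == ls.effective_distance(rook_path)


def test_resistance_distance_single_patch(rook_path):
    grid = ls.CategoryGrid(np.ones((5, 5), dtype=int), cell_size=5.0)
    # 20 m of meadow (CV 1) = 0.02 km * 1
    assert ls.resistance_distance(rook_path, grid) == pytest.approx(0.02)


def test_resistance_distance_two_patch_formula():
    # straight 1200 m path: 1000 m meadow (CV 1) + 200 m annual crop (CV 25)
    cells = [(0, j) for j in range(13)]
    path = ls.Path8(cells=cells, accumulated_cost=0.0, cell_size=100.0)
    row = [1] * 10 + [4] * 3
    grid = ls.CategoryGrid(np.tile(row, (1, 1)), cell_size=100.0)
    got = ls.resistance_distance(path, grid)
    # boundary step (cell 9 -> 10) splits half/half between the categories
    m_meadow = (9 + 0.5) * 0.1
    m_crop = (2 + 0.5) * 0.1
    assert got == pytest.approx(m_meadow * 1 + m_crop * 25)


def test_resistance_distance_matches_per_cell_oracle(rng):
    cv_map = ls.DEFAULT_COST_VALUES
    cats = rng.integers(1, 10, size=(10, 10))
    grid = ls.CategoryGrid(cats, cell_size=5.0)
    res = ls.build_resistance(grid)
    path = ls.least_cost_path(res, (0, 0), (9, 9))
    got = ls.resistance_distance(path, grid)
    # oracle: each cell's length is half of each incident step
    lengths = np.zeros(len(path.cells))
    for s, ((r1, c1), (r2, c2)) in enumerate(zip(path.cells, path.cells[1:])):
        d = 5.0 * (SQRT2 if (r1 != r2 and c1 != c2) else 1.0)
        lengths[s] += d / 2
        lengths[s + 1] += d / 2
    want = sum(
        l / 1000.0 * cv_map[int(cats[r, c])]
        for l, (r, c) in zip(lengths, path.cells)
    )
    assert got == pytest.approx(want)


# ---------------------------------------------------------------------------
# Euclidean geometry of the published coordinates
# ---------------------------------------------------------------------------


def test_euclidean_matrix_from_published_coordinates():
    em = ls.euclidean_matrix(study_demes())
    assert em.iloc[8, 9] == pytest.approx(math.hypot(925, 529) / 1000)
    assert em.iloc[8, 9] == pytest.approx(1.0656, abs=1e-4)
    assert em.iloc[0, 9] == pytest.approx(20.299, abs=1e-3)
    assert np.all(np.diag(em.to_numpy()) == 0)


def test_coincident_demes_zero_distance():
    demes = [DemeInfo("a", 0, 5.0, 5.0), DemeInfo("b", 1, 5.0, 5.0)]
    assert ls.euclidean_matrix(demes).iloc[0, 1] == 0.0


# ---------------------------------------------------------------------------
# lens suitability
# ---------------------------------------------------------------------------


def test_suitability_full_and_empty_lens():
    a = DemeInfo("a", 0, 1000.0, 2500.0)
    b = DemeInfo("b", 1, 3000.0, 2500.0)
    meadow = ls.CategoryGrid(np.ones((100, 100), dtype=int), cell_size=50.0)
    water = ls.CategoryGrid(np.full((100, 100), 9), cell_size=50.0)
    assert ls.suitability(a, b, meadow) == pytest.approx(0.5)  # SH/TL=1, d=2 km
    assert ls.suitability(a, b, water) == 0.0


def test_suitability_striped_grid_matches_point_in_lens_oracle():
    data = np.ones((60, 60), dtype=int)
    data[:, ::2] = 9  # alternate suitable / water columns
    grid = ls.CategoryGrid(data, cell_size=50.0, origin=(0.0, 0.0))
    a = DemeInfo("a", 0, 700.0, 1500.0)
    b = DemeInfo("b", 1, 2300.0, 1600.0)
    r = math.hypot(b.easting - a.easting, b.northing - a.northing)
    sh = tl = 0
    for row in range(60):
        for col in range(60):
            x, y = grid.cell_center(row, col)
            if (x - a.easting) ** 2 + (y - a.northing) ** 2 <= r**2 and (
                x - b.easting
            ) ** 2 + (y - b.northing) ** 2 <= r**2:
                tl += 1
                sh += data[row, col] in (1, 2, 3)
    want = (sh / tl) / (r / 1000.0)
    assert ls.suitability(a, b, grid) == pytest.approx(want)


def test_suitability_off_grid_lens_is_nan():
    grid = ls.CategoryGrid(np.ones((4, 4), dtype=int), cell_size=10.0)
    a = DemeInfo("a", 0, 100000.0, 100000.0)
    b = DemeInfo("b", 1, 100010.0, 100000.0)
    assert math.isnan(ls.suitability(a, b, grid))


def test_identical_demes_rejected():
    grid = ls.CategoryGrid(np.ones((4, 4), dtype=int), cell_size=10.0)
    a = DemeInfo("a", 0, 10.0, 10.0)
    with pytest.raises(ValueError):
        ls.suitability(a, a, grid)


# ---------------------------------------------------------------------------
# distance bundle
# ---------------------------------------------------------------------------


def test_bundle_on_uniform_landscape(rng):
    grid = ls.CategoryGrid(np.ones((60, 60), dtype=int), cell_size=50.0)
    demes = [
        DemeInfo("a", 0, 300.0, 400.0),
        DemeInfo("b", 1, 2500.0, 2200.0),
        DemeInfo("c", 2, 700.0, 2600.0),
    ]
    bundle = ls.distance_bundle(demes, grid)
    e = bundle.euclidean_km.to_numpy()
    f = bundle.effective_km.to_numpy()
    r = bundle.resistance.to_numpy()
    tri = np.tril_indices(3, -1)
    # octile elongation bound on a uniform surface (allow one cell of snap)
    snap = 2 * 50.0 * SQRT2 / 1000.0
    assert np.all(f[tri] <= 1.083 * e[tri] + snap)
    assert np.all(f[tri] >= e[tri] - snap)
    # CV >= 1 everywhere makes resistance at least the Euclidean km
    assert np.all(r[tri] >= e[tri] - snap)
    assert np.all(np.diag(f) == 0) and np.all(np.diag(r) == 0)


def test_bundle_two_demes_shape():
    grid = ls.CategoryGrid(np.ones((20, 20), dtype=int), cell_size=50.0)
    demes = [DemeInfo("a", 0, 100.0, 100.0), DemeInfo("b", 1, 800.0, 800.0)]
    bundle = ls.distance_bundle(demes, grid)
    for m in (bundle.euclidean_km, bundle.effective_km, bundle.resistance):
        assert m.shape == (2, 2)
        assert m.iloc[0, 1] == m.iloc[1, 0]
    assert math.isnan(bundle.suitability_per_km.iloc[0, 0])
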