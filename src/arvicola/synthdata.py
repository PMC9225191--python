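"""Synthetic landscapes and forward-simulated microsatellite genotypes.

Every analysis stage in this package can be exercised without downloads:
this module generates (i) multi-category land-cover mosaics statistically
resembling a fine-grained enclosed-field (bocage) agro-ecosystem with
roughly 30% suitable grass habitat, and (ii) diploid microsatellite
genotypes from a forward Wright–Fisher simulation with stepwise mutation
and migration that can follow an island, stepping-stone or
cost-distance-decay model.  The generator returns its ground truth
(migration matrix, expected equilibrium differentiation, cluster
membership) so parameter-recovery tests can compare estimates to it.

``study_fixture_dataset`` produces a full study-shaped dataset: ten demes with
the published sample sizes (18, 14, 14, 11, 12, 14, 14, 15, 14, 11 — 137
voles), real orchard coordinates, 11 loci, simulated under cost-decay
migration on a generated landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genio import DemeInfo, GenotypeDataset, Locus
from .landscape import (
    SUITABLE_CATEGORIES,
    CategoryGrid,
    distance_bundle,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "STUDY_DEMES",
    "generate_landscape",
    "place_demes",
    "simulate_genotypes",
    "island_fst_expectation",
    "study_fixture_dataset",
    "study_demes",
]

#: Published per-deme survey metadata of the ten-orchard study system:
#: (name, sample date, UTM easting, UTM northing, area in ha, N genotyped).
STUDY_DEMES: list[tuple[str, str, float, float, float, int]] = [
    ("Vegadali", "2011-09", 298049, 4804471, 2.31, 18),
    ("Ceceda", "2012-12", 302152, 4803618, 5.95, 14),
    ("Fresnadiello", "2011-06", 302809, 4805229, 2.84, 14),
    ("Poreno", "2012-07", 301923, 4812449, 7.58, 11),
    ("Serida", "2011-06", 302393, 4816492, 7.26, 12),
    ("Priesca", "2011-04", 309079, 4817418, 2.03, 14),
    ("Rozada", "2012-03", 305277, 4820835, 2.99, 14),
    ("Oles", "2011-06", 301922, 4822568, 4.55, 15),
    ("Telena", "2012-07", 304030, 4823030, 1.13, 14),
    ("Marina", "2012-07", 304955, 4823559, 1.00, 11),
]


def study_demes() -> list[DemeInfo]:
    """The ten study demes as :class:`DemeInfo` (order defines indices)."""
    return [
        DemeInfo(name=n, index=i, easting=x, northing=y, area_ha=a, sample_date=dt, n=nn)
        for i, (n, dt, x, y, a, nn) in enumerate(STUDY_DEMES)
    ]


@dataclass
class SimConfig:
    """Parameters of the landscape + genotype generator.

    Defaults emulate the study conditions: ten demes of 11-18 voles, 11
    microsatellite loci with several alleles each, moderate differentiation
    (theta in roughly 0-0.3) with isolation by distance, and a mosaic
    landscape with ~30% suitable habitat.
    """

    # landscape
    shape: tuple[int, int] = (250, 250)
    cell_size: float = 50.0
    mixture: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.18, 2: 0.06, 3: 0.06, 4: 0.18, 5: 0.08,
            6: 0.12, 7: 0.22, 8: 0.06, 9: 0.04,
        }
    )
    patch_scale: float = 6.0  # expected patch diameter in cells
    origin: tuple[float, float] = (0.0, 0.0)
    # demography
    n_demes: int = 10
    sample_sizes: tuple[int, ...] = (18, 14, 14, 11, 12, 14, 14, 15, 14, 11)
    n_loci: int = 11
    n_alleles: int = 8
    mutation_rate: float = 5e-4
    n_e: int = 100
    migration_model: str = "cost_decay"  # island | stepping_stone | cost_decay
    m0: float = 0.15
    decay: float = 0.3  # per unit cost distance (here: per km of LCP length)
    n_generations: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        s = sum(self.mixture.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {s}, expected 1")
        for r in (self.mutation_rate, self.m0):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SyntheticTruth:
    migration: np.ndarray  # row-stochastic parent-origin matrix
    expected_fst: float  # island closed form (NaN for non-island models)
    coords: np.ndarray  # (n_demes, 2) metres
    cluster_truth: np.ndarray  # deme -> generating cluster (demes themselves)
    n_generations: int
    seed: int


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def generate_landscape(config: SimConfig) -> CategoryGrid:
    """Seeded region-growth mosaic: nearest Poisson seed labels each cell.

    Seed intensity is matched to ``patch_scale`` (one seed per
    patch_scale^2 cells on average) and seed categories are drawn from the
    mixture, so realized category proportions track the request for grids
    of a few hundred cells a side.
    """
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    n_cells = nrows * ncols
    n_seeds = max(int(round(n_cells / config.patch_scale**2)), len(config.mixture))
    seeds = rng.random((n_seeds, 2)) * [nrows, ncols]
    cats = np.array(sorted(config.mixture))
    probs = np.array([config.mixture[c] for c in cats])
    seed_cat = rng.choice(cats, size=n_seeds, p=probs)
    from scipy.spatial import cKDTree

    rr, cc = np.meshgrid(np.arange(nrows) + 0.5, np.arange(ncols) + 0.5, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    _, nearest = cKDTree(seeds).query(pts)
    data = seed_cat[nearest].reshape(nrows, ncols)
    return CategoryGrid(data=data, cell_size=config.cell_size, origin=config.origin)


def place_demes(
    grid: CategoryGrid,
    n_demes: int,
    min_separation_m: float,
    seed: int | None = 0,
    max_tries: int = 10000,
) -> list[DemeInfo]:
    """Deme centres on suitable cells, pairwise separation >= threshold."""
    rng = np.random.default_rng(seed)
    suitable = np.argwhere(np.isin(grid.data, list(SUITABLE_CATEGORIES)))
    if suitable.size == 0:
        raise ValueError("no suitable cells to place demes on")
    chosen: list[tuple[float, float]] = []
    tries = 0
    while len(chosen) < n_demes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place demes; lower min_separation_m or enlarge the grid"
            )
        r, c = suitable[rng.integers(len(suitable))]
        x, y = grid.cell_center(int(r), int(c))
        if all((x - px) ** 2 + (y - py) ** 2 >= min_separation_m**2 for px, py in chosen):
            chosen.append((x, y))
    return [
        DemeInfo(name=f"deme{i + 1}", index=i, easting=x, northing=y)
        for i, (x, y) in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# Forward Wright-Fisher genotypes
# ---------------------------------------------------------------------------


def _migration_matrix(config: SimConfig, cost_distances: np.ndarray | None) -> np.ndarray:
    d = config.n_demes
    m = np.zeros((d, d))
    if config.migration_model == "island":
        off = config.m0 / (d - 1) if d > 1 else 0.0
        m[:] = off
    elif config.migration_model == "stepping_stone":
        for i in range(d):
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < d]
            for j in nbrs:
                m[i, j] = config.m0 / 2.0
    elif config.migration_model == "cost_decay":
        if cost_distances is None:
            raise ValueError("cost_decay migration needs a cost-distance matrix")
        m = config.m0 * np.exp(-config.decay * np.asarray(cost_distances, float))
        np.fill_diagonal(m, 0.0)
        # cap total emigration at m0, keeping the absolute distance decay
        rows = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            m = np.where(rows > config.m0, config.m0 * m / rows, m)
    else:
        raise ValueError(f"unknown migration model {config.migration_model!r}")
    np.fill_diagonal(m, 0.0)
    if (m.sum(axis=1) > 1 + 1e-9).any():
        raise ValueError("migration row sum exceeds 1")
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


def island_fst_expectation(n_e: int, m: float, n_demes: int) -> float:
    """Finite-island equilibrium approximation for Weir–Cockerham theta.

    ``1 / (1 + 4 N_e m d/(d-1))`` with total emigration rate ``m``.  From
    the structured coalescent: a within-deme pair has mean coalescence time
    ``2 N_e d`` generations, a between-deme pair needs ``(d-1)/(2m)`` extra
    generations to co-locate, and theta estimates ``1 - T_within/T_between``.
    """
    d = n_demes
    if d < 2 or m <= 0:
        return float("nan")
    return 1.0 / (1.0 + 4.0 * n_e * m * d / (d - 1.0))


def simulate_genotypes(
    demes: list[DemeInfo],
    cost_distances: np.ndarray | None,
    config: SimConfig,
) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Forward Wright–Fisher simulation of diploid microsatellite demes.

    Each generation every deme draws 2*N_e gene copies: the parent deme of
    each copy follows the migration matrix row, the parent individual is
    uniform within that deme, the transmitted allele is a random one of the
    parent's two, mutated stepwise (+-1 repeat) with the configured rate.
    Allele states are repeat numbers offset into a fragment-size-like range
    (~100-300).  Sampled individuals are drawn without replacement at the
    final generation.
    """
    d = len(demes)
    if d != config.n_demes:
        config = replace(config, n_demes=d)
    if len(config.sample_sizes) != d:
        raise ValueError("sample_sizes length must match deme count")
    rng = np.random.default_rng(config.seed)
    mig = _migration_matrix(config, cost_distances)
    n_e, L = config.n_e, config.n_loci
    # initial standing variation: per locus, alleles around a random center
    centers = rng.integers(60, 140, size=L)
    pop = np.empty((d, n_e, L, 2), dtype=np.int64)
    half = config.n_alleles // 2
    pop[:] = centers[None, None, :, None] + rng.integers(
        -half, half + 1, size=(d, n_e, L, 2)
    )
    for _ in range(config.n_generations):
        # parent deme for every new gene copy
        src = np.empty((d, n_e, L, 2), dtype=np.int64)
        for i in range(d):
            src[i] = rng.choice(d, size=(n_e, L, 2), p=mig[i])
        parent = rng.integers(0, n_e, size=(d, n_e, L, 2))
        which = rng.integers(0, 2, size=(d, n_e, L, 2))
        locus_idx = np.broadcast_to(np.arange(L)[None, None, :, None], src.shape)
        new = pop[src, parent, locus_idx, which]
        mut = rng.random(new.shape) < config.mutation_rate
        step = rng.choice([-1, 1], size=new.shape)
        new = np.where(mut, new + step, new)
        pop = new
    # sample individuals
    loci = [Locus(f"L{l + 1:02d}") for l in range(L)]
    calls = []
    individuals = []
    out_demes = []
    for i, deme in enumerate(demes):
        n_s = config.sample_sizes[i]
        if n_s > n_e:
            raise ValueError("sample size exceeds N_e")
        pick = rng.choice(n_e, size=n_s, replace=False)
        for j, ind in enumerate(pick):
            individuals.append((f"{deme.name}_{j + 1:02d}", i, None))
            calls.append(pop[i, ind])
        out_demes.append(replace(deme, index=i, n=n_s))
    dataset = GenotypeDataset(
        loci=loci,
        demes=out_demes,
        individuals=individuals,
        calls=np.array(calls),
    )
    if config.migration_model == "island":
        exp_fst = island_fst_expectation(n_e, config.m0, d)
    else:
        exp_fst = float("nan")
    truth = SyntheticTruth(
        migration=mig,
        expected_fst=exp_fst,
        coords=np.array([[p.easting, p.northing] for p in demes]),
        cluster_truth=np.arange(d),
        n_generations=config.n_generations,
        seed=config.seed,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Study-shaped fixture
# ---------------------------------------------------------------------------


def study_fixture_dataset(
    seed: int = 0, config: SimConfig | None = None
) -> tuple[GenotypeDataset, list[DemeInfo], CategoryGrid, SyntheticTruth]:
    """A full study-shaped synthetic dataset on a generated landscape.

    Ten demes at the published orchard coordinates with the published
    sample sizes (total 137), 11 loci, cost-decay migration computed from
    least-cost-path resistance distances across the generated mosaic.
    """
    demes = study_demes()
    xs = [d.easting for d in demes]
    ys = [d.northing for d in demes]
    pad = 1000.0
    cell = 100.0
    ncols = int((max(xs) - min(xs) + 2 * pad) // cell) + 1
    nrows = int((max(ys) - min(ys) + 2 * pad) // cell) + 1
    base = SimConfig(seed=seed) if config is None else replace(config, seed=seed)
    cfg = replace(
        base,
        shape=(nrows, ncols),
        cell_size=cell,
        origin=(min(xs) - pad, min(ys) - pad),
        n_demes=10,
        sample_sizes=(18, 14, 14, 11, 12, 14, 14, 15, 14, 11),
        n_loci=11,
    )
    grid = generate_landscape(cfg)
    bundle = distance_bundle(demes, grid)
    # migration decays with the least-cost-path length between demes, so the
    # generated mosaic shapes gene flow (detours around high-cost patches)
    dataset, truth = simulate_genotypes(
        demes, bundle.effective_km.to_numpy(), cfg
    )
    return dataset, demes, grid, truth
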