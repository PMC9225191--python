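"""Shared fixtures: tiny hand-built datasets and one session-scoped
study-shaped synthetic dataset (expensive pieces computed once)."""

from __future__ import annotations

import numpy as np
import pytest

from arvicola.genio import DemeInfo, GenotypeDataset, Locus


def make_dataset(
    deme_calls: list[np.ndarray],
    locus_names: list[str] | None = None,
    coords: list[tuple[float, float]] | None = None,
) -> GenotypeDataset:
    """Build a dataset from per-deme call arrays of shape (n_i, L, 2)."""
    deme_calls = [np.asarray(c, dtype=np.int64) for c in deme_calls]
    L = deme_calls[0].shape[1]
    locus_names = locus_names or [f"L{l + 1}" for l in range(L)]
    demes, individuals, calls = [], [], []
    for d, block in enumerate(deme_calls):
        x, y = coords[d] if coords else (1000.0 * d, 0.0)
        demes.append(
            DemeInfo(name=f"deme{d + 1}", index=d, easting=x, northing=y, n=block.shape[0])
        )
        for i in range(block.shape[0]):
            individuals.append((f"d{d + 1}_{i + 1}", d, None))
            calls.append(block[i])
    return GenotypeDataset(
        loci=[Locus(n) for n in locus_names],
        demes=demes,
        individuals=individuals,
        calls=np.array(calls),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def two_fixed_demes():
    """Two demes fixed for alternate alleles at two loci: theta must be 1."""
    a = np.full((6, 2, 2), 101)
    b = np.full((6, 2, 2), 102)
    return make_dataset([a, b])


@pytest.fixture(scope="session")
def three_deme_toy():
    """Printed 3-deme, 2-locus toy used against the independent WC oracle."""
    d1 = np.array(
        [[[1, 1], [3, 4]], [[1, 2], [3, 3]], [[2, 2], [4, 4]], [[1, 1], [3, 4]]]
    )
    d2 = np.array(
        [[[1, 2], [3, 3]], [[2, 2], [3, 4]], [[2, 2], [3, 3]], [[1, 2], [4, 4]]]
    )
    d3 = np.array(
        [[[1, 1], [4, 4]], [[1, 1], [3, 4]], [[1, 2], [4, 4]], [[2, 2], [4, 4]]]
    )
    return make_dataset([d1, d2, d3])


@pytest.fixture(scope="session")
def island_dataset():
    """Two-island simulation with strong structure for clustering tests."""
    from arvicola.synthdata import SimConfig, simulate_genotypes

    cfg = SimConfig(
        n_demes=2,
        sample_sizes=(30, 30),
        n_loci=20,
        n_e=100,
        migration_model="island",
        m0=0.005,
        n_generations=300,
        seed=3,
    )
    demes = [DemeInfo("A", 0, 0.0, 0.0), DemeInfo("B", 1, 10000.0, 0.0)]
    return simulate_genotypes(demes, None, cfg)


@pytest.fixture(scope="session")
def study_fixture():
    """Study-shaped synthetic dataset (10 demes, 137 voles, 11 loci, grid)."""
    from arvicola.synthdata import study_fixture_dataset

    return study_fixture_dataset(seed=11)
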