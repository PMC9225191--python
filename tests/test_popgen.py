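"""Diversity and differentiation statistics against independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from arvicola import genio, popgen
from conftest import make_dataset


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequencies_basic_counts():
    ds = make_dataset([np.array([[[1, 1]], [[1, 2]]])])
    af = popgen.allele_frequencies(ds)
    assert af.freqs[("deme1", "L1")] == {1: 0.75, 2: 0.25}
    assert af.size[("deme1", "L1")] == 4


def test_allele_frequencies_all_missing_cell():
    ds = make_dataset([np.array([[[0, 0]], [[0, 0]]])])
    af = popgen.allele_frequencies(ds)
    assert af.size[("deme1", "L1")] == 0
    assert af.freqs[("deme1", "L1")] == {}


def test_pooled_frequencies_equal_direct_counts(rng):
    blocks = [rng.integers(1, 5, size=(4, 2, 2)), rng.integers(1, 5, size=(6, 2, 2))]
    ds = make_dataset(blocks)
    pooled = popgen.allele_frequencies(ds, grouping="pooled")
    for l, locus in enumerate(["L1", "L2"]):
        alleles = np.concatenate([b[:, l, :].ravel() for b in blocks])
        codes, counts = np.unique(alleles, return_counts=True)
        expected = {int(c): n / alleles.size for c, n in zip(codes, counts)}
        assert pooled.freqs[("all", locus)] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def test_monomorphic_locus_diversity():
    ds = make_dataset([np.full((5, 1, 2), 7)])
    stats = popgen.diversity_stats(ds)
    row = stats.iloc[0]
    assert row["H_E"] == 0 and row["H_O"] == 0 and row["A_R"] == 1 and row["N_A"] == 1


def test_rarefaction_equals_exhaustive_subsample_enumeration(rng):
    """A_R at g copies = mean allele count over all C(2n, g) subsamples."""
    calls = rng.integers(1, 5, size=(4, 1, 2))
    ds = make_dataset([calls])
    g = 4
    stats = popgen.diversity_stats(ds, rarefaction_copies=g)
    copies = calls[:, 0, :].ravel()
    counts = [len(set(sub)) for sub in itertools.combinations(copies, g)]
    assert stats.iloc[0]["A_R"] == pytest.approx(np.mean(counts))


def test_rarefaction_identity_at_minimum_sample(rng):
    """The deme whose size sets g has A_R exactly equal to N_A."""
    blocks = [rng.integers(1, 8, size=(5, 3, 2)), rng.integers(1, 8, size=(9, 3, 2))]
    ds = make_dataset(blocks)
    stats = popgen.diversity_stats(ds)  # g defaults to 2 * min sample = 10
    assert stats.iloc[0]["A_R"] == pytest.approx(stats.iloc[0]["N_A"])
    assert stats.iloc[1]["A_R"] <= stats.iloc[1]["N_A"] + 1e-12


def test_rarefaction_size_must_be_at_least_two(two_fixed_demes):
    with pytest.raises(ValueError):
        popgen.diversity_stats(two_fixed_demes, rarefaction_copies=1)


def test_heterozygosity_invariant_under_allele_relabeling(rng):
    calls = rng.integers(1, 5, size=(8, 2, 2))
    ds = make_dataset([calls])
    relabel = {1: 104, 2: 98, 3: 240, 4: 7}
    ds2 = make_dataset([np.vectorize(relabel.get)(calls)])
    a = popgen.diversity_stats(ds, rarefaction_copies=4)
    b = popgen.diversity_stats(ds2, rarefaction_copies=4)
    for col in ("N_A", "A_R", "H_O", "H_E", "F_IS"):
        assert a.iloc[0][col] == pytest.approx(b.iloc[0][col], nan_ok=True)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_oracle(ds) -> float:
    """Independent textbook implementation of multilocus theta.

    Written directly from the variance-component definitions, looping over
    loci and alleles with no shared code with the package internals.
    """
    deme_of = ds.deme_index_per_individual
    num = den = 0.0
    for l in range(ds.n_loci):
        present = ~ds.missing_mask[:, l]
        pops = [np.flatnonzero((deme_of == d) & present) for d in range(ds.n_demes)]
        pops = [p for p in pops if p.size > 0]
        r = len(pops)
        if r < 2:
            continue
        alleles = sorted(set(ds.calls[present, l, :].ravel()))
        if len(alleles) < 2:
            continue
        n_i = np.array([p.size for p in pops], dtype=float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for allele in alleles:
            p_i = np.array(
                [(ds.calls[p, l, :] == allele).sum() / (2 * p.size) for p in pops]
            )
            h_i = np.array(
                [
                    np.mean(
                        [
                            (allele in ds.calls[i, l]) and ds.calls[i, l, 0] != ds.calls[i, l, 1]
                            for i in p
                        ]
                    )
                    for p in pops
                ]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def test_theta_is_one_for_fixed_different_demes(two_fixed_demes):
    res = popgen.fst_overall(two_fixed_demes, n_boot=10, seed=0)
    assert res.overall == pytest.approx(1.0)


def test_theta_near_zero_for_identical_frequency_demes(rng):
    blocks = [rng.integers(1, 5, size=(50, 5, 2)), rng.integers(1, 5, size=(50, 5, 2))]
    ds = make_dataset(blocks)
    res = popgen.fst_overall(ds, n_boot=10, seed=0)
    assert abs(res.overall) < 0.02


def test_theta_matches_independent_oracle(three_deme_toy):
    res = popgen.fst_overall(three_deme_toy, n_boot=10, seed=0)
    assert res.overall == pytest.approx(_wc_oracle(three_deme_toy), abs=1e-12)


def test_pairwise_theta_matches_oracle_per_pair(three_deme_toy):
    fm = popgen.fst_matrix(three_deme_toy, n_perm=10, seed=0)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        sub = make_dataset(
            [
                three_deme_toy.calls[three_deme_toy.deme_members(i)],
                three_deme_toy.calls[three_deme_toy.deme_members(j)],
            ]
        )
        assert fm.theta.iloc[i, j] == pytest.approx(_wc_oracle(sub), abs=1e-12)
    assert np.allclose(fm.theta.to_numpy(), fm.theta.to_numpy().T)
    assert np.all(np.diag(fm.theta.to_numpy()) == 0)


def test_theta_invariant_under_locus_order(three_deme_toy):
    flipped = three_deme_toy.subset_loci(["L2", "L1"])
    assert popgen.fst_overall(flipped, n_boot=5, seed=0).overall == pytest.approx(
        popgen.fst_overall(three_deme_toy, n_boot=5, seed=0).overall
    )


def test_permutation_pvalues_in_open_unit_interval(three_deme_toy):
    fm = popgen.fst_matrix(three_deme_toy, n_perm=49, seed=0)
    tri = np.tril_indices(3, -1)
    p = fm.p_values.to_numpy()[tri]
    assert np.all(p > 0) and np.all(p <= 1)


def test_bootstrap_degenerate_cases(two_fixed_demes):
    res = popgen.fst_overall(two_fixed_demes, n_boot=1, seed=0)
    assert res.ci[0] == pytest.approx(res.ci[1])  # single replicate CI
    single = two_fixed_demes.subset_loci(["L1"])
    assert popgen.fst_overall(single, n_boot=100, seed=0).ci is None


def test_small_deme_pair_flagged_na():
    ds = make_dataset([np.full((1, 1, 2), 1), np.full((4, 1, 2), 2)])
    fm = popgen.fst_matrix(ds, n_perm=5, seed=0)
    assert np.isnan(fm.theta.iloc[0, 1])


# ---------------------------------------------------------------------------
# linearisation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "x, expected",
    [(0.5, 1.0), (0.0, 0.0), (-0.01, -0.01 / 1.01)],
)
def test_linearized_fst_formula(x, expected):
    m = np.array([[0.0, x], [x, 0.0]])
    assert popgen.linearized_fst(m)[0, 1] == pytest.approx(expected)


def test_linearized_fst_rejects_unit_entries():
    with pytest.raises(ValueError):
        popgen.linearized_fst(np.array([[0.0, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _levene_probability(n_aa: int, n_ab: int, n_bb: int) -> float:
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    return (
        math.factorial(n)
        / (math.factorial(n_aa) * math.factorial(n_ab) * math.factorial(n_bb))
        * 2**n_ab
        * math.factorial(na)
        * math.factorial(nb)
        / math.factorial(2 * n)
    )


def test_hwe_enumeration_matches_levene_oracle():
    """All-heterozygote sample vs complete enumeration of biallelic tables."""
    ds = make_dataset([np.tile([1, 2], (5, 1, 1)).reshape(5, 1, 2)])
    res = popgen.hwe_test(ds, 0, 0)
    assert res.method == "enumeration"
    tables = [
        ((5 - h) // 2, h, (5 - h) // 2) for h in (1, 3, 5)
    ]  # margins (5,5) force n_aa = n_bb
    probs = {t: _levene_probability(*t) for t in tables}
    p_obs = probs[(0, 5, 0)]
    expected = sum(v for v in probs.values() if v <= p_obs + 1e-12)
    assert res.p == pytest.approx(expected)


def test_hwe_monomorphic_is_one():
    ds = make_dataset([np.full((4, 1, 2), 3)])
    assert popgen.hwe_test(ds, 0, 0).p == 1.0


def test_hwe_mc_agrees_with_enumeration(rng):
    calls = rng.integers(1, 4, size=(10, 1, 2))
    ds = make_dataset([calls])
    exact = popgen.hwe_test(ds, 0, 0, method="enumeration")
    n_mc = 20000
    mc = popgen.hwe_test(ds, 0, 0, method="mc", n_mc=n_mc, seed=1)
    se = math.sqrt(exact.p * (1 - exact.p) / n_mc)
    assert abs(mc.p - exact.p) < 3 * se + 2 / n_mc


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _duplicated_locus_dataset(rng, n=30):
    a = rng.integers(1, 5, size=(n, 1, 2))
    calls = np.concatenate([a, a], axis=1)  # locus 2 is a copy of locus 1
    return make_dataset([calls], locus_names=["orig", "copy"])


def test_duplicated_locus_hits_permutation_floor(rng):
    ds = _duplicated_locus_dataset(rng)
    n_perm = 99
    res = popgen.ld_test(ds, "orig", "copy", n_perm=n_perm, seed=0)
    assert res.p <= 1 / (n_perm + 1) + 1e-9


def test_single_deme_global_p_equals_per_deme_p(rng):
    ds = _duplicated_locus_dataset(rng)
    res = popgen.ld_test(ds, 0, 1, n_perm=99, seed=0)
    # Fisher's method on one p returns that p
    assert res.method == "fisher"
    assert res.p == pytest.approx(1 / 100, rel=1e-6)


def test_ld_filter_drops_fewer_allele_member(rng):
    base = rng.integers(1, 9, size=(40, 1, 2))  # 8 alleles
    collapsed = np.minimum(base, 5)  # same signal, 5 alleles
    other = rng.integers(1, 6, size=(40, 1, 2))
    calls = np.concatenate([base, collapsed, other], axis=1)
    ds = make_dataset([calls], locus_names=["rich", "poor", "free"])
    filtered, dropped = popgen.ld_filter(ds, alpha=0.001, n_perm=2999, seed=0)
    assert dropped == ["poor"]
    assert [l.name for l in filtered.loci] == ["rich", "free"]


def test_ld_filter_keeps_independent_loci(rng):
    calls = rng.integers(1, 5, size=(30, 3, 2))
    ds = make_dataset([calls])
    filtered, dropped = popgen.ld_filter(ds, alpha=0.001, n_perm=199, seed=0)
    assert dropped == [] and filtered is ds


def test_ld_type_one_error_calibrated(rng):
    """Independent loci at equilibrium are rejected at ~ the nominal rate."""
    n_rep, alpha, n_perm = 200, 0.05, 99
    hits = 0
    for _ in range(n_rep):
        calls = rng.integers(1, 4, size=(25, 2, 2))
        ds = make_dataset([calls])
        res = popgen.ld_test(ds, 0, 1, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
        hits += res.p < alpha
    rate = hits / n_rep
    se = math.sqrt(alpha * (1 - alpha) / n_rep)
    assert abs(rate - alpha) < 3 * se


# ---------------------------------------------------------------------------
# F_IS permutation test
# ---------------------------------------------------------------------------


def test_fis_test_detects_heterozygote_deficit(rng):
    hom = rng.integers(1, 5, size=(20, 3, 1))
    calls = np.concatenate([hom, hom], axis=2)  # fully homozygous deme
    ds = make_dataset([calls])
    res = popgen.fis_test(ds, 0, n_perm=199, seed=0)
    assert res.statistic == pytest.approx(1.0)
    assert res.p < 0.05
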