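"""Diversity and differentiation statistics for microsatellite demes.

Implements the population-genetic layer of the pipeline:

* allele frequency tables (per deme or pooled),
* per-deme diversity: mean allele number ``N_A``, rarefied allelic richness
  ``A_R`` (hypergeometric rarefaction to a common number of gene copies),
  observed and Nei's unbiased expected heterozygosity, Weir–Cockerham
  ``f`` (F_IS) and a multi-locus Hardy–Weinberg exact p per deme,
* Weir–Cockerham theta (F_ST): pairwise with permutation p-values, and the
  overall multilocus estimate with a bootstrap-over-loci confidence interval,
* exact Hardy–Weinberg tests (probability ordering; complete enumeration of
  genotype tables when feasible, otherwise Monte Carlo),
* genotypic linkage-disequilibrium tests (per-deme G statistic with
  permutation p, demes combined by Fisher's method) and the resulting
  locus-exclusion filter that drops the less informative member of each
  significantly linked locus pair.

Negative theta estimates are reported as computed, never truncated;
``linearized_fst`` passes them through so that downstream matrix
regressions are not biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .genio import GenotypeDataset

__all__ = [
    "AlleleFreqTable",
    "FstResult",
    "PairTestResult",
    "allele_frequencies",
    "diversity_stats",
    "fst_matrix",
    "fst_overall",
    "linearized_fst",
    "hwe_test",
    "ld_test",
    "ld_filter",
    "fis_test",
]


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Relative allele frequencies per (group, locus) with gene-copy counts.

    ``freqs[(group, locus)]`` maps allele code -> relative frequency among
    non-missing gene copies; ``size[(group, locus)]`` is the number of gene
    copies counted (0 flags an empty cell, whose map is empty).
    """

    freqs: dict[tuple[str, str], dict[int, float]]
    size: dict[tuple[str, str], int]
    groups: list[str]
    loci: list[str]


def allele_frequencies(
    dataset: GenotypeDataset, grouping: Literal["demes", "pooled"] = "demes"
) -> AlleleFreqTable:
    """Count allele frequencies, excluding missing calls."""
    if grouping == "demes":
        group_names = [d.name for d in dataset.demes]
        group_of = dataset.deme_index_per_individual
    elif grouping == "pooled":
        group_names = ["all"]
        group_of = np.zeros(dataset.n_individuals, dtype=int)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    freqs: dict[tuple[str, str], dict[int, float]] = {}
    size: dict[tuple[str, str], int] = {}
    miss = dataset.missing_mask
    for g, gname in enumerate(group_names):
        members = np.flatnonzero(group_of == g)
        for l, locus in enumerate(dataset.loci):
            ok = members[~miss[members, l]]
            alleles = dataset.calls[ok, l, :].ravel()
            size[(gname, locus.name)] = alleles.size
            if alleles.size == 0:
                freqs[(gname, locus.name)] = {}
                continue
            codes, counts = np.unique(alleles, return_counts=True)
            freqs[(gname, locus.name)] = {
                int(c): float(n) / alleles.size for c, n in zip(codes, counts)
            }
    return AlleleFreqTable(freqs=freqs, size=size, groups=group_names, loci=[l.name for l in dataset.loci])


# ---------------------------------------------------------------------------
# Dense per-locus encoding shared by the estimators
# ---------------------------------------------------------------------------


@dataclass
class _Encoded:
    """Per-locus dense allele encoding of a dataset.

    For locus ``l`` with ``k_l`` distinct alleles: ``X[l]`` is the
    (n_individuals, k_l) allele dosage matrix (0/1/2, zero rows where
    missing), ``H[l]`` marks carried-while-heterozygous alleles and
    ``present[l]`` is the non-missing indicator.
    """

    X: list[np.ndarray]
    H: list[np.ndarray]
    present: np.ndarray  # (n_individuals, n_loci) bool
    alleles: list[np.ndarray]  # original codes per locus


def _encode(dataset: GenotypeDataset) -> _Encoded:
    n, L = dataset.n_individuals, dataset.n_loci
    present = ~dataset.missing_mask
    X, H, alleles = [], [], []
    for l in range(L):
        calls = dataset.calls[:, l, :]
        ok = present[:, l]
        codes = np.unique(calls[ok].ravel()) if ok.any() else np.empty(0, dtype=np.int64)
        alleles.append(codes)
        k = codes.size
        x = np.zeros((n, k), dtype=np.float64)
        h = np.zeros((n, k), dtype=np.float64)
        if k:
            a = np.searchsorted(codes, calls[ok, 0])
            b = np.searchsorted(codes, calls[ok, 1])
            rows = np.flatnonzero(ok)
            np.add.at(x, (rows, a), 1.0)
            np.add.at(x, (rows, b), 1.0)
            het = calls[ok, 0] != calls[ok, 1]
            hr = rows[het]
            h[hr, a[het]] = 1.0
            h[hr, b[het]] = 1.0
        X.append(x)
        H.append(h)
    return _Encoded(X=X, H=H, present=present, alleles=alleles)


def _wc_per_locus(
    enc: _Encoded, group_of: np.ndarray, n_groups: int, loci: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components summed over alleles, per locus.

    Returns arrays (a, b, c) of length len(loci); loci where fewer than two
    groups have data contribute NaN.
    """
    loci = list(range(len(enc.X))) if loci is None else loci
    G = np.zeros((n_groups, len(group_of)))
    G[group_of, np.arange(len(group_of))] = 1.0
    a_out = np.full(len(loci), np.nan)
    b_out = np.full(len(loci), np.nan)
    c_out = np.full(len(loci), np.nan)
    for out_i, l in enumerate(loci):
        x, h = enc.X[l], enc.H[l]
        if x.shape[1] < 2:
            # monomorphic locus: no information, contributes zero components
            a_out[out_i] = b_out[out_i] = c_out[out_i] = 0.0
            continue
        n_i = G @ enc.present[:, l].astype(float)  # individuals per group
        use = n_i > 0
        r = int(use.sum())
        if r < 1 or (n_groups >= 2 and r < 2):
            continue
        n_i = n_i[use]
        if r == 1:
            # single group: only the within-group components b and c exist
            n1 = n_i[0]
            if n1 <= 1:
                continue
            counts1 = (G @ x)[use][0]
            hets1 = (G @ h)[use][0]
            p1 = counts1 / (2.0 * n1)
            h1 = hets1 / n1
            b1 = (n1 / (n1 - 1)) * (p1 * (1 - p1) - (2 * n1 - 1) / (4 * n1) * h1)
            a_out[out_i] = 0.0
            b_out[out_i] = b1.sum()
            c_out[out_i] = (h1 / 2.0).sum()
            continue
        counts = (G @ x)[use]  # (r, k) allele counts
        hets = (G @ h)[use]
        p_i = counts / (2.0 * n_i[:, None])
        h_i = hets / n_i[:, None]
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n_i[:, None] * p_i).sum(0) / (r * nbar)
        s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (n_i[:, None] * h_i).sum(0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        a_out[out_i], b_out[out_i], c_out[out_i] = a.sum(), b.sum(), c.sum()
    return a_out, b_out, c_out


def _theta_from_components(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele number in a hypergeometric subsample of g gene copies."""
    n = int(counts.sum())
    if g > n:
        return float("nan")
    tot = 0.0
    for c in counts:
        c = int(c)
        if n - c < g:
            tot += 1.0
        else:
            tot += 1.0 - math.exp(
                _lchoose(n - c, g) - _lchoose(n, g)
            )
    return tot


def _lchoose(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def diversity_stats(
    dataset: GenotypeDataset,
    rarefaction_copies: int | None = None,
    hwe_n_mc: int = 10000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-deme diversity table mirroring the classic summary layout.

    Columns: ``N`` (individuals), ``N_A`` (mean alleles per locus), ``A_R``
    (allelic richness rarefied to ``rarefaction_copies`` gene copies;
    default twice the smallest per-(deme, locus) sample), ``H_O``, ``H_E``
    (Nei unbiased), ``F_IS`` (Weir–Cockerham f) and ``HWE_p`` (per-locus
    exact tests combined over loci by Fisher's method).
    """
    enc = _encode(dataset)
    deme_of = dataset.deme_index_per_individual
    D, L = dataset.n_demes, dataset.n_loci

    n_dl = np.zeros((D, L), dtype=int)  # non-missing individuals
    for d in range(D):
        members = dataset.deme_members(d)
        n_dl[d] = enc.present[members].sum(0)
    g = rarefaction_copies
    if g is None:
        positive = n_dl[n_dl > 0]
        g = 2 * int(positive.min()) if positive.size else 2
    if g < 2:
        raise ValueError("rarefaction_copies must be >= 2")

    rng = np.random.default_rng(seed)
    rows = []
    for d in range(D):
        members = dataset.deme_members(d)
        na, ar, ho, he = [], [], [], []
        hwe_ps = []
        for l in range(L):
            ok = members[enc.present[members, l]]
            if ok.size == 0:
                continue
            counts = enc.X[l][ok].sum(0)
            counts = counts[counts > 0]
            n2 = int(counts.sum())
            na.append(counts.size)
            ar.append(_rarefied_richness(counts, g) if g <= n2 else np.nan)
            p = counts / n2
            he.append((n2 / (n2 - 1)) * (1 - (p**2).sum()) if n2 > 1 else 0.0)
            het = (
                dataset.calls[ok, l, 0] != dataset.calls[ok, l, 1]
            ).mean()
            ho.append(float(het))
            if counts.size > 1:
                hwe_ps.append(
                    hwe_test(
                        dataset, d, l, n_mc=hwe_n_mc,
                        seed=int(rng.integers(2**31 - 1)),
                    ).p
                )
        # Weir-Cockerham f for a single deme
        sub_group = np.zeros(members.size, dtype=int)
        sub = _subset_encoding(enc, members)
        _, b, c = _wc_per_locus(sub, sub_group, 1)
        fis = _fis_from_components(b, c)
        if hwe_ps:
            stat = -2.0 * np.log(np.clip(hwe_ps, 1e-300, 1.0)).sum()
            hwe_p = float(chi2.sf(stat, 2 * len(hwe_ps)))
        else:
            hwe_p = float("nan")
        rows.append(
            {
                "deme": dataset.demes[d].name,
                "N": members.size,
                "N_A": float(np.mean(na)) if na else np.nan,
                "A_R": float(np.nanmean(ar)) if ar else np.nan,
                "H_O": float(np.mean(ho)) if ho else np.nan,
                "H_E": float(np.mean(he)) if he else np.nan,
                "F_IS": fis,
                "HWE_p": hwe_p,
            }
        )
    return pd.DataFrame(rows).set_index("deme")


def _subset_encoding(enc: _Encoded, members: np.ndarray) -> _Encoded:
    return _Encoded(
        X=[x[members] for x in enc.X],
        H=[h[members] for h in enc.H],
        present=enc.present[members],
        alleles=enc.alleles,
    )


def _fis_from_components(b: np.ndarray, c: np.ndarray) -> float:
    """Single-group Weir–Cockerham f = 1 - sum(c)/sum(b+c)."""
    ok = np.isfinite(b)
    denom = (b[ok] + c[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - c[ok].sum() / denom)


def fis_test(
    dataset: GenotypeDataset,
    deme: int,
    n_perm: int = 10000,
    seed: int | None = 0,
) -> "PairTestResult":
    """Two-sided permutation test of F_IS within one deme.

    Gene copies are shuffled among the deme's non-missing individuals per
    locus, destroying within-individual allele correlation under the null.
    """
    enc = _encode(dataset)
    members = dataset.deme_members(deme)
    calls = dataset.calls[members].copy()
    miss = dataset.missing_mask[members]
    sub = _subset_encoding(enc, members)
    zeros = np.zeros(members.size, dtype=int)
    _, b, c = _wc_per_locus(sub, zeros, 1)
    f_obs = _fis_from_components(b, c)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_calls = calls.copy()
        for l in range(dataset.n_loci):
            ok = np.flatnonzero(~miss[:, l])
            copies = calls[ok, l, :].ravel()
            rng.shuffle(copies)
            perm_calls[ok, l, :] = np.sort(copies.reshape(-1, 2), axis=1)
        perm_ds = GenotypeDataset(
            loci=list(dataset.loci),
            demes=[dataset.demes[deme]],
            individuals=[(f"i{i}", 0, None) for i in range(members.size)],
            calls=perm_calls,
        )
        pe = _encode(perm_ds)
        _, b2, c2 = _wc_per_locus(pe, zeros, 1)
        f_star = _fis_from_components(b2, c2)
        if np.isfinite(f_star) and abs(f_star) >= abs(f_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PairTestResult(labels=(dataset.demes[deme].name, "F_IS"), statistic=f_obs, p=p, method="MC")


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    """Pairwise and overall Weir–Cockerham theta."""

    theta: pd.DataFrame | None = None  # deme x deme
    p_values: pd.DataFrame | None = None
    overall: float = float("nan")
    ci: tuple[float, float] | None = None
    ci_level: float = 0.95
    per_locus: pd.DataFrame | None = None


def fst_matrix(
    dataset: GenotypeDataset, n_perm: int = 1000, seed: int | None = 0
) -> FstResult:
    """Pairwise theta with permutation p-values.

    p is one-sided: the fraction of label permutations between the two demes
    whose theta is at least the observed (add-one rule).  Pairs where either
    deme has fewer than two individuals are NA.
    """
    if dataset.n_demes < 2:
        raise ValueError("need at least 2 demes")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    enc = _encode(dataset)
    deme_of = dataset.deme_index_per_individual
    D = dataset.n_demes
    names = [d.name for d in dataset.demes]
    theta = np.full((D, D), 0.0)
    pvals = np.full((D, D), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(D):
        for j in range(i + 1, D):
            mi, mj = dataset.deme_members(i), dataset.deme_members(j)
            if mi.size < 2 or mj.size < 2:
                theta[i, j] = theta[j, i] = np.nan
                continue
            members = np.concatenate([mi, mj])
            sub = _subset_encoding(enc, members)
            labels = np.concatenate([np.zeros(mi.size, int), np.ones(mj.size, int)])
            a, b, c = _wc_per_locus(sub, labels, 2)
            t_obs = _theta_from_components(a, b, c)
            theta[i, j] = theta[j, i] = t_obs
            if not np.isfinite(t_obs):
                continue
            hits = 0
            lab = labels.copy()
            for _ in range(n_perm):
                rng.shuffle(lab)
                a2, b2, c2 = _wc_per_locus(sub, lab, 2)
                t_star = _theta_from_components(a2, b2, c2)
                if np.isfinite(t_star) and t_star >= t_obs - 1e-12:
                    hits += 1
            pvals[i, j] = pvals[j, i] = (1 + hits) / (n_perm + 1)
    return FstResult(
        theta=pd.DataFrame(theta, index=names, columns=names),
        p_values=pd.DataFrame(pvals, index=names, columns=names),
    )


def fst_overall(
    dataset: GenotypeDataset,
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> FstResult:
    """Overall multilocus theta with a percentile bootstrap-over-loci CI."""
    enc = _encode(dataset)
    deme_of = dataset.deme_index_per_individual
    a, b, c = _wc_per_locus(enc, deme_of, dataset.n_demes)
    overall = _theta_from_components(a, b, c)
    per_locus = pd.DataFrame(
        {"locus": [l.name for l in dataset.loci], "a": a, "b": b, "c": c}
    ).set_index("locus")
    ok = np.isfinite(a)
    a, b, c = a[ok], b[ok], c[ok]
    L = a.size
    if L < 2:
        ci = None
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, L, size=(n_boot, L))
        num = a[idx].sum(axis=1)
        den = (a + b + c)[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = num / den
        boots = boots[np.isfinite(boots)]
        if boots.size == 0:
            ci = None
        else:
            alpha = (1 - ci_level) / 2
            ci = (
                float(np.quantile(boots, alpha)),
                float(np.quantile(boots, 1 - alpha)),
            )
    return FstResult(overall=overall, ci=ci, ci_level=ci_level, per_locus=per_locus)


def linearized_fst(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise x / (1 - x); negative estimates pass through unchanged."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if np.nanmax(values) >= 1.0:
        raise ValueError("linearized_fst undefined for entries >= 1")
    out = values / (1.0 - values)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------


@dataclass
class PairTestResult:
    labels: tuple
    statistic: float
    p: float
    method: str  # "enumeration" | "MC" | "fisher"


_MAX_ENUM_TABLES = 100_000


def _genotype_counts(dataset: GenotypeDataset, deme: int, locus: int):
    members = dataset.deme_members(deme)
    ok = members[~dataset.missing_mask[members, locus]]
    calls = dataset.calls[ok, locus, :]
    codes = np.unique(calls.ravel())
    k = codes.size
    table = np.zeros((k, k), dtype=int)
    a = np.searchsorted(codes, calls[:, 0])
    b = np.searchsorted(codes, calls[:, 1])
    for x, y in zip(a, b):
        table[min(x, y), max(x, y)] += 1
    return table, codes


def _table_logprob_var(table: np.ndarray, lgamma_cache: np.ndarray) -> float:
    """Variable part of the conditional table probability: H*ln2 - sum(ln g!)."""
    het = table.sum() - np.trace(table)
    g = table[np.triu_indices_from(table)]
    return float(het * math.log(2.0) - lgamma_cache[g].sum())


def hwe_test(
    dataset: GenotypeDataset,
    deme: int,
    locus: int,
    method: Literal["auto", "enumeration", "mc"] = "auto",
    n_mc: int = 10000,
    seed: int | None = 0,
) -> PairTestResult:
    """Exact Hardy–Weinberg test with probability ordering.

    The p-value is the total conditional probability (given allele counts)
    of genotype tables no more probable than the observed one.  Complete
    enumeration is used when the table count stays below 1e5, otherwise
    tables are sampled by randomly pairing the observed gene copies
    (Guo–Thompson style Monte Carlo, add-one rule).
    """
    table, codes = _genotype_counts(dataset, deme, locus)
    n = int(table.sum())
    if n < 1:
        raise ValueError("no non-missing calls")
    if codes.size < 2:
        return PairTestResult((deme, locus), 0.0, 1.0, "enumeration")
    allele_counts = table.sum(axis=0) + table.sum(axis=1)  # margins incl diagonal twice
    k = codes.size
    lg = gammaln(np.arange(2 * n + 2) + 1.0)
    obs_var = _table_logprob_var(table, lg)

    tables: list[float] | None = None
    if method in ("auto", "enumeration"):
        # enumeration is worthwhile only for few alleles; with many alleles
        # the table count explodes and the cap would be burned in recursion
        feasible = k <= 3 or (k == 4 and n <= 16)
        if method == "enumeration" or feasible:
            tables = _enumerate_tables(
                allele_counts, lg, cap=_MAX_ENUM_TABLES if method == "auto" else None
            )
    if tables is not None:
        # normalise over the enumerated distribution
        logps = np.array(tables)
        logZ = _logsumexp(logps)
        probs = np.exp(logps - logZ)
        p = float(probs[logps <= obs_var + 1e-9].sum())
        return PairTestResult((deme, locus), obs_var, min(p, 1.0), "enumeration")

    # Monte Carlo: random pairings of the observed gene copies, vectorised
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(k), allele_counts)
    perms = rng.permuted(np.tile(copies, (n_mc, 1)), axis=1)
    lo = np.minimum(perms[:, 0::2], perms[:, 1::2])
    hi = np.maximum(perms[:, 0::2], perms[:, 1::2])
    code = lo * k + hi
    ncodes = k * k
    rows = np.repeat(np.arange(n_mc), lo.shape[1])
    counts = np.bincount(
        rows * ncodes + code.ravel(), minlength=n_mc * ncodes
    ).reshape(n_mc, ncodes)
    het = (lo != hi).sum(axis=1)
    var = het * math.log(2.0) - lg[counts].sum(axis=1)
    hits = int((var <= obs_var + 1e-9).sum())
    p = (1 + hits) / (n_mc + 1)
    return PairTestResult((deme, locus), obs_var, p, "MC")


def _enumerate_tables(
    allele_counts: np.ndarray, lg: np.ndarray, cap: int | None
) -> list[float] | None:
    """All genotype tables with the given allele margins; log-prob variable
    part per table.  Returns None if the cap is exceeded."""
    k = allele_counts.size
    rem = allele_counts.astype(int).copy()
    out: list[float] = []
    log2 = math.log(2.0)
    overflow = False

    def rec(i: int, het: int, slog: float) -> None:
        nonlocal overflow
        if overflow:
            return
        if i == k:
            out.append(het * log2 - slog)
            if cap is not None and len(out) > cap:
                overflow = True
            return
        total_i = rem[i]
        for hom in range(total_i // 2 + 1):
            spread(i, i + 1, total_i - 2 * hom, het, slog + lg[hom])
            if overflow:
                return

    def spread(i: int, j: int, left: int, het: int, slog: float) -> None:
        # distribute `left` copies of allele i over heterozygotes (i, j > i)
        nonlocal overflow
        if overflow:
            return
        if j == k:
            if left == 0:
                saved = rem[i]
                rem[i] = 0
                rec(i + 1, het, slog)
                rem[i] = saved
            return
        for gij in range(min(left, rem[j]) + 1):
            rem[j] -= gij
            spread(i, j + 1, left - gij, het + gij, slog + lg[gij])
            rem[j] += gij
            if overflow:
                return

    rec(0, 0, 0.0)
    if overflow:
        return None
    return out


def _logsumexp(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def _g_statistic(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_test(
    dataset: GenotypeDataset,
    locus_a: int | str,
    locus_b: int | str,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> PairTestResult:
    """Genotypic linkage-disequilibrium test for one locus pair.

    Within each deme the genotype x genotype contingency table gets a
    log-likelihood-ratio G statistic whose null distribution is obtained by
    permuting one locus's genotypes among the deme's individuals; per-deme
    p-values are combined across demes with Fisher's method.
    """
    names = [l.name for l in dataset.loci]
    la = names.index(locus_a) if isinstance(locus_a, str) else locus_a
    lb = names.index(locus_b) if isinstance(locus_b, str) else locus_b
    rng = np.random.default_rng(seed)
    per_deme_p = []
    g_total = 0.0
    miss = dataset.missing_mask
    for d in range(dataset.n_demes):
        members = dataset.deme_members(d)
        ok = members[~miss[members, la] & ~miss[members, lb]]
        if ok.size < 2:
            continue
        ga = [tuple(c) for c in dataset.calls[ok, la, :]]
        gb = [tuple(c) for c in dataset.calls[ok, lb, :]]
        if len(set(ga)) < 2 or len(set(gb)) < 2:
            continue
        cat_a = {g: i for i, g in enumerate(sorted(set(ga)))}
        cat_b = {g: i for i, g in enumerate(sorted(set(gb)))}
        ia = np.array([cat_a[g] for g in ga])
        ib = np.array([cat_b[g] for g in gb])
        table = np.zeros((len(cat_a), len(cat_b)), dtype=int)
        np.add.at(table, (ia, ib), 1)
        g_obs = _g_statistic(table)
        g_total += g_obs
        hits = 0
        perm = ib.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            t = np.zeros_like(table)
            np.add.at(t, (ia, perm), 1)
            if _g_statistic(t) >= g_obs - 1e-12:
                hits += 1
        per_deme_p.append((1 + hits) / (n_perm + 1))
    if not per_deme_p:
        return PairTestResult((names[la], names[lb]), float("nan"), float("nan"), "fisher")
    stat = -2.0 * np.log(per_deme_p).sum()
    p = float(chi2.sf(stat, 2 * len(per_deme_p)))
    # Fisher's chi2 can underflow to 0 with extreme per-deme p; clamp by the
    # permutation resolution so p stays in (0, 1]
    floor = np.prod([min(q, 1.0) for q in per_deme_p]) * 0.0 + 1e-300
    p = max(p, floor)
    return PairTestResult((names[la], names[lb]), g_total, p, "fisher")


def ld_filter(
    dataset: GenotypeDataset,
    alpha: float = 0.001,
    n_perm: int = 2000,
    seed: int | None = 0,
) -> tuple[GenotypeDataset, list[str]]:
    """Drop the less informative member of each significantly linked pair.

    All locus pairs are tested; pairs with global p < ``alpha`` are visited
    in ascending-p order and, where both members survive so far, the locus
    with fewer distinct alleles is removed (ties: the later locus in file
    order).  Mirrors the practice of excluding redundant linked markers
    before downstream structure analyses.
    """
    names = [l.name for l in dataset.loci]
    enc = _encode(dataset)
    n_alleles = {names[l]: enc.alleles[l].size for l in range(dataset.n_loci)}
    rng = np.random.default_rng(seed)
    results = []
    for i in range(dataset.n_loci):
        for j in range(i + 1, dataset.n_loci):
            res = ld_test(dataset, i, j, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
            if np.isfinite(res.p):
                results.append(res)
    results.sort(key=lambda r: r.p)
    dropped: list[str] = []
    alive = set(names)
    for res in results:
        if res.p >= alpha:
            break
        a, b = res.labels
        if a not in alive or b not in alive:
            continue
        if n_alleles[a] < n_alleles[b]:
            victim = a
        elif n_alleles[b] < n_alleles[a]:
            victim = b
        else:
            victim = b if names.index(b) > names.index(a) else a
        alive.discard(victim)
        dropped.append(victim)
    if not dropped:
        return dataset, []
    kept = [n for n in names if n in alive]
    return dataset.subset_loci(kept), dropped
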