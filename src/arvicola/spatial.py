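"""Matrix correlation and spatial autocorrelation analyses.

Mantel and partial Mantel tests relate pairwise genetic distance matrices
(linearised theta) to landscape distance matrices (log10 Euclidean,
resistance or suitability) and to a binary same-cluster membership matrix,
in the causal-modelling style of isolation-by-distance studies.  Reduced
major axis (RMA) regression summarises the slope of those relationships.

Individual-level spatial structure uses the multilocus autocorrelation
coefficient r of Smouse & Peakall: squared genetic distances between
codominant genotypes (per-locus values 0/1/2/3/4, summed over loci) are
Gower-centred into a covariance matrix, and r per geographic distance
class compares within-class covariance with the within-individual terms.
A permutation null band (shuffling genotypes among individuals) and a
bootstrap CI (resampling pairs within class) accompany each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeDataset

__all__ = [
    "MantelResult",
    "RmaFit",
    "AutocorrResult",
    "mantel",
    "partial_mantel",
    "rma_fit",
    "membership_matrix",
    "autocorr",
    "genetic_distance_matrix",
]


def _tri(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    m = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("matrix is not symmetric")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str  # "greater" | "less" | "two-sided"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
    tail: str = "auto",
) -> MantelResult:
    """Mantel test: Pearson r over the strict lower triangle.

    The null permutes rows and columns of B simultaneously.  ``tail="auto"``
    tests one-sided in the direction of the observed r (the convention of
    the classic IBD software); "two-sided" is available explicitly.
    """
    a = np.asarray(A.to_numpy() if isinstance(A, pd.DataFrame) else A, float)
    b = np.asarray(B.to_numpy() if isinstance(B, pd.DataFrame) else B, float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    if a.shape[0] < 4:
        raise ValueError("need at least 4 demes for a Mantel test")
    va, vb = _tri(a), _tri(b)
    r_obs = _pearson(va, vb)
    if not np.isfinite(r_obs):
        return MantelResult(float("nan"), float("nan"), n_perm, tail)
    if tail == "auto":
        tail = "greater" if r_obs >= 0 else "less"
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = _pearson(va, _tri(b[np.ix_(perm, perm)]))
        if not np.isfinite(r_star):
            continue
        if tail == "greater":
            hit = r_star >= r_obs - 1e-12
        elif tail == "less":
            hit = r_star <= r_obs + 1e-12
        else:
            hit = abs(r_star) >= abs(r_obs) - 1e-12
        hits += bool(hit)
    return MantelResult(r_obs, (1 + hits) / (n_perm + 1), n_perm, tail)


def _residual_matrix(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Symmetric matrix of residuals of A's triangle regressed on C's."""
    va, vc = _tri(A), _tri(C)
    beta = np.cov(va, vc)[0, 1] / np.var(vc)
    alpha = va.mean() - beta * vc.mean()
    resid = A - (alpha + beta * C)
    np.fill_diagonal(resid, 0.0)
    return resid


def partial_mantel(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    C: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
    tail: str = "auto",
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    The statistic is the first-order partial correlation of the triangle
    vectors; the null permutes the residuals of A on C (residual
    permutation), correlating them with the residuals of B on C.
    """
    a = np.asarray(A.to_numpy() if isinstance(A, pd.DataFrame) else A, float)
    b = np.asarray(B.to_numpy() if isinstance(B, pd.DataFrame) else B, float)
    c = np.asarray(C.to_numpy() if isinstance(C, pd.DataFrame) else C, float)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("matrices must be conformable")
    if np.allclose(_tri(b), _tri(c)):
        # controlling for B itself: nothing left to correlate
        return MantelResult(0.0, 1.0, n_perm, tail)
    r_ab = _pearson(_tri(a), _tri(b))
    r_ac = _pearson(_tri(a), _tri(c))
    r_bc = _pearson(_tri(b), _tri(c))
    if abs(r_ac) >= 1 - 1e-12 or abs(r_bc) >= 1 - 1e-12:
        return MantelResult(float("nan"), float("nan"), n_perm, tail)
    r_obs = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if tail == "auto":
        tail = "greater" if r_obs >= 0 else "less"
    ra = _residual_matrix(a, c)
    rb = _residual_matrix(b, c)
    vrb = _tri(rb)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = _pearson(_tri(ra[np.ix_(perm, perm)]), vrb)
        if not np.isfinite(r_star):
            continue
        if tail == "greater":
            hit = r_star >= r_obs - 1e-12
        elif tail == "less":
            hit = r_star <= r_obs + 1e-12
        else:
            hit = abs(r_star) >= abs(r_obs) - 1e-12
        hits += bool(hit)
    return MantelResult(float(r_obs), (1 + hits) / (n_perm + 1), n_perm, tail)


@dataclass
class RmaFit:
    slope: float
    intercept: float
    r: float
    transform: str


def rma_fit(
    x_matrix: pd.DataFrame | np.ndarray,
    y_matrix: pd.DataFrame | np.ndarray,
    log_x: bool = False,
) -> RmaFit:
    """Reduced major axis regression on the matrix triangles.

    slope = sign(r) * sd(y) / sd(x); the line passes through the means.
    With ``log_x`` the x triangle is log10-transformed first (landscape
    variables enter the regressions on a decimal-log scale).
    """
    x = _tri(x_matrix)
    y = _tri(y_matrix)
    if log_x:
        if (x <= 0).any():
            raise ValueError("log_x requires strictly positive x entries")
        x = np.log10(x)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a matrix triangle")
    r = _pearson(x, y)
    slope = float(np.sign(r) * y.std() / x.std())
    intercept = float(y.mean() - slope * x.mean())
    return RmaFit(slope=slope, intercept=intercept, r=r, transform="log10(x)" if log_x else "none")


def membership_matrix(labels: dict[str, int], order: list[str] | None = None) -> pd.DataFrame:
    """Binary deme x deme matrix: 1 for same-cluster pairs (diagonal 1)."""
    names = list(labels) if order is None else list(order)
    missing = [n for n in names if n not in labels]
    if missing:
        raise ValueError(f"unlabelled deme(s): {missing}")
    v = np.array([labels[n] for n in names])
    m = (v[:, None] == v[None, :]).astype(float)
    return pd.DataFrame(m, index=names, columns=names)


# ---------------------------------------------------------------------------
# Individual-level spatial autocorrelation
# ---------------------------------------------------------------------------



def _locus_sq_distance(calls: np.ndarray) -> np.ndarray:
    """Pairwise squared genetic distance at one locus (codominant metric).

    Genotype pairs score 0 (identical), 1 (one shared allele or
    homozygote vs heterozygote containing it), 2 (two heterozygotes, no
    shared allele), 3 (homozygote vs non-matching heterozygote) or 4
    (different homozygotes); missing genotypes contribute 0.
    """
    n = calls.shape[0]
    a, b = calls[:, 0], calls[:, 1]
    het = a != b
    present = a > 0
    d = np.zeros((n, n))
    # shared-allele counts between unordered pairs
    share = (
        (a[:, None] == a[None, :]).astype(int)
        + (a[:, None] == b[None, :]).astype(int)
        + (b[:, None] == a[None, :]).astype(int)
        + (b[:, None] == b[None, :]).astype(int)
    )
    both_het = het[:, None] & het[None, :]
    both_hom = ~het[:, None] & ~het[None, :]
    mixed = ~both_het & ~both_hom
    # heterozygote pairs: same genotype share=2 -> 0; one allele shared -> 1;
    # none shared -> 2
    d = np.where(both_het, np.select([share >= 2, share == 1], [0, 1], 2), d)
    # homozygote pairs: same -> share=4 -> 0; different -> 4
    d = np.where(both_hom, np.where(share >= 4, 0, 4), d)
    # hom vs het: hom allele in het -> 1; else 3
    d = np.where(mixed, np.where(share >= 1, 1, 3), d)
    ok = present[:, None] & present[None, :]
    d = np.where(ok, d, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def genetic_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Multilocus squared genetic distance between individuals."""
    d = np.zeros((dataset.n_individuals, dataset.n_individuals))
    for l in range(dataset.n_loci):
        d += _locus_sq_distance(dataset.calls[:, l, :])
    return d


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    return -0.5 * (d2 - row - col + d2.mean())


def _class_r(cov: np.ndarray, pairs: tuple[np.ndarray, np.ndarray]) -> float:
    i, j = pairs
    if i.size == 0:
        return float("nan")
    num = 2.0 * cov[i, j].sum()
    den = (cov[i, i] + cov[j, j]).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


@dataclass
class AutocorrResult:
    """Per-distance-class multilocus autocorrelation with uncertainty bands."""

    table: pd.DataFrame  # lower_m, upper_m, n_pairs, r, perm_lo, perm_hi, boot_lo, boot_hi
    class_width: float
    overall_p: float = float("nan")


def autocorr(
    dataset: GenotypeDataset,
    coords: np.ndarray | None = None,
    class_width: float = 100.0,
    n_perm: int = 999,
    n_boot: int = 1000,
    seed: int | None = 0,
    max_classes: int | None = None,
) -> AutocorrResult:
    """Distance-class spatial autocorrelation of individual genotypes.

    Individuals inherit their deme's coordinates unless per-individual
    ``coords`` (n x 2, metres) are supplied, so same-deme pairs fall in the
    first class.  Classes are half-open ``[lower, upper)`` multiples of
    ``class_width``.  Per class: the autocorrelation r, a 95% permutation
    null band (genotypes shuffled among individuals) and a 95% bootstrap CI
    (pairs resampled within class).  Classes with < 2 pairs are NaN.
    """
    n = dataset.n_individuals
    if coords is None:
        deme_of = dataset.deme_index_per_individual
        xy = np.array([[d.easting, d.northing] for d in dataset.demes])
        coords = xy[deme_of]
    coords = np.asarray(coords, float)
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n_individuals, 2)")
    geo = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    d2 = genetic_distance_matrix(dataset)
    cov = _gower_center(d2)

    iu, ju = np.tril_indices(n, k=-1)
    dist = geo[iu, ju]
    k_max = int(dist.max() // class_width) + 1
    if max_classes is not None:
        k_max = min(k_max, max_classes)
    cls = np.minimum((dist // class_width).astype(int), k_max - 1)
    rng = np.random.default_rng(seed)

    rows = []
    pair_idx_per_class = []
    for k in range(k_max):
        sel = cls == k
        pair_idx_per_class.append((iu[sel], ju[sel]))
    # permutation null: shuffle individual identities in the covariance matrix
    perm_r = np.full((n_perm, k_max), np.nan)
    for pi in range(n_perm):
        perm = rng.permutation(n)
        pc = cov[np.ix_(perm, perm)]
        for k in range(k_max):
            perm_r[pi, k] = _class_r(pc, pair_idx_per_class[k])
    for k in range(k_max):
        i, j = pair_idx_per_class[k]
        n_pairs = i.size
        r = _class_r(cov, (i, j)) if n_pairs >= 2 else float("nan")
        if n_pairs >= 2:
            boots = np.empty(n_boot)
            for bi in range(n_boot):
                pick = rng.integers(0, n_pairs, n_pairs)
                boots[bi] = _class_r(cov, (i[pick], j[pick]))
            boot_lo, boot_hi = np.nanquantile(boots, [0.025, 0.975])
            pk = perm_r[:, k]
            pk = pk[np.isfinite(pk)]
            perm_lo, perm_hi = (
                np.quantile(pk, [0.025, 0.975]) if pk.size else (np.nan, np.nan)
            )
        else:
            boot_lo = boot_hi = perm_lo = perm_hi = float("nan")
        rows.append(
            {
                "lower_m": k * class_width,
                "upper_m": (k + 1) * class_width,
                "n_pairs": n_pairs,
                "r": r,
                "perm_lo": perm_lo,
                "perm_hi": perm_hi,
                "boot_lo": boot_lo,
                "boot_hi": boot_hi,
            }
        )
    return AutocorrResult(table=pd.DataFrame(rows), class_width=class_width)
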