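"""Model-based genetic clustering and hierarchical AMOVA.

The clustering model is the classic no-admixture mixture model for
multilocus genotypes: each individual belongs to one of ``K`` clusters and
its genotype at every locus is an independent Hardy–Weinberg draw from that
cluster's allele frequencies.  A Gibbs sampler alternates between sampling
cluster allele frequencies (Dirichlet(1 + counts)) and individual
assignments (proportional to the genotype likelihood).  The number of
clusters is chosen from replicate runs with the log model evidence
``Ln P(K)`` (estimated as ``mean(logL) - var(logL)/2`` over post-burn-in
sweeps) and its standardised second difference ``Delta K``.

The AMOVA decomposes allele-identity variance (infinite-alleles distance:
0 for the same allele code, 1 otherwise) between gene copies over four
nested strata: among clusters, among demes within clusters, among
individuals within demes, and within individuals.  Variance components are
obtained from the nested sums of squares with unbalanced-design
coefficients; significance comes from stratum-appropriate permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeDataset
from .popgen import _encode, _Encoded

__all__ = [
    "ClusterModel",
    "KSelection",
    "AmovaResult",
    "gibbs_cluster",
    "select_k",
    "deme_cluster_labels",
    "membership_counts",
    "amova",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    K: int
    q: np.ndarray  # (n_individuals, K) posterior assignment probabilities
    loglik_trace: np.ndarray
    log_evidence: float
    seed: int | None

    def q_table(self, dataset: GenotypeDataset) -> pd.DataFrame:
        df = pd.DataFrame(
            self.q, columns=[f"q_{k + 1}" for k in range(self.K)]
        )
        df.insert(0, "deme", [dataset.demes[i[1]].name for i in dataset.individuals])
        df.insert(0, "individual", [i[0] for i in dataset.individuals])
        return df


def _stack_encoding(enc: _Encoded) -> tuple[np.ndarray, list[slice], float]:
    """Concatenate per-locus dosage blocks; return (X, locus slices, het const)."""
    slices = []
    start = 0
    for x in enc.X:
        slices.append(slice(start, start + x.shape[1]))
        start += x.shape[1]
    X = np.hstack(enc.X) if enc.X else np.zeros((enc.present.shape[0], 0))
    # heterozygous genotypes per individual: a het call marks 2 alleles in H
    het_counts = np.zeros(enc.present.shape[0])
    for h in enc.H:
        het_counts += (h.sum(1) == 2).astype(float)
    het_const = float(het_counts.sum()) * np.log(2.0)
    return X, slices, het_const


def gibbs_cluster(
    dataset: GenotypeDataset,
    K: int,
    n_iter: int = 20000,
    burnin: int = 5000,
    seed: int | None = 0,
) -> ClusterModel:
    """Fit the K-cluster no-admixture model by Gibbs sampling.

    ``q`` is the Rao-Blackwellised average of per-sweep conditional
    assignment probabilities over post-burn-in sweeps.  Note the defaults
    are scaled-down relative to classic half-million-sweep practice; raise
    them for production runs on real data.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > dataset.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    rng = np.random.default_rng(seed)
    enc = _encode(dataset)
    X, slices, het_const = _stack_encoding(enc)
    n = dataset.n_individuals

    z = rng.integers(0, K, size=n)
    q_sum = np.zeros((n, K))
    trace = []
    kept = 0
    for it in range(n_iter):
        onehot = np.zeros((K, n))
        onehot[z, np.arange(n)] = 1.0
        counts = onehot @ X  # (K, total alleles)
        gam = rng.gamma(shape=1.0 + counts)
        logp = np.empty_like(gam)
        for sl in slices:
            block = gam[:, sl]
            logp[:, sl] = np.log(block / block.sum(axis=1, keepdims=True))
        ll = X @ logp.T  # (n, K) genotype log-likelihood per cluster
        mx = ll.max(axis=1, keepdims=True)
        w = np.exp(ll - mx)
        probs = w / w.sum(axis=1, keepdims=True)
        z = _sample_rows(probs, rng)
        loglik = float(ll[np.arange(n), z].sum() + het_const)
        trace.append(loglik)
        if it >= burnin:
            q_sum += probs
            kept += 1
    trace = np.asarray(trace)
    post = trace[burnin:]
    log_ev = float(post.mean() - post.var(ddof=1) / 2.0) if post.size > 1 else float(post.mean())
    return ClusterModel(
        K=K, q=q_sum / max(kept, 1), loglik_trace=trace, log_evidence=log_ev, seed=seed
    )


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(probs.shape[0])
    cum = probs.cumsum(axis=1)
    return (u[:, None] > cum).sum(axis=1)


@dataclass
class KSelection:
    table: pd.DataFrame  # index K: mean_lnp, sd_lnp, delta_k

    @property
    def best_k(self) -> int:
        dk = self.table["delta_k"].dropna()
        if dk.empty:
            return int(self.table["mean_lnp"].idxmax())
        return int(dk.idxmax())


def select_k(
    dataset: GenotypeDataset,
    k_max: int,
    n_reps: int = 10,
    n_iter: int = 20000,
    burnin: int = 5000,
    seed: int | None = 0,
) -> KSelection:
    """Replicate runs over K = 1..k_max; Delta K on the evidence curve.

    ``Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K)``,
    defined for interior K with nonzero replicate spread.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (Delta K needs a spread)")
    if k_max < 3:
        raise ValueError("k_max must be >= 3 for Delta K")
    rng = np.random.default_rng(seed)
    means, sds = {}, {}
    for K in range(1, k_max + 1):
        evs = [
            gibbs_cluster(
                dataset, K, n_iter=n_iter, burnin=burnin,
                seed=int(rng.integers(2**31 - 1)),
            ).log_evidence
            for _ in range(n_reps)
        ]
        means[K] = float(np.mean(evs))
        sds[K] = float(np.std(evs, ddof=1))
    rows = []
    for K in range(1, k_max + 1):
        if 2 <= K <= k_max - 1:
            second = abs(means[K + 1] - 2 * means[K] + means[K - 1])
            dk = second / sds[K] if sds[K] > 0 else float("nan")
        else:
            dk = float("nan")
        rows.append({"K": K, "mean_lnp": means[K], "sd_lnp": sds[K], "delta_k": dk})
    return KSelection(table=pd.DataFrame(rows).set_index("K"))


def deme_cluster_labels(model: ClusterModel, dataset: GenotypeDataset) -> dict[str, int]:
    """Label each deme by its members' highest mean assignment probability."""
    labels = {}
    deme_of = dataset.deme_index_per_individual
    for d in range(dataset.n_demes):
        mean_q = model.q[deme_of == d].mean(axis=0)
        best = int(np.argmax(mean_q))
        ties = np.flatnonzero(np.isclose(mean_q, mean_q[best], atol=1e-12))
        if ties.size > 1:
            log.warning(
                "deme %s tied between clusters %s; taking the lowest index",
                dataset.demes[d].name, ties.tolist(),
            )
            best = int(ties.min())
        labels[dataset.demes[d].name] = best
    return labels


def membership_counts(model: ClusterModel, dataset: GenotypeDataset) -> pd.DataFrame:
    """Modal-cluster counts per deme (diagnostic companion to the labels)."""
    modal = model.q.argmax(axis=1)
    deme_of = dataset.deme_index_per_individual
    out = np.zeros((dataset.n_demes, model.K), dtype=int)
    np.add.at(out, (deme_of, modal), 1)
    return pd.DataFrame(
        out,
        index=[d.name for d in dataset.demes],
        columns=[f"cluster_{k + 1}" for k in range(model.K)],
    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Four-component nested variance decomposition.

    ``table`` rows: among_clusters, among_demes_within_clusters,
    among_individuals_within_demes, within_individuals — with sigma2,
    percent (sums to 100; negative components retained), fixation index
    (F_CT, F_SC, F_IS, F_IT) and permutation p for the first three.
    """

    table: pd.DataFrame
    n_perm: int

    @property
    def f_ct(self) -> float:
        return float(self.table.loc["among_clusters", "fixation"])

    @property
    def f_sc(self) -> float:
        return float(self.table.loc["among_demes_within_clusters", "fixation"])


class _AmovaData:
    """Per-locus count machinery for fast repeated decompositions."""

    def __init__(self, dataset: GenotypeDataset):
        enc = _encode(dataset)
        self.n_demes = dataset.n_demes
        self.loci = []
        deme_of = dataset.deme_index_per_individual
        for l in range(dataset.n_loci):
            ok = np.flatnonzero(enc.present[:, l])
            if ok.size == 0 or enc.alleles[l].size == 0:
                continue
            codes = enc.alleles[l]
            a = np.searchsorted(codes, dataset.calls[ok, l, 0])
            b = np.searchsorted(codes, dataset.calls[ok, l, 1])
            self.loci.append(
                {
                    "k": codes.size,
                    "ind": ok,
                    "deme": deme_of[ok],
                    "a": a,
                    "b": b,
                }
            )

    @staticmethod
    def _t(counts: np.ndarray) -> np.ndarray:
        """SSD contribution of sets given allele-count rows: (n^2 - sum m^2)/(2n)."""
        n = counts.sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (n.astype(float) ** 2 - (counts.astype(float) ** 2).sum(axis=-1)) / (
                2.0 * n
            )
        return np.where(n > 0, t, 0.0)

    def components(
        self,
        cluster_of_deme: np.ndarray,
        deme_override: list[np.ndarray] | None = None,
        het_override: list[int] | None = None,
    ) -> np.ndarray:
        """(sigma_a, sigma_b, sigma_c, sigma_d) summed over loci."""
        G = int(cluster_of_deme.max()) + 1
        ss = np.zeros(4)  # ag, ad, ai, wi
        coef = np.zeros((4, 4))  # rows: equations; cols sigma a,b,c,d
        for li, loc in enumerate(self.loci):
            deme = loc["deme"] if deme_override is None else deme_override[li]
            a, b, k = loc["a"], loc["b"], loc["k"]
            I = a.size
            N = 2 * I
            # per-deme allele counts
            dcounts = np.zeros((self.n_demes, k))
            np.add.at(dcounts, (deme, a), 1.0)
            np.add.at(dcounts, (deme, b), 1.0)
            gcounts = np.zeros((G, k))
            for g in range(G):
                gcounts[g] = dcounts[cluster_of_deme == g].sum(axis=0)
            tot = gcounts.sum(axis=0)
            n_d = dcounts.sum(axis=1)
            n_g = gcounts.sum(axis=1)
            D = int((n_d > 0).sum())
            Gl = int((n_g > 0).sum())
            if het_override is None:
                H = int((a != b).sum())
            else:
                H = het_override[li]
            ss_wi = H / 2.0
            t_d = self._t(dcounts).sum()
            t_g = self._t(gcounts).sum()
            t_tot = self._t(tot[None, :]).sum()
            ss[3] += ss_wi
            ss[2] += t_d - ss_wi
            ss[1] += t_g - t_d
            ss[0] += t_tot - t_g
            # unbalanced-design coefficients (2 copies per present individual)
            with np.errstate(divide="ignore", invalid="ignore"):
                sb_ad = N - np.nansum(
                    np.where(n_g[cluster_of_deme] > 0, n_d**2 / n_g[cluster_of_deme], 0.0)
                )
                sb_ag = np.nansum(
                    np.where(n_g[cluster_of_deme] > 0, n_d**2 / n_g[cluster_of_deme], 0.0)
                ) - (n_d**2).sum() / N
                sa_ag = N - (n_g**2).sum() / N
            coef[3, 3] += I  # within individuals: N - I = I
            coef[2, 3] += I - D
            coef[2, 2] += 2.0 * (I - D)
            coef[1, 3] += D - Gl
            coef[1, 2] += 2.0 * (D - Gl)
            coef[1, 1] += sb_ad
            coef[0, 3] += Gl - 1
            coef[0, 2] += 2.0 * (Gl - 1)
            coef[0, 1] += sb_ag
            coef[0, 0] += sa_ag
        sigma = np.zeros(4)
        sigma[3] = ss[3] / coef[3, 3] if coef[3, 3] > 0 else 0.0
        sigma[2] = (
            (ss[2] - coef[2, 3] * sigma[3]) / coef[2, 2] if coef[2, 2] > 0 else 0.0
        )
        sigma[1] = (
            (ss[1] - coef[1, 3] * sigma[3] - coef[1, 2] * sigma[2]) / coef[1, 1]
            if coef[1, 1] > 0
            else 0.0
        )
        sigma[0] = (
            (ss[0] - coef[0, 3] * sigma[3] - coef[0, 2] * sigma[2] - coef[0, 1] * sigma[1])
            / coef[0, 0]
            if coef[0, 0] > 0
            else 0.0
        )
        return sigma  # (a, b, c, d)


def amova(
    dataset: GenotypeDataset,
    labels: dict[str, int],
    n_perm: int = 10000,
    seed: int | None = 0,
) -> AmovaResult:
    """Three-stratum hierarchical AMOVA on allele identity (IAM distance).

    ``labels`` maps deme name -> cluster.  Permutation schemes: F_SC —
    individuals among demes within clusters; F_CT — whole demes among
    clusters; the among-individuals (F_IS) level — gene copies among
    individuals within demes.
    """
    name_to_idx = {d.name: d.index for d in dataset.demes}
    missing = [n for n in name_to_idx if n not in labels]
    if missing:
        raise ValueError(f"unlabelled deme(s): {missing}")
    raw = np.array([labels[d.name] for d in dataset.demes])
    uniq = np.unique(raw)
    if uniq.size < 2:
        raise ValueError("between-cluster level undefined: all demes in one cluster")
    cluster_of_deme = np.searchsorted(uniq, raw)

    data = _AmovaData(dataset)
    def ratio(num: float, den: float) -> float:
        return float(num / den) if den != 0 else float("nan")

    sigma = data.components(cluster_of_deme)
    total = sigma.sum()
    percent = 100.0 * sigma / total
    f_ct = ratio(sigma[0], total)
    f_sc = ratio(sigma[1], sigma[1] + sigma[2] + sigma[3])
    f_is = ratio(sigma[2], sigma[2] + sigma[3])
    f_it = ratio(sigma[0] + sigma[1] + sigma[2], total)

    rng = np.random.default_rng(seed)
    # F_CT: demes among clusters
    p_ct = p_sc = p_is = float("nan")
    if np.isfinite(f_ct):
        hits_ct = 0
        perm_clusters = cluster_of_deme.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_clusters)
            s = data.components(perm_clusters)
            if ratio(s[0], s.sum()) >= f_ct - 1e-12:
                hits_ct += 1
        p_ct = (1 + hits_ct) / (n_perm + 1)
    # F_SC: individuals among demes within clusters
    if np.isfinite(f_sc):
        hits_sc = 0
        for _ in range(n_perm):
            override = []
            for loc in data.loci:
                deme = loc["deme"].copy()
                for g in np.unique(cluster_of_deme):
                    mask = np.isin(deme, np.flatnonzero(cluster_of_deme == g))
                    vals = deme[mask]
                    rng.shuffle(vals)
                    deme[mask] = vals
                override.append(deme)
            s = data.components(cluster_of_deme, deme_override=override)
            if ratio(s[1], s[1] + s[2] + s[3]) >= f_sc - 1e-12:
                hits_sc += 1
        p_sc = (1 + hits_sc) / (n_perm + 1)
    # F_IS level: gene copies among individuals within demes
    if np.isfinite(f_is):
        hits_is = 0
        for _ in range(n_perm):
            het_override = []
            for loc in data.loci:
                H = 0
                for d in np.unique(loc["deme"]):
                    mask = loc["deme"] == d
                    copies = np.concatenate([loc["a"][mask], loc["b"][mask]])
                    rng.shuffle(copies)
                    half = copies.size // 2
                    H += int((copies[:half] != copies[half:]).sum())
                het_override.append(H)
            s = data.components(cluster_of_deme, het_override=het_override)
            if ratio(s[2], s[2] + s[3]) >= f_is - 1e-12:
                hits_is += 1
        p_is = (1 + hits_is) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "sigma2": sigma,
            "percent": percent,
            "fixation": [f_ct, f_sc, f_is, f_it],
            "p": [p_ct, p_sc, p_is, float("nan")],
        },
        index=[
            "among_clusters",
            "among_demes_within_clusters",
            "among_individuals_within_demes",
            "within_individuals",
        ],
    )
    return AmovaResult(table=table, n_perm=n_perm)
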