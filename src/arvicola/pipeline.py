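"""End-to-end analysis orchestration.

``run_pipeline`` sequences the full landscape-genetics analysis from a
:class:`RunConfig` (loadable from YAML): LD locus filter -> diversity ->
pairwise/overall theta -> clustering with K selection -> AMOVA -> distance
matrices -> Mantel / partial-Mantel suite -> individual autocorrelation ->
migrant detection.  Every stage derives its seed deterministically from the
master seed and the stage name, writes one TSV (or JSON) artefact into the
output directory, and registers it in the returned :class:`RunReport`, so
identical config + seed reproduce byte-identical outputs.  Stages that
need a land-cover grid degrade gracefully when none is supplied (the
Mantel suite then runs on Euclidean distance only).

``real_data_summary`` reproduces the headline statistics of a deposited
study dataset (Genepop + deme CSV) end to end: LD filter, overall theta,
per-locus heterozygosities, per-deme F_IS and the count of significant
pairwise tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign, cluster, genio, landscape, popgen, spatial

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_seed", "real_data_summary"]

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """All pipeline settings; every field has a usable default."""

    genepop: str | None = None
    deme_csv: str | None = None
    category_grid: str | None = None
    dem_grid: str | None = None
    genepop_dialect: int = 3
    cost_values: dict[int, float] = field(
        default_factory=lambda: dict(landscape.DEFAULT_COST_VALUES)
    )
    suitable_categories: list[int] = field(default_factory=lambda: [1, 2, 3])
    rarefaction_copies: int | None = None
    ld_alpha: float = 0.001
    ld_n_perm: int = 2000  # must resolve finer than ld_alpha
    k_max: int = 6
    k_reps: int = 3
    mcmc_iterations: int = 2000
    mcmc_burnin: int = 500
    n_perm: int = 200
    n_boot: int = 1000
    autocorr_class_width: float = 100.0
    migrant_alpha: float = 0.01
    migrant_n_mc: int = 10000
    seed: int = 0
    outdir: str = "arvicola_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cost_values" in raw:
            raw["cost_values"] = {int(k): float(v) for k, v in raw["cost_values"].items()}
        return cls(**raw)


@dataclass
class RunReport:
    registry: dict[str, str]
    settings: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"seed": self.seed, "registry": self.registry, "settings": self.settings},
                indent=2,
                default=str,
            )
            + "\n"
        )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def run_pipeline(
    config: RunConfig,
    dataset: genio.GenotypeDataset | None = None,
    grid: landscape.CategoryGrid | None = None,
) -> RunReport:
    """Run every stage in dependency order and write one artefact each.

    ``dataset``/``grid`` may be passed directly (e.g. from the synthetic
    generator) instead of via file paths in the config.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    registry: dict[str, str] = {}
    seed = config.seed

    if dataset is None:
        if config.genepop is None:
            raise ValueError("missing mandatory input: genepop path or dataset")
        dataset = genio.read_genepop(config.genepop, dialect=config.genepop_dialect)
        if config.deme_csv:
            dataset = dataset.with_demes(genio.read_deme_table(config.deme_csv))
    if grid is None and config.category_grid:
        grid = landscape.read_ascii_grid(config.category_grid)
    dem = (
        landscape.read_ascii_grid(config.dem_grid, as_elevation=True)
        if config.dem_grid
        else None
    )

    # 1. LD filter
    filtered, dropped = popgen.ld_filter(
        dataset, alpha=config.ld_alpha, n_perm=config.ld_n_perm,
        seed=stage_seed(seed, "ld_filter"),
    )
    (out / "ld_filter.json").write_text(json.dumps({"dropped": dropped}) + "\n")
    registry["ld_filter"] = str(out / "ld_filter.json")
    if dropped:
        log.warning("LD filter dropped locus/loci: %s", dropped)

    # 2. diversity
    div = popgen.diversity_stats(
        filtered, rarefaction_copies=config.rarefaction_copies,
        seed=stage_seed(seed, "diversity"),
    )
    _write(div, out / "diversity.tsv")
    registry["diversity"] = str(out / "diversity.tsv")

    # 3. F_ST
    fst = popgen.fst_matrix(filtered, n_perm=config.n_perm, seed=stage_seed(seed, "fst"))
    overall = popgen.fst_overall(filtered, n_boot=config.n_boot, seed=stage_seed(seed, "fst_boot"))
    _write(fst.theta, out / "fst_pairwise.tsv")
    _write(fst.p_values, out / "fst_pvalues.tsv")
    (out / "fst_overall.json").write_text(
        json.dumps({"theta": overall.overall, "ci": overall.ci, "level": overall.ci_level})
        + "\n"
    )
    registry["fst"] = str(out / "fst_pairwise.tsv")
    registry["fst_overall"] = str(out / "fst_overall.json")

    # 4. clustering
    ks = cluster.select_k(
        filtered, k_max=config.k_max, n_reps=config.k_reps,
        n_iter=config.mcmc_iterations, burnin=config.mcmc_burnin,
        seed=stage_seed(seed, "select_k"),
    )
    best_k = max(ks.best_k, 2)
    model = cluster.gibbs_cluster(
        filtered, best_k, n_iter=config.mcmc_iterations,
        burnin=config.mcmc_burnin, seed=stage_seed(seed, "gibbs"),
    )
    _write(ks.table, out / "k_selection.tsv")
    model.q_table(filtered).to_csv(out / "q_matrix.tsv", sep="\t", index=False, lineterminator="\n")
    registry["k_selection"] = str(out / "k_selection.tsv")
    registry["q_matrix"] = str(out / "q_matrix.tsv")
    labels = cluster.deme_cluster_labels(model, filtered)

    # 5. AMOVA (needs >= 2 deme-level clusters)
    if len(set(labels.values())) >= 2:
        am = cluster.amova(filtered, labels, n_perm=config.n_perm, seed=stage_seed(seed, "amova"))
        _write(am.table, out / "amova.tsv")
        registry["amova"] = str(out / "amova.tsv")
    else:
        log.warning("all demes in one cluster; AMOVA skipped")

    # 6. distances
    demes = filtered.demes
    if grid is not None:
        bundle = landscape.distance_bundle(
            demes, grid, cv=config.cost_values, dem=dem,
            suitable=set(config.suitable_categories),
        )
        for name, p in bundle.to_tsv(out).items():
            registry[f"distance_{name}"] = str(p)
        euclid = bundle.euclidean_km
    else:
        euclid = landscape.euclidean_matrix(demes)
        _write(euclid, out / "distance_euclidean_km.tsv")
        registry["distance_euclidean_km"] = str(out / "distance_euclidean_km.tsv")
        bundle = None

    # 7. Mantel suite on linearised theta
    lin = popgen.linearized_fst(fst.theta)
    membership = spatial.membership_matrix(labels, order=[d.name for d in demes])
    tests: list[dict] = []

    def add_test(name: str, corrected: str, res: spatial.MantelResult) -> None:
        tests.append(
            {"test": name, "corrected_by": corrected, "r": res.r, "p": res.p}
        )

    def logm(m: pd.DataFrame) -> np.ndarray:
        v = m.to_numpy().astype(float).copy()
        np.fill_diagonal(v, 1.0)
        if (v <= 0).any():
            raise ValueError("non-positive off-diagonal distance; cannot log")
        lv = np.log10(v)
        np.fill_diagonal(lv, 0.0)
        return lv

    predictors: dict[str, np.ndarray] = {"euclidean": logm(euclid)}
    if bundle is not None:
        predictors["resistance"] = logm(bundle.resistance)
        predictors["suitability"] = logm(bundle.suitability_per_km)
    predictors["membership"] = membership.to_numpy()

    sd = stage_seed(seed, "mantel")
    rng = np.random.default_rng(sd)
    lin_v = lin.to_numpy()
    for name, mat in predictors.items():
        add_test(
            name, "-", spatial.mantel(lin_v, mat, n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)))
        )
        for cname, cmat in predictors.items():
            if cname == name:
                continue
            add_test(
                name,
                cname,
                spatial.partial_mantel(
                    lin_v, mat, cmat, n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1))
                ),
            )
    mantel_df = pd.DataFrame(tests)
    mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False, lineterminator="\n")
    registry["mantel"] = str(out / "mantel.tsv")

    # 8. autocorrelation
    ac = spatial.autocorr(
        filtered, class_width=config.autocorr_class_width,
        n_perm=min(config.n_perm * 5 - 1, 999), n_boot=config.n_boot,
        seed=stage_seed(seed, "autocorr"),
    )
    ac.table.to_csv(out / "autocorr.tsv", sep="\t", index=False, lineterminator="\n")
    registry["autocorr"] = str(out / "autocorr.tsv")

    # 9. migrants
    mig = assign.detect_migrants(
        filtered, n_mc=config.migrant_n_mc, alpha=config.migrant_alpha,
        seed=stage_seed(seed, "migrants"),
    )
    mig.table.to_csv(out / "migrants.tsv", sep="\t", index=False, lineterminator="\n")
    registry["migrants"] = str(out / "migrants.tsv")

    report = RunReport(registry=registry, settings=asdict(config), seed=seed)
    report.to_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# Real-data reproduction
# ---------------------------------------------------------------------------


def real_data_summary(
    genepop_path: str | Path,
    dialect: int = 3,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Headline statistics of a deposited study dataset, computed end to end.

    Returns the dropped loci from the LD filter, the overall theta on the
    remaining loci, the mean per-locus observed/expected heterozygosity on
    the full locus set, per-deme F_IS, the maximum pairwise theta and the
    number of deme pairs significant at p < 0.05.
    """
    dataset = genio.read_genepop(genepop_path, dialect=dialect)
    filtered, dropped = popgen.ld_filter(
        dataset, alpha=0.001, n_perm=max(n_perm, 2000), seed=stage_seed(seed, "ld_filter")
    )
    # per-locus mean heterozygosities over the pooled sample (all loci)
    enc = popgen._encode(dataset)
    ho_per_locus, he_per_locus = [], []
    deme_of = dataset.deme_index_per_individual
    for l in range(dataset.n_loci):
        ho_d, he_d = [], []
        for d in range(dataset.n_demes):
            members = dataset.deme_members(d)
            ok = members[enc.present[members, l]]
            if ok.size == 0:
                continue
            calls = dataset.calls[ok, l, :]
            ho_d.append(float((calls[:, 0] != calls[:, 1]).mean()))
            counts = enc.X[l][ok].sum(axis=0)
            n2 = counts.sum()
            p = counts[counts > 0] / n2
            he_d.append(float((n2 / (n2 - 1)) * (1 - (p**2).sum())))
        ho_per_locus.append(float(np.mean(ho_d)))
        he_per_locus.append(float(np.mean(he_d)))
    overall = popgen.fst_overall(filtered, n_boot=n_boot, seed=stage_seed(seed, "boot"))
    pairwise = popgen.fst_matrix(filtered, n_perm=n_perm, seed=stage_seed(seed, "pairs"))
    div = popgen.diversity_stats(filtered, seed=stage_seed(seed, "div"))
    tri = np.tril_indices(dataset.n_demes, k=-1)
    return {
        "dropped_loci": dropped,
        "overall_theta": overall.overall,
        "theta_ci": overall.ci,
        "mean_ho_per_locus": float(np.mean(ho_per_locus)),
        "mean_he_per_locus": float(np.mean(he_per_locus)),
        "fis_per_deme": div["F_IS"].to_dict(),
        "max_pairwise_theta": float(np.nanmax(pairwise.theta.to_numpy())),
        "n_significant_pairs": int((pairwise.p_values.to_numpy()[tri] < 0.05).sum()),
        "n_pairs": int(len(tri[0])),
    }
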