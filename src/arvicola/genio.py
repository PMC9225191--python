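"""Genotype and deme-metadata I/O.

Single source of truth for the shape of a microsatellite dataset: diploid
multilocus genotypes grouped into demes (local breeding populations, here
the voles trapped in one orchard) with planar metre coordinates.

Genepop text files (2- or 3-digit allele codes, ``POP``-delimited sections)
are the exchange format; deme metadata travels in a plain CSV with columns
``name, easting, northing, area, date``.

Allele codes are kept verbatim (they are fragment sizes in base pairs);
recoding to dense indices happens inside the statistics modules so that
written files stay diff-able against the originals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "DemeInfo",
    "GenotypeDataset",
    "GenepopError",
    "PloidyError",
    "LocusCountError",
    "EmptyPopError",
    "DemeOrderError",
    "AlleleWidthError",
    "DemeTableError",
    "read_genepop",
    "write_genepop",
    "read_deme_table",
    "write_deme_table",
]

MISSING = 0  # allele code reserved for missing data


class GenepopError(ValueError):
    """Base class for malformed Genepop input."""


class PloidyError(GenepopError):
    """A call does not carry exactly two alleles (or is half-missing)."""


class LocusCountError(GenepopError):
    """An individual row does not list one call per declared locus."""


class EmptyPopError(GenepopError):
    """A POP section contains no individuals."""


class DemeOrderError(GenepopError):
    """Genepop POP order does not match the deme metadata order."""


class AlleleWidthError(GenepopError):
    """An allele code does not fit the requested digit width."""


class DemeTableError(ValueError):
    """Malformed deme metadata CSV."""


@dataclass(frozen=True)
class Locus:
    name: str
    missing_code: int = MISSING


@dataclass(frozen=True)
class DemeInfo:
    """One sampled deme: plot centre in planar metres plus survey metadata."""

    name: str
    index: int
    easting: float = 0.0
    northing: float = 0.0
    area_ha: float = float("nan")
    sample_date: str = ""
    n: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.easting) and np.isfinite(self.northing)):
            raise DemeTableError(f"non-finite coordinates for deme {self.name!r}")


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes grouped into demes.

    ``calls`` has shape ``(n_individuals, n_loci, 2)``; a missing call is
    ``(0, 0)``.  Alleles within a call are unordered; they are stored sorted
    so that equality of datasets is well defined.
    """

    loci: list[Locus]
    demes: list[DemeInfo]
    individuals: list[tuple[str, int, str | None]]  # (id, deme index, sex)
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        self.calls = np.sort(self.calls, axis=2)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names not unique")
        dnames = [d.name for d in self.demes]
        if len(set(dnames)) != len(dnames):
            raise ValueError("deme names not unique")
        deme_idx = self.deme_index_per_individual
        if len(deme_idx) and (deme_idx.min() < 0 or deme_idx.max() >= len(self.demes)):
            raise ValueError("individual mapped to unknown deme")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise PloidyError(
                f"half-missing call for individual {self.individuals[i][0]!r} "
                f"at locus {self.loci[j].name!r}"
            )
        if (self.calls < 0).any():
            raise ValueError("negative allele code")
        counts = np.bincount(deme_idx, minlength=len(self.demes))
        for d, c in zip(self.demes, counts):
            if d.n and d.n != c:
                raise ValueError(
                    f"deme {d.name!r} declares n={d.n} but has {c} individuals"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    @property
    def deme_index_per_individual(self) -> np.ndarray:
        return np.asarray([i[1] for i in self.individuals], dtype=np.int64)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def deme_members(self, deme: int) -> np.ndarray:
        return np.flatnonzero(self.deme_index_per_individual == deme)

    def deme_sizes(self) -> np.ndarray:
        return np.bincount(self.deme_index_per_individual, minlength=self.n_demes)

    def subset_loci(self, keep: Sequence[str]) -> "GenotypeDataset":
        keep_set = set(keep)
        idx = [i for i, l in enumerate(self.loci) if l.name in keep_set]
        return GenotypeDataset(
            loci=[self.loci[i] for i in idx],
            demes=list(self.demes),
            individuals=list(self.individuals),
            calls=self.calls[:, idx, :].copy(),
        )

    def with_demes(self, demes: Sequence[DemeInfo]) -> "GenotypeDataset":
        """Attach metadata (coordinates etc.) to the demes, by order.

        Names must match positionally or a :class:`DemeOrderError` is raised;
        the metadata order is authoritative for indexing.
        """
        if len(demes) != self.n_demes:
            raise DemeOrderError(
                f"{len(demes)} metadata rows for {self.n_demes} demes"
            )
        sizes = self.deme_sizes()
        out = []
        for i, (old, new) in enumerate(zip(self.demes, demes)):
            if new.name != old.name and not old.name.startswith("pop"):
                raise DemeOrderError(
                    f"deme order mismatch at position {i}: "
                    f"genotypes say {old.name!r}, metadata says {new.name!r}"
                )
            out.append(replace(new, index=i, n=int(sizes[i])))
        return GenotypeDataset(
            loci=list(self.loci),
            demes=out,
            individuals=list(self.individuals),
            calls=self.calls.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            [l.name for l in self.loci] == [l.name for l in other.loci]
            and [d.name for d in self.demes] == [d.name for d in other.demes]
            and [(i[0], i[1]) for i in self.individuals]
            == [(i[0], i[1]) for i in other.individuals]
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_call(token: str, dialect: int, where: str) -> tuple[int, int]:
    if len(token) != 2 * dialect or not token.isdigit():
        raise PloidyError(
            f"{where}: call {token!r} is not two {dialect}-digit allele codes"
        )
    a, b = int(token[:dialect]), int(token[dialect:])
    if (a == MISSING) != (b == MISSING):
        raise PloidyError(f"{where}: half-missing call {token!r}")
    return a, b


def read_genepop(path: str | Path, dialect: int = 3) -> GenotypeDataset:
    """Parse a Genepop file into a :class:`GenotypeDataset`.

    Demes are named ``pop1 .. popN`` in POP order (attach real metadata with
    :meth:`GenotypeDataset.with_demes`).  An all-zero call is missing.
    """
    if dialect not in (2, 3):
        raise ValueError("dialect must be 2 or 3 digits per allele")
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise GenepopError("empty file")
    # header: title line then locus names until the first POP
    body = iter(enumerate(lines[1:], start=2))
    loci: list[Locus] = []
    first_pop_at = None
    for ln, line in body:
        if _POP_RE.match(line):
            first_pop_at = ln
            break
        for name in re.split(r"[,\s]+", line.strip()):
            if name:
                loci.append(Locus(name))
    if first_pop_at is None:
        raise GenepopError("no POP section found")
    if not loci:
        raise GenepopError("no locus names before first POP")

    individuals: list[tuple[str, int, str | None]] = []
    rows: list[list[tuple[int, int]]] = []
    deme = 0
    deme_counts: list[int] = [0]
    for ln, line in body:
        if _POP_RE.match(line):
            if deme_counts[deme] == 0:
                raise EmptyPopError(f"POP section ending at line {ln} is empty")
            deme += 1
            deme_counts.append(0)
            continue
        if not line.strip():
            continue
        if "," in line:
            ident, _, geno = line.partition(",")
        else:  # tolerate missing comma (some exporters)
            ident, _, geno = line.partition(" ")
        ident = ident.strip()
        tokens = geno.split()
        where = f"line {ln} ({ident!r})"
        if len(tokens) != len(loci):
            raise LocusCountError(
                f"{where}: {len(tokens)} calls for {len(loci)} loci"
            )
        rows.append([_split_call(t, dialect, where) for t in tokens])
        individuals.append((ident, deme, None))
        deme_counts[deme] += 1
    if deme_counts[-1] == 0:
        raise EmptyPopError("final POP section is empty")

    demes = [
        DemeInfo(name=f"pop{i + 1}", index=i, n=c) for i, c in enumerate(deme_counts)
    ]
    calls = np.array(rows, dtype=np.int64) if rows else np.empty((0, len(loci), 2))
    return GenotypeDataset(loci=loci, demes=demes, individuals=individuals, calls=calls)


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    dialect: int = 3,
    title: str = "arvicola export",
) -> None:
    """Write a Genepop file; inverse of :func:`read_genepop`."""
    if dialect not in (2, 3):
        raise ValueError("dialect must be 2 or 3 digits per allele")
    limit = 10**dialect - 1
    if dataset.calls.size and int(dataset.calls.max()) > limit:
        raise AlleleWidthError(
            f"allele code {int(dataset.calls.max())} exceeds {dialect}-digit width"
        )
    out = [title]
    out.extend(l.name for l in dataset.loci)
    deme_idx = dataset.deme_index_per_individual
    for d in range(dataset.n_demes):
        out.append("POP")
        for i in dataset.deme_members(d):
            ident, _, _ = dataset.individuals[i]
            toks = [
                f"{a:0{dialect}d}{b:0{dialect}d}" for a, b in dataset.calls[i]
            ]
            out.append(f"{ident} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Deme metadata CSV
# ---------------------------------------------------------------------------

_REQUIRED = ["name", "easting", "northing", "area", "date"]


def read_deme_table(path: str | Path) -> list[DemeInfo]:
    """Read deme metadata; row order defines deme indices (authoritative)."""
    try:
        df = pd.read_csv(path, dtype={"name": str, "date": str})
    except pd.errors.EmptyDataError as exc:
        raise DemeTableError("no demes: empty metadata file") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DemeTableError(f"missing column(s): {', '.join(missing)}")
    if df.empty:
        raise DemeTableError("no demes: metadata table has no rows")
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise DemeTableError(f"duplicate deme name(s): {dupes}")
    for col in ("easting", "northing", "area"):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number):
            raise DemeTableError(f"non-numeric column {col!r}")
        if pd.to_numeric(df[col], errors="coerce").isna().any():
            raise DemeTableError(f"non-numeric value in column {col!r}")
    out = []
    for i, row in df.iterrows():
        out.append(
            DemeInfo(
                name=str(row["name"]),
                index=int(i),
                easting=float(row["easting"]),
                northing=float(row["northing"]),
                area_ha=float(row["area"]),
                sample_date=str(row["date"]),
                n=int(row["n"]) if "n" in df.columns else 0,
            )
        )
    return out


def write_deme_table(demes: Iterable[DemeInfo], path: str | Path) -> None:
    demes = list(demes)
    df = pd.DataFrame(
        {
            "name": [d.name for d in demes],
            "easting": [d.easting for d in demes],
            "northing": [d.northing for d in demes],
            "area": [d.area_ha for d in demes],
            "date": [d.sample_date for d in demes],
            "n": [d.n for d in demes],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")
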