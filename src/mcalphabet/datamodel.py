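"""Core data containers and delimited-text I/O.

Genotypes are allele dosages in {0, 1, 2} (count of one allele of a biallelic
SNP), phenotypes are real-valued trait records, and a class allocation maps
each SNP-class label to the set of marker indices it contains.  Classes may
overlap: one marker may belong to several classes and then contributes one
additive effect term per class it appears in.

File dialects are comma- or tab-delimited with a header row; the missing
token is ``NA``.  SNP-map positions are 1-based inclusive base-pair
coordinates.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "ClassAllocation",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_class_map",
    "write_class_map",
    "impute_and_center",
    "align_individuals",
]


class ParseError(ValueError):
    """Raised when an input file violates the declared dialect."""


def _detect_sep(path: str) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


@dataclass
class GenotypeMatrix:
    """n×m allele-dosage matrix plus its SNP map.

    ``dosages`` is float64 with NaN marking missing calls; all non-missing
    entries are in {0, 1, 2}.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.validate()

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, m = self.dosages.shape
        for name, arr, length in (
            ("snp_ids", self.snp_ids, m),
            ("chromosomes", self.chromosomes, m),
            ("positions", self.positions, m),
            ("individual_ids", self.individual_ids, n),
        ):
            if len(arr) != length:
                raise ValueError(f"{name} has length {len(arr)}, expected {length}")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids are not unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids are not unique")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} not in {{0,1,2}}")

    def snp_index(self) -> dict:
        return {s: i for i, s in enumerate(self.snp_ids)}


@dataclass
class PhenotypeTable:
    """n×t matrix of trait records, one row per individual."""

    values: np.ndarray
    trait_names: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.individual_ids) != 1:
            self.values = self.values.T
        self.trait_names = np.asarray(self.trait_names, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.values.shape != (len(self.individual_ids), len(self.trait_names)):
            raise ValueError("phenotype shape inconsistent with ids/trait names")

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def drop_missing(self) -> "PhenotypeTable":
        """Drop individuals with any missing trait record."""
        keep = ~np.isnan(self.values).any(axis=1)
        return PhenotypeTable(
            self.values[keep], self.trait_names, self.individual_ids[keep]
        )


@dataclass
class ClassAllocation:
    """Ordered mapping from SNP-class label to a set of marker indices.

    ``members[label]`` is a sorted int64 array of column indices into the
    genotype matrix.  Classes may overlap; their union need not cover all
    markers.
    """

    classes: list
    members: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = list(self.classes)
        self.members = {
            c: np.unique(np.asarray(self.members[c], dtype=np.int64))
            for c in self.classes
        }

    def validate(self, n_snps: int) -> None:
        for c in self.classes:
            idx = self.members[c]
            if idx.size and (idx.min() < 0 or idx.max() >= n_snps):
                raise ValueError(f"class {c!r} has marker index out of range")

    def sizes(self) -> dict:
        return {c: int(self.members[c].size) for c in self.classes}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @classmethod
    def single_class(cls, n_snps: int, label: str = "all") -> "ClassAllocation":
        """The conventional one-class model: every marker in one class."""
        return cls([label], {label: np.arange(n_snps, dtype=np.int64)})


# ---------------------------------------------------------------------------
# genotype I/O

def read_genotypes(path: str, format: str = "csv", map_path: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``csv`` or ``plink-text`` files.

    csv dialect: header row of SNP ids, first column individual id, entries
    in {0,1,2,NA}.  ``map_path`` optionally points to a SNP map
    (snp_id, chromosome, position); without it SNPs are placed on a single
    unnamed chromosome at consecutive positions.

    plink-text: ``path`` is the ``.ped`` file (or the common prefix); the
    matching ``.map`` file must sit alongside.  Dosage counts the minor
    allele of each biallelic locus; ``0`` alleles are missing.
    """
    if format == "csv":
        return _read_genotypes_csv(path, map_path)
    if format == "plink-text":
        return _read_genotypes_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_csv(path: str, map_path: str | None) -> GenotypeMatrix:
    sep = _detect_sep(path)
    with open(path) as fh:  # pandas renames duplicate columns, so check raw
        raw_header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(raw_header)) != len(raw_header):
        raise ParseError(f"{path}: duplicate SNP id in header")
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN], keep_default_na=False)
    ind_ids = df.iloc[:, 0].astype(str).to_numpy()
    snp_ids = df.columns[1:].to_numpy(dtype=object)
    try:
        dos = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage entry ({exc})") from exc
    ok = np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: dosage {dos[r, c]!r} at row {ind_ids[r]!r}, column "
            f"{snp_ids[c]!r} not in {{0,1,2,{MISSING_TOKEN}}}"
        )
    if map_path is not None:
        smap = pd.read_csv(map_path, sep=_detect_sep(map_path), dtype={0: str})
        smap = smap.set_index(smap.columns[0]).loc[[str(s) for s in snp_ids]]
        chroms = smap.iloc[:, 0].astype(str).to_numpy(dtype=object)
        poss = smap.iloc[:, 1].to_numpy(dtype=np.int64)
    else:
        chroms = np.array(["1"] * len(snp_ids), dtype=object)
        poss = np.arange(1, len(snp_ids) + 1, dtype=np.int64)
    return GenotypeMatrix(dos, snp_ids, chroms, poss, ind_ids)


def _read_genotypes_plink(path: str) -> GenotypeMatrix:
    prefix = path[:-4] if path.endswith(".ped") else path
    ped_path,mp = prefix + ".ped", prefix + ".map"
    if not (os.path.exists(ped_path) and os.path.exists(mp)):
        raise FileNotFoundError(f"need both {ped_path} and {mp}")
    mdf = pd.read_csv(mp, sep=r"\s+", header=None, dtype=str)
    chroms = mdf.iloc[:, 0].to_numpy(dtype=object)
    snp_ids = mdf.iloc[:, 1].to_numpy(dtype=object)
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{mp}: duplicate SNP id")
    poss = mdf.iloc[:, 3].astype(np.int64).to_numpy()
    m = len(snp_ids)

    ind_ids, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(tok)}"
                )
            ind_ids.append(tok[1])
            rows.append(tok[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), m, 2)
    dos = np.full((len(rows), m), np.nan)
    for j in range(m):
        a = alleles[:, j, :]
        obs = a[a != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size > 2:
            raise ParseError(f"{ped_path}: locus {snp_ids[j]!r} is not biallelic")
        minor = uniq[np.argmin(counts)] if uniq.size == 2 else (uniq[0] if uniq.size else None)
        if minor is None:
            continue
        miss = (a == "0").any(axis=1)
        dos[:, j] = (a == minor).sum(axis=1)
        dos[miss, j] = np.nan
    return GenotypeMatrix(dos, snp_ids, chroms, poss, np.array(ind_ids, dtype=object))


def write_genotypes(g: GenotypeMatrix, path: str, map_path: str | None = None, sep: str = ",") -> None:
    df = pd.DataFrame(g.dosages, columns=list(g.snp_ids))
    # integer-format dosages, NA for missing
    out = df.map(lambda v: MISSING_TOKEN if np.isnan(v) else str(int(v)))
    out.insert(0, "individual_id", list(g.individual_ids))
    out.to_csv(path, sep=sep, index=False)
    if map_path is not None:
        pd.DataFrame(
            {"snp_id": list(g.snp_ids), "chromosome": list(g.chromosomes),
             "position": g.positions}
        ).to_csv(map_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# phenotype I/O

def read_phenotypes(path: str) -> PhenotypeTable:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=[MISSING_TOKEN], keep_default_na=False)
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    traits = df.columns[1:].to_numpy(dtype=object)
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    return PhenotypeTable(vals, traits, ids)


def write_phenotypes(p: PhenotypeTable, path: str, sep: str = ",") -> None:
    df = pd.DataFrame(p.values, columns=list(p.trait_names))
    df.insert(0, "individual_id", list(p.individual_ids))
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# class-map I/O

def read_class_map(path: str, g: GenotypeMatrix) -> ClassAllocation:
    """Read a two-column (snp_id, class_label) file into a ClassAllocation.

    Duplicate (snp, class) rows collapse; a SNP listed under several labels
    joins every one of those classes.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (snp_id, class_label)")
    lookup = g.snp_index()
    unknown = sorted(set(df.iloc[:, 0]) - set(lookup))
    if unknown:
        raise ValueError(f"class map names unknown SNP ids: {unknown[:10]}")
    classes: list = []
    members: dict = {}
    for snp, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if label not in members:
            classes.append(label)
            members[label] = set()
        members[label].add(lookup[snp])
    return ClassAllocation(classes, {c: sorted(members[c]) for c in classes})


def write_class_map(alloc: ClassAllocation, g: GenotypeMatrix, path: str, sep: str = ",") -> None:
    rows = [
        (g.snp_ids[i], c) for c in alloc.classes for i in alloc.members[c]
    ]
    pd.DataFrame(rows, columns=["snp_id", "class_label"]).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# preparation

def impute_and_center(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and mean-center every column.

    Returns the n×m real covariate matrix used for model fitting and the
    per-column means (needed to center validation individuals identically).
    """
    X = np.array(g.dosages, dtype=float)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        j = int(np.argmax(all_missing))
        raise ValueError(f"SNP {g.snp_ids[j]!r} has no observed dosages")
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    X -= col_means
    return X, col_means


def align_individuals(g: GenotypeMatrix, p: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Inner-join genotypes and phenotypes on individual id, preserving
    genotype order, after dropping phenotype rows with missing records."""
    p = p.drop_missing()
    ppos = {s: i for i, s in enumerate(p.individual_ids)}
    keep = [i for i, s in enumerate(g.individual_ids) if s in ppos]
    if not keep:
        raise ValueError("no individuals shared between genotypes and phenotypes")
    gsub = GenotypeMatrix(
        g.dosages[keep], g.snp_ids, g.chromosomes, g.positions, g.individual_ids[keep]
    )
    order = [ppos[g.individual_ids[i]] for i in keep]
    psub = PhenotypeTable(p.values[order], p.trait_names, p.individual_ids[order])
    return gsub, psub
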