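"""Constructing SNP-class allocations from biological information.

Three strategies are provided: one class per genome-annotation feature type
(unannotated SNPs absorbed by an ``intergenic`` class), one class per
chromosome, and a two-class split around a focal SNP list such as the hits
of a previous GWAS.  A SNP carrying several annotation feature types is
placed in every matching class, so annotation allocations may overlap;
chromosome and two-class allocations always partition the markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import ClassAllocation, GenotypeMatrix

__all__ = [
    "AnnotationTable",
    "allocate_by_annotation",
    "allocate_by_chromosome",
    "allocate_two_class",
]

DEFAULT_CLASS = "intergenic"

#: annotation feature types observed in livestock/crop genome annotation
KNOWN_FEATURE_TYPES = (
    "protein_coding",
    "pseudogene",
    "processed_pseudogene",
    "ncRNA",
    "non_translating_CDS",
    "intergenic",
)


class AnnotationTable:
    """Rows of (snp_id, feature_type); a SNP may carry multiple types."""

    def __init__(self, rows) -> None:
        df = pd.DataFrame(rows, columns=["snp_id", "feature_type"]) if not isinstance(rows, pd.DataFrame) else rows.iloc[:, :2].set_axis(["snp_id", "feature_type"], axis=1)
        self.frame = df.astype(str).drop_duplicates()

    @classmethod
    def read(cls, path: str) -> "AnnotationTable":
        sep = "\t" if open(path).readline().count("\t") else ","
        return cls(pd.read_csv(path, sep=sep, dtype=str))

    def write(self, path: str, sep: str = ",") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def allocate_by_annotation(
    ann: AnnotationTable, g: GenotypeMatrix, default_class: str = DEFAULT_CLASS
) -> ClassAllocation:
    """One class per distinct feature type; SNPs with no annotation row fall
    in ``default_class``.  Overlap is allowed when a SNP carries several
    feature types."""
    lookup = g.snp_index()
    unknown = sorted(set(ann.frame["snp_id"]) - set(lookup))
    if unknown:
        raise ValueError(f"annotation names unknown SNP ids: {unknown[:10]}")
    if len(ann) == 0:
        warnings.warn("empty annotation table: all markers fall in the default class")
        return ClassAllocation(
            [default_class], {default_class: np.arange(g.n_snps, dtype=np.int64)}
        )
    classes: list = []
    members: dict = {}
    annotated = np.zeros(g.n_snps, dtype=bool)
    for snp, feat in zip(ann.frame["snp_id"], ann.frame["feature_type"]):
        idx = lookup[snp]
        annotated[idx] = True
        if feat not in members:
            classes.append(feat)
            members[feat] = set()
        members[feat].add(idx)
    rest = np.flatnonzero(~annotated)
    if rest.size:
        members.setdefault(default_class, set())
        if default_class not in classes:
            classes.append(default_class)
        members[default_class].update(rest.tolist())
    return ClassAllocation(classes, {c: sorted(members[c]) for c in classes})


def allocate_by_chromosome(g: GenotypeMatrix) -> ClassAllocation:
    """One class per distinct chromosome label; a partition of the markers."""
    order: list = []
    members: dict = {}
    for i, ch in enumerate(g.chromosomes):
        key = str(ch)
        if key not in members:
            order.append(key)
            members[key] = []
        members[key].append(i)
    return ClassAllocation(order, members)


def allocate_two_class(
    g: GenotypeMatrix, focal, focal_label: str = "focal", rest_label: str = "rest"
) -> ClassAllocation:
    """Two disjoint exhaustive classes: the focal SNPs and their complement.

    Mirrors the GWAS-driven strategy of putting markers near a known signal
    (e.g. one chromosome) in their own class.
    """
    focal = set(focal)
    lookup = g.snp_index()
    unknown = sorted(focal - set(lookup))
    if unknown:
        raise ValueError(f"focal list names unknown SNP ids: {unknown[:10]}")
    if not focal:
        raise ValueError("focal SNP set is empty: model degenerates to one class")
    if len(focal) == g.n_snps:
        raise ValueError("focal set equals all SNPs: model degenerates to one class")
    fidx = sorted(lookup[s] for s in focal)
    rest = sorted(set(range(g.n_snps)) - set(fidx))
    return ClassAllocation([focal_label, rest_label], {focal_label: fidx, rest_label: rest})
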