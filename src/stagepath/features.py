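"""Build the binary event matrix the staging model consumes.

Somatic SNV/indel calls are binarized per (sample, gene), filtered by a
cohort-wide mutation-frequency threshold, and sparse related genes are
aggregated into gene families (logical OR over members) so that each event
column carries enough signal to be ordered.  The default event set is six
frequently mutated gastric-cancer genes plus eleven gene families, 17
events in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MutationRecord

__all__ = [
    "BinaryMutationMatrix",
    "FamilyMap",
    "DEFAULT_FREQUENT_GENES",
    "DEFAULT_FAMILY_NAMES",
    "default_family_map",
    "binarize",
    "select_frequent",
    "aggregate_families",
]

#: genes whose cohort-wide mutation frequency exceeded the threshold of 150
DEFAULT_FREQUENT_GENES = ("TTN", "MUC16", "TP53", "LRP1B", "OBSCN", "ARID1A")

#: gene families aggregated from literature-curated gastric-cancer genes
DEFAULT_FAMILY_NAMES = (
    "SYNE", "FAT", "CSMD", "CDH", "PCDH", "DNAH",
    "NOTCH", "ERBB", "FGF", "KMT", "BMP",
)

# Shipped membership lists are an editable default: family names are fixed by
# the analysis design, but the full curated membership table is user-editable
# (two-column TSV gene\tfamily).  Members here are the canonical paralog sets.
_DEFAULT_FAMILY_MEMBERS: dict[str, tuple[str, ...]] = {
    "SYNE": ("SYNE1", "SYNE2", "SYNE3"),
    "FAT": ("FAT1", "FAT2", "FAT3", "FAT4"),
    "CSMD": ("CSMD1", "CSMD2", "CSMD3"),
    "CDH": ("CDH1", "CDH2", "CDH3"),
    "PCDH": ("PCDH15", "PCDH17", "PCDH19", "PCDHA1", "PCDHB1"),
    "DNAH": ("DNAH2", "DNAH3", "DNAH5", "DNAH7", "DNAH8", "DNAH9", "DNAH11"),
    "NOTCH": ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"),
    "ERBB": ("ERBB2", "ERBB3", "ERBB4"),
    "FGF": ("FGF10", "FGF14", "FGFR1", "FGFR2", "FGFR3"),
    "KMT": ("KMT2A", "KMT2B", "KMT2C", "KMT2D"),
    "BMP": ("BMP2", "BMP4", "BMP6", "BMPR1A", "BMPR2"),
}


@dataclass
class BinaryMutationMatrix:
    """Samples x events binary matrix with irreversible-event semantics.

    ``provenance`` records per event whether it is a single gene or a
    family aggregate.
    """

    data: pd.DataFrame  # index = samples, columns = events, values {0,1}
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate event names")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("matrix values must be strictly binary")
        self.data = self.data.astype(np.int8)
        for event in self.data.columns:
            self.provenance.setdefault(event, "gene")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def event_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def column_counts(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_events(self, events: list[str]) -> "BinaryMutationMatrix":
        missing = [e for e in events if e not in self.data.columns]
        if missing:
            raise KeyError(f"events not in matrix: {missing}")
        return BinaryMutationMatrix(
            self.data[events].copy(),
            {e: self.provenance[e] for e in events},
        )

    def to_tsv(self, path: str | Path) -> None:
        # events in rows, per the on-disk convention for matrices
        self.data.T.to_csv(path, sep="\t", index_label="event")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).T
        df.index.name = None
        return cls(df)


class FamilyMap:
    """Mapping family name -> member gene symbols; a gene joins one family."""

    def __init__(self, families: dict[str, list[str] | tuple[str, ...]]):
        seen: dict[str, str] = {}
        clean: dict[str, list[str]] = {}
        for family, members in families.items():
            members = list(members)
            if not members:
                raise ValueError(f"family {family!r} is empty")
            for gene in members:
                if gene in seen:
                    raise ValueError(
                        f"gene {gene!r} assigned to both {seen[gene]!r} and {family!r}"
                    )
                seen[gene] = family
            clean[family] = members
        self.families = clean

    def __iter__(self):
        return iter(self.families.items())

    def __len__(self) -> int:
        return len(self.families)

    def member_to_family(self) -> dict[str, str]:
        return {g: f for f, members in self.families.items() for g in members}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("family map TSV needs two columns: gene, family")
        gene_col, family_col = df.columns[:2]
        grouped: dict[str, list[str]] = {}
        for gene, family in zip(df[gene_col], df[family_col]):
            grouped.setdefault(family, []).append(gene)
        return cls(grouped)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, f) for f, members in self.families.items() for g in members]
        pd.DataFrame(rows, columns=["gene", "family"]).to_csv(path, sep="\t", index=False)


def default_family_map() -> FamilyMap:
    return FamilyMap({k: list(v) for k, v in _DEFAULT_FAMILY_MEMBERS.items()})


def binarize(
    records: list[MutationRecord],
    samples: list[str],
    *,
    strict: bool = False,
) -> BinaryMutationMatrix:
    """Collapse call records to a samples x genes 0/1 matrix.

    An entry is 1 iff at least one qualifying record exists for the
    (sample, gene) pair; samples without records get all-zero rows.
    Records for samples outside ``samples`` are dropped with a warning
    (``strict=True`` raises instead).
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    sample_set = set(samples)
    unknown = sorted({r.sample for r in records} - sample_set)
    if unknown:
        if strict:
            raise ValueError(f"records reference unknown samples: {unknown}")
        warnings.warn(f"dropping records for {len(unknown)} unknown sample(s)")
    genes = sorted({r.gene for r in records if r.sample in sample_set})
    data = pd.DataFrame(0, index=list(samples), columns=genes, dtype=np.int8)
    for rec in records:
        if rec.sample in sample_set:
            data.at[rec.sample, rec.gene] = 1
    return BinaryMutationMatrix(data)


def select_frequent(matrix: BinaryMutationMatrix, min_count: int = 150) -> list[str]:
    """Events mutated in strictly more than ``min_count`` samples.

    Ordered by descending mutation count, ties by name.
    """
    counts = matrix.column_counts()
    kept = counts[counts > min_count]
    order = sorted(kept.index, key=lambda g: (-int(kept[g]), g))
    return order


def aggregate_families(
    matrix: BinaryMutationMatrix, fmap: FamilyMap
) -> BinaryMutationMatrix:
    """OR member-gene columns into family events; members leave the event set.

    Family members absent from the gene universe are ignored with a warning;
    a family with no present member yields an all-zero column.  Genes not in
    any family pass through unchanged.
    """
    member_of = fmap.member_to_family()
    present = set(matrix.event_names)
    data = {}
    provenance = {}
    for gene in matrix.event_names:
        if gene not in member_of:
            data[gene] = matrix.data[gene]
            provenance[gene] = matrix.provenance.get(gene, "gene")
    for family, members in fmap:
        missing = [m for m in members if m not in present]
        if missing:
            warnings.warn(
                f"family {family!r}: members absent from gene universe: {missing}"
            )
        available = [m for m in members if m in present]
        if available:
            column = matrix.data[available].max(axis=1)
        else:
            column = pd.Series(0, index=matrix.data.index, dtype=np.int8)
        data[family] = column
        provenance[family] = "family"
    out = pd.DataFrame(data, index=matrix.data.index)
    return BinaryMutationMatrix(out, provenance)
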