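"""Readers and writers for the plain-text formats the pipeline touches.

Mutation calls arrive as a minimal MAF-like table (tab-delimited, header
required) with at least a sample identifier, a gene symbol and a variant
classification; any extra TCGA MAF columns are tolerated and ignored.
Gene sets use standard GMT. Expression and clinical tables are TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MutationRecord",
    "FormatError",
    "read_maf_minimal",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_json",
    "write_json",
]

#: variant classes treated as non-qualifying by default (the class filter is
#: configurable; silent and non-coding classes carry no event information here)
DEFAULT_EXCLUDED_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)

_MAF_COLUMN_ALIASES = {
    "sample": ("sample", "tumor_sample_barcode", "sample_id"),
    "gene": ("gene", "hugo_symbol", "gene_symbol"),
    "variant_class": ("variant_class", "variant_classification", "variant"),
}


class FormatError(ValueError):
    """A text input does not conform to the expected dialect."""


@dataclass(frozen=True)
class MutationRecord:
    sample: str
    gene: str
    variant_class: str


def _resolve_column(columns: list[str], role: str) -> str:
    lowered = {c.lower(): c for c in columns}
    for alias in _MAF_COLUMN_ALIASES[role]:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(
        f"missing required column for {role!r}; accepted names: "
        f"{', '.join(_MAF_COLUMN_ALIASES[role])}"
    )


def read_maf_minimal(
    path: str | Path,
    *,
    excluded_classes: frozenset[str] | set[str] | None = DEFAULT_EXCLUDED_CLASSES,
) -> list[MutationRecord]:
    """Parse a minimal MAF-like TSV into one record per row.

    Parsing is header-keyed, so column order is irrelevant.  Rows whose
    variant classification is in ``excluded_classes`` are dropped (pass
    ``None`` or an empty set to keep everything).  Duplicate
    (sample, gene) rows are preserved; binarization collapses them later.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty file")
    cols = list(df.columns)
    sample_col = _resolve_column(cols, "sample")
    gene_col = _resolve_column(cols, "gene")
    class_col = _resolve_column(cols, "variant_class")
    excluded = frozenset(excluded_classes or ())
    records = [
        MutationRecord(sample=row[0], gene=row[1], variant_class=row[2])
        for row in df[[sample_col, gene_col, class_col]].itertuples(index=False)
        if row[2] not in excluded
    ]
    return records


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set name: unique gene list}``.

    Gene order within each line is preserved; duplicated symbols are dropped
    with a warning.  Lines need name, description and at least one gene.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name, genes = fields[0], fields[2:]
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} dropped")
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes-in-rows expression TSV (first column = gene symbol)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
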