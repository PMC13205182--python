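"""Single-sample gene-set scoring and signature-based classification.

Two rank-based scores are provided.  The ssGSEA score of a set in one
sample ranks all genes by descending expression and walks the list with
a running sum: in-set genes add their rank weight raised to ``alpha``
(normalised by the total in-set weight) and out-of-set genes subtract
1/(G - |set|); the score is the sum of the running sum over all
positions (the integral convention), so sets concentrated at the top of
the ranking score high and sets at the bottom score symmetrically low.
The AUCell-style score is the area under the set-recovery curve within
the top fraction of the ranking, normalised so a set packed at the very
top scores exactly 1.

Phenotype scoring uses the gastric Squamousness and Glandular marker
sets by default; trajectory-signature classification standardises each
signature's ssGSEA score across samples and labels each sample by the
larger z-score (accelerated- vs gradual-path-like).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import write_json

__all__ = [
    "GeneSet",
    "ScoreMatrix",
    "SQUAMOUSNESS",
    "GLANDULAR",
    "ssgsea",
    "ssgsea_matrix",
    "aucell",
    "classify_ap_gp",
]

#: keratinisation / squamous-differentiation markers
SQUAMOUSNESS = ("KRT14", "PKP1", "SPRR3", "SPRR1B", "SPRR2E")
#: gastric glandular lineage markers
GLANDULAR = ("PGA3", "PGA4", "PGC", "GIF", "ATP4A", "ATP4B")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_list(cls, name: str, genes) -> "GeneSet":
        return cls(name, tuple(dict.fromkeys(genes)))


@dataclass
class ScoreMatrix:
    """Sets x samples score matrix with the method and parameters used."""

    data: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_set")
        write_json(
            {"method": self.method, "params": self.params},
            Path(path).with_suffix(".params.json"),
        )


def _present_genes(index: pd.Index, gene_set: GeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in index]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in expression")
    if len(present) < len(gene_set):
        warnings.warn(
            f"set {gene_set.name!r}: {len(present)}/{len(gene_set)} genes present"
        )
    return present


def ssgsea(expr_column: pd.Series, gene_set: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression column.

    Rank-based with average ranks for ties; invariant to any strictly
    increasing transform of the expression values.
    """
    present = _present_genes(expr_column.index, gene_set)
    g = len(expr_column)
    m = len(present)
    if m >= g:
        raise ValueError("gene set covers the whole expression index")
    values = expr_column.to_numpy(dtype=float)
    # average rank, top gene gets rank g
    ranks = stats.rankdata(values)
    in_set = expr_column.index.isin(present)
    # walk positions in descending expression; name-keyed secondary sort for
    # a deterministic walk under exact ties (the score itself uses avg ranks)
    order = np.lexsort((np.asarray(expr_column.index), -ranks))
    weights = np.abs(ranks) ** alpha
    in_weight = np.where(in_set, weights, 0.0)[order]
    out_hit = (~in_set).astype(float)[order]
    p_in = np.cumsum(in_weight) / in_weight.sum()
    p_out = np.cumsum(out_hit) / (g - m)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: pd.DataFrame, gene_sets: list[GeneSet], alpha: float = 0.25
) -> ScoreMatrix:
    """ssGSEA scores for every set x sample of a genes-x-samples matrix."""
    data = pd.DataFrame(
        {
            sample: [ssgsea(expr[sample], s, alpha=alpha) for s in gene_sets]
            for sample in expr.columns
        },
        index=[s.name for s in gene_sets],
    )
    return ScoreMatrix(data, method="ssgsea", params={"alpha": alpha})


def aucell(cell_ranking, gene_set: GeneSet, top_frac: float = 0.05) -> float:
    """Area under the set-recovery curve within the top-ranked window.

    ``cell_ranking`` is either a best-first list of gene names or an
    expression Series (ranked descending, ties broken by gene name).  The
    score is in [0, 1]: 1 when the whole set sits at the very top of the
    window, 0 when no set gene enters it.
    """
    if isinstance(cell_ranking, pd.Series):
        ranks = stats.rankdata(cell_ranking.to_numpy(dtype=float))
        order = np.lexsort((np.asarray(cell_ranking.index), -ranks))
        genes = list(np.asarray(cell_ranking.index)[order])
    else:
        genes = list(cell_ranking)
    g = len(genes)
    if top_frac * g < 1:
        raise ValueError("top_frac window is empty (top_frac * n_genes < 1)")
    window = math.ceil(top_frac * g)
    members = set(gene_set.genes) & set(genes)
    if not members:
        raise ValueError(f"no genes of set {gene_set.name!r} in the ranking")
    m = len(members)
    hits = np.cumsum([1 if genes[i] in members else 0 for i in range(window)])
    max_area = sum(min(i, m) for i in range(1, window + 1))
    return float(hits.sum() / max_area)


def classify_ap_gp(
    expr: pd.DataFrame,
    ap_sig: GeneSet,
    gp_sig: GeneSet,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Label each sample accelerated-path-like or gradual-path-like.

    Both signatures are ssGSEA-scored per sample, each score is z-scored
    across samples (removing set-size bias), and the label follows the
    larger standardised score; exact ties are 'indeterminate'.  Needs at
    least two samples for the standardisation to be defined.
    """
    if expr.shape[1] < 2:
        raise ValueError("classification needs >= 2 samples (z-score undefined)")
    scores = ssgsea_matrix(expr, [ap_sig, gp_sig], alpha=alpha).data
    ap_raw = scores.loc[ap_sig.name].to_numpy()
    gp_raw = scores.loc[gp_sig.name].to_numpy()

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    ap_z, gp_z = z(ap_raw), z(gp_raw)
    margin = ap_z - gp_z
    label = np.where(margin > 0, "AP-like", np.where(margin < 0, "GP-like", "indeterminate"))
    return pd.DataFrame(
        {
            "ap_score": ap_raw,
            "gp_score": gp_raw,
            "ap_z": ap_z,
            "gp_z": gp_z,
            "margin": margin,
            "label": label,
        },
        index=pd.Index(expr.columns, name="sample"),
    )
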