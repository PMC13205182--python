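"""Screen genes whose expression tracks the inferred trajectory stage.

Within one subtype, each gene's expression is rank-correlated (Spearman)
with the per-sample maximum-a-posteriori stage; p-values are adjusted by
Benjamini-Hochberg within the screen, and a gene is selected when
|rho| exceeds the correlation threshold and the adjusted q falls below
the FDR level.  The absolute-value criterion is deliberate: stage-linked
genes may be down-regulated along the trajectory (negative rho) just as
well as up-regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import bh_adjust
from .ebm import AssignmentTable

__all__ = ["StageGeneTable", "stage_screen", "compare_screens", "spearman_by_gene"]

MIN_SAMPLES = 8


@dataclass
class StageGeneTable:
    """Per-gene stage-correlation screen for one subtype."""

    table: pd.DataFrame  # index gene: rho, p, q, tested, selected
    subtype: int
    rho_threshold: float
    fdr_threshold: float
    n_samples: int

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def spearman_by_gene(expr: pd.DataFrame, stage: np.ndarray) -> pd.DataFrame:
    """Vectorised Spearman rho and two-sided p for every gene row vs stage.

    Average ranks for ties; p from the t approximation (the standard
    large-sample reference).  Constant rows get rho = NaN and tested=False.
    """
    n = expr.shape[1]
    gene_ranks = stats.rankdata(expr.to_numpy(), axis=1)
    stage_ranks = stats.rankdata(stage)
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    sr = stage_ranks - stage_ranks.mean()
    denom = np.sqrt((gr**2).sum(axis=1) * (sr**2).sum())
    constant = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ sr) / denom
    rho[constant] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[constant] = np.nan
    return pd.DataFrame({"rho": rho, "p": p, "tested": ~constant}, index=expr.index)


def stage_screen(
    expr: pd.DataFrame,
    assignments: AssignmentTable,
    subtype: int,
    rho_threshold: float = 0.35,
    fdr_threshold: float = 0.05,
    stage: str = "map",
) -> StageGeneTable:
    """Spearman screen of expression (genes x samples) against stage.

    Only samples assigned (MAP) to ``subtype`` enter.  ``stage='map'``
    correlates against the MAP stage label; ``stage='posterior_mean'``
    against the stage-posterior mean.
    """
    if stage not in ("map", "posterior_mean"):
        raise ValueError(f"unknown stage summary {stage!r}")
    frame = assignments.to_frame()
    members = frame.index[frame["map_subtype"] == subtype]
    shared = [s for s in members if s in expr.columns]
    if not shared:
        raise ValueError("no overlapping samples between expression and assignments")
    if len(shared) < MIN_SAMPLES:
        raise ValueError(
            f"subtype {subtype} has {len(shared)} usable samples; need >= {MIN_SAMPLES}"
        )
    idx = [assignments.sample_ids.index(s) for s in shared]
    if stage == "map":
        stage_values = assignments.map_stage[idx].astype(float)
    else:
        n_stages = assignments.stage_posteriors.shape[1]
        stage_values = assignments.stage_posteriors[idx] @ np.arange(n_stages)
    sub_expr = expr[shared]
    table = spearman_by_gene(sub_expr, stage_values)
    tested = table["tested"].to_numpy()
    q = np.full(len(table), np.nan)
    if tested.any():
        q[tested] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["q"] = q
    with np.errstate(invalid="ignore"):
        table["selected"] = (
            tested
            & (np.abs(table["rho"].to_numpy()) > rho_threshold)
            & (table["q"].to_numpy() < fdr_threshold)
        )
    return StageGeneTable(
        table=table,
        subtype=subtype,
        rho_threshold=rho_threshold,
        fdr_threshold=fdr_threshold,
        n_samples=len(shared),
    )


def compare_screens(table_a: StageGeneTable, table_b: StageGeneTable) -> dict:
    """Set algebra on the selected genes of two screens."""
    universe_a, universe_b = set(table_a.table.index), set(table_b.table.index)
    if universe_a != universe_b:
        warnings.warn("screens cover different gene universes; using intersection")
    universe = universe_a & universe_b
    sel_a = set(table_a.selected_genes) & universe
    sel_b = set(table_b.selected_genes) & universe
    shared = sorted(sel_a & sel_b)
    only_a = sorted(sel_a - sel_b)
    only_b = sorted(sel_b - sel_a)
    return {
        "shared": shared,
        "unique_to_a": only_a,
        "unique_to_b": only_b,
        "n_shared": len(shared),
        "n_unique_to_a": len(only_a),
        "n_unique_to_b": len(only_b),
    }
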