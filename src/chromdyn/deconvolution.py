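"""Myonuclear stratification of bulk differential expression.

"Deconvolution" here is list-based stratification, not statistical mixture
deconvolution: genes carrying at least one differentially accessible
myonuclear peak in any condition form the myonuclear list, and bulk RNA-seq
differential-expression results are restricted to that list, split by the
gene's global accessibility association (gain, loss, or gain_and_loss).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .dynamics import DirectionSetTable
from .models import STATES, TIMES

ASSOCIATIONS = ("gain", "loss", "gain_and_loss")


def build_myonuclear_list(direction_sets: DirectionSetTable) -> pd.DataFrame:
    """Union of all differential genes with their accessibility association.

    Returns a DataFrame indexed by gene_id with one column ``association``:
    ``gain_and_loss`` iff the gene has both a gain and a loss peak somewhere
    across conditions.  An empty table yields an empty list with a warning.
    """
    gains: set[str] = set()
    losses: set[str] = set()
    for (state, time, direction), members in direction_sets.items():
        (gains if direction == "gain" else losses).update(members)
    all_genes = gains | losses
    if not all_genes:
        warnings.warn("direction-set table is empty; myonuclear list is empty")
    assoc = {
        g: "gain_and_loss" if (g in gains and g in losses) else ("gain" if g in gains else "loss")
        for g in all_genes
    }
    return pd.DataFrame(
        {"association": [assoc[g] for g in sorted(all_genes)]},
        index=pd.Index(sorted(all_genes), name="gene_id"),
    )


@dataclass
class StratifiedDE:
    """Per-condition up/down x association counts plus the gene-level table."""

    gene_table: pd.DataFrame
    counts: pd.DataFrame
    myonuclear_fraction: float


def stratify_de(
    de_table: pd.DataFrame,
    myo: pd.DataFrame,
    lfc_cut: float = 0.585,
    fdr_cut: float = 0.05,
    *,
    expressed_genes: set[str] | None = None,
) -> StratifiedDE:
    """Restrict bulk DE results to the myonuclear list and tally directions.

    ``de_table`` needs one row per gene per condition with columns
    ``gene_id``, ``condition``, ``log2fc``, ``fdr``.  A gene is up when
    log2fc >= +lfc_cut and fdr < fdr_cut, down when log2fc <= -lfc_cut and
    fdr < fdr_cut.  The myonuclear fraction is |myo & expressed| /
    |expressed| with ``expressed_genes`` defaulting to all genes in
    ``de_table``.
    """
    if lfc_cut <= 0 or fdr_cut <= 0:
        raise ValueError("thresholds must be > 0")
    required = {"gene_id", "condition", "log2fc", "fdr"}
    if not required <= set(de_table.columns):
        raise ValueError(f"de_table must have columns {sorted(required)}")
    tbl = de_table.copy()
    sig = tbl["fdr"] < fdr_cut
    tbl["direction"] = "none"
    tbl.loc[sig & (tbl["log2fc"] >= lfc_cut), "direction"] = "up"
    tbl.loc[sig & (tbl["log2fc"] <= -lfc_cut), "direction"] = "down"

    tbl = tbl[tbl["gene_id"].isin(myo.index)].copy()
    tbl["association"] = tbl["gene_id"].map(myo["association"])

    cells = []
    for cond in sorted(tbl["condition"].unique()):
        sub = tbl[(tbl["condition"] == cond) & (tbl["direction"] != "none")]
        for reg in ("up", "down"):
            for assoc in ASSOCIATIONS:
                n = int(((sub["direction"] == reg) & (sub["association"] == assoc)).sum())
                cells.append((cond, reg, assoc, n))
    counts = pd.DataFrame(cells, columns=["condition", "regulation", "association", "n_genes"])

    if expressed_genes is None:
        expressed_genes = set(de_table["gene_id"])
    frac = len(set(myo.index) & expressed_genes) / len(expressed_genes) if expressed_genes else 0.0
    return StratifiedDE(gene_table=tbl, counts=counts, myonuclear_fraction=frac)


def union_regulated_genes(stratified: StratifiedDE) -> set[str]:
    """Genes up- or downregulated in at least one condition."""
    tbl = stratified.gene_table
    return set(tbl.loc[tbl["direction"] != "none", "gene_id"])
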