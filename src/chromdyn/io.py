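"""Readers and writers for the pipeline's on-disk formats.

Peaks travel as BED6, matrices (counts, TPM, z-scores, motif counts,
activities) as TSV with a header row of sample/motif ids, gene models as a
GTF-like TSV with one row per gene, the sample design as TSV, direction sets
and the synthetic ground truth as JSON.  PWMs are read from JASPAR files via
Biopython, peak sequences from FASTA.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .models import CONDITION_LABELS, GeneModel, PeakRecord, SyntheticTruth
from .motifs import MotifModel


# ---------------------------------------------------------------------------
# peaks (BED6)

def write_peaks_bed(peaks: list[PeakRecord], path: str | Path) -> None:
    rows = [(p.chrom, p.start, p.end, p.peak_id, 0, ".") for p in peaks]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={"chrom": str, "name": str},
    )
    return [
        PeakRecord(r.chrom, int(r.start), int(r.end), r.name)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# gene models (GTF-like TSV, one row per gene)

def _fmt_ivs(ivs: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs) or "."


def _parse_ivs(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", "", None) or (isinstance(text, float) and np.isnan(text)):
        return ()
    return tuple(tuple(int(x) for x in part.split("-")) for part in text.split(";"))


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    rows = [
        (
            g.gene_id, g.chrom, g.strand, g.tss, g.tes,
            _fmt_ivs(g.exons), _fmt_ivs(g.utr5), _fmt_ivs(g.utr3),
        )
        for g in genes
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "strand", "tss", "tes", "exons", "utr5", "utr3"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    return [
        GeneModel(
            gene_id=r.gene_id, chrom=r.chrom, strand=r.strand,
            tss=int(r.tss), tes=int(r.tes),
            exons=_parse_ivs(r.exons), utr5=_parse_ivs(r.utr5), utr3=_parse_ivs(r.utr3),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# matrices and design

def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = out.index.name or index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


# ---------------------------------------------------------------------------
# synthetic truth / direction sets (JSON)

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize the ground truth; 'none' directions are omitted for size."""
    directions: dict[str, dict[str, str]] = {}
    arr = truth.directions
    mask = (arr != "none").any(axis=1)
    for pid in arr.index[mask]:
        row = arr.loc[pid]
        directions[pid] = {c: v for c, v in row.items() if v != "none"}
    payload = {
        "directions": directions,
        "myonuclear_genes": sorted(truth.myonuclear_genes),
        "peak_gene": truth.peak_gene.to_dict(),
        "atac_lib_factors": truth.atac_lib_factors.to_dict()
        if truth.atac_lib_factors is not None else None,
        "rna_lib_factors": truth.rna_lib_factors.to_dict()
        if truth.rna_lib_factors is not None else None,
        "expression_lfc": truth.expression_lfc.to_dict()
        if truth.expression_lfc is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    peak_gene = pd.Series(payload["peak_gene"], name="gene_id")
    directions = pd.DataFrame(
        "none", index=peak_gene.index, columns=list(CONDITION_LABELS)
    )
    for pid, conds in payload["directions"].items():
        for cond, d in conds.items():
            directions.loc[pid, cond] = d
    return SyntheticTruth(
        directions=directions,
        myonuclear_genes=frozenset(payload["myonuclear_genes"]),
        peak_gene=peak_gene,
        atac_lib_factors=pd.Series(payload["atac_lib_factors"])
        if payload.get("atac_lib_factors") else None,
        rna_lib_factors=pd.Series(payload["rna_lib_factors"])
        if payload.get("rna_lib_factors") else None,
        expression_lfc=pd.DataFrame(payload["expression_lfc"])
        if payload.get("expression_lfc") else None,
    )


def write_direction_sets(table: dict, path: str | Path) -> None:
    payload = {
        f"{state}_{time}_{direction}": sorted(members)
        for (state, time, direction), members in table.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_direction_sets(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    table = {}
    for key, members in payload.items():
        state, time, direction = key.rsplit("_", 2)
        table[(state, time, direction)] = set(members)
    return table


# ---------------------------------------------------------------------------
# sequences and PWMs

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_jaspar_motifs(
    path: str | Path,
    *,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    threshold_frac: float = 0.8,
) -> list[MotifModel]:
    """Load JASPAR-format PWMs as :class:`MotifModel` objects.

    Each motif's hit threshold defaults to ``threshold_frac`` of its maximal
    log2-odds score.
    """
    models = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            pwm = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
            pwm = pwm / pwm.sum(axis=0, keepdims=True)
            model = MotifModel(
                motif_id=m.name or m.matrix_id,
                pwm=tuple(tuple(float(x) for x in row) for row in pwm),
                background=background,
            )
            thr = threshold_frac * model.max_score()
            models.append(
                MotifModel(
                    motif_id=model.motif_id, pwm=model.pwm,
                    background=background, threshold=thr,
                )
            )
    return models
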