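"""Priority-ordered peak-to-gene annotation.

Each peak is assigned the single highest-priority feature class it overlaps —
promoter > 5'UTR > 3'UTR > exon > intron > downstream > intergenic — together
with the gene owning that feature.  Ties within a class are broken by the
smallest absolute distance from the peak midpoint to the candidate TSS (then
by gene id).  Peaks overlapping nothing fall back to intergenic with the
nearest-TSS gene.  Overlap means >= 1 bp intersection of the full peak
interval; all coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, PeakRecord

FEATURE_PRIORITY: tuple[str, ...] = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "intergenic",
)
_RANK = {cls: i for i, cls in enumerate(FEATURE_PRIORITY)}


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    feature_class: str
    gene_id: str
    distance_to_tss: int

    def __post_init__(self) -> None:
        if self.feature_class not in _RANK:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


class FeatureIndex:
    """Per-chromosome interval index over gene feature annotations."""

    def __init__(self) -> None:
        self.trees: dict[str, IntervalTree] = {}
        self.genes: dict[str, GeneModel] = {}
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}

    def add(self, chrom: str, start: int, end: int, feature: str, gene_id: str) -> None:
        if end <= start:
            return
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end, (feature, gene_id))

    def overlapping(self, peak: PeakRecord) -> list[tuple[str, str]]:
        """(feature_class, gene_id) pairs for every feature the peak touches."""
        tree = self.trees.get(peak.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(peak.start, peak.end)]

    def nearest_tss_gene(self, chrom: str, pos: int) -> str:
        positions, ids = self._tss[chrom]
        i = int(np.searchsorted(positions, pos))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(ids):
                cand = (abs(int(positions[j]) - pos), ids[j])
                best = cand if best is None or cand < best else best
        assert best is not None
        return best[1]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._tss


def tss_distance(gene: GeneModel, position: int) -> int:
    """Signed bp from a position to the gene's strand-aware TSS.

    Negative = upstream of the TSS in transcription orientation, positive =
    downstream.
    """
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position


def build_feature_index(
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_window: int = 3000,
) -> FeatureIndex:
    """Index promoter/UTR/exon/intron/downstream intervals of all genes.

    ``promoter_window`` is (upstream bp, downstream bp) relative to
    transcription direction around the strand-aware TSS; intervals are
    clipped at 0.  Duplicate gene ids raise.
    """
    up, down = promoter_window
    if up < 0 or down < 0 or downstream_window < 0:
        raise ValueError("windows must be >= 0")
    index = FeatureIndex()
    for gene in genes:
        if gene.gene_id in index.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        index.genes[gene.gene_id] = gene
        if gene.strand == "+":
            prom = (max(0, gene.tss - up), gene.tss + down)
            dstr = (gene.tes, gene.tes + downstream_window)
        else:
            prom = (max(0, gene.tss - down), gene.tss + up)
            dstr = (max(0, gene.tes - downstream_window), gene.tes)
        index.add(gene.chrom, *prom, "promoter", gene.gene_id)
        index.add(gene.chrom, *dstr, "downstream", gene.gene_id)
        for s, e in gene.utr5:
            index.add(gene.chrom, s, e, "utr5", gene.gene_id)
        for s, e in gene.utr3:
            index.add(gene.chrom, s, e, "utr3", gene.gene_id)
        exons = sorted(gene.exons)
        for s, e in exons:
            index.add(gene.chrom, s, e, "exon", gene.gene_id)
        for (s1, e1), (s2, e2) in zip(exons[:-1], exons[1:]):
            index.add(gene.chrom, e1, s2, "intron", gene.gene_id)
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append((gene.tss, gene.gene_id))
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        index._tss[chrom] = (np.array([p for p, _ in pairs]), [g for _, g in pairs])
    return index


def annotate_peak(
    peak: PeakRecord,
    index: FeatureIndex,
    *,
    missing_chrom: str = "error",
) -> PeakAnnotation:
    """Annotate one peak by feature priority.

    ``missing_chrom`` controls peaks on chromosomes absent from the index:
    ``"error"`` (default) raises; ``"intergenic"`` is not meaningful without
    a nearest gene and also raises.
    """
    if not index.genes:
        raise ValueError("empty gene index")
    if not index.has_chrom(peak.chrom):
        raise ValueError(f"chromosome {peak.chrom!r} not present in the index")
    hits = index.overlapping(peak)
    mid = peak.midpoint
    if hits:
        best = min(
            hits,
            key=lambda h: (
                _RANK[h[0]],
                abs(tss_distance(index.genes[h[1]], mid)),
                h[1],
            ),
        )
        feature, gene_id = best
    else:
        feature = "intergenic"
        gene_id = index.nearest_tss_gene(peak.chrom, mid)
    return PeakAnnotation(
        peak_id=peak.peak_id,
        feature_class=feature,
        gene_id=gene_id,
        distance_to_tss=tss_distance(index.genes[gene_id], mid),
    )


def annotate_peaks(
    peaks: list[PeakRecord],
    index: FeatureIndex,
) -> pd.DataFrame:
    """Annotate many peaks; returns a DataFrame indexed by peak_id."""
    anns = [annotate_peak(p, index) for p in peaks]
    return pd.DataFrame(
        {
            "feature_class": [a.feature_class for a in anns],
            "gene_id": [a.gene_id for a in anns],
            "distance_to_tss": [a.distance_to_tss for a in anns],
        },
        index=pd.Index([a.peak_id for a in anns], name="peak_id"),
    )


def feature_distribution(annotations: list[PeakAnnotation] | pd.DataFrame) -> dict[str, float]:
    """Fraction of peaks per feature class; fractions sum to 1."""
    if isinstance(annotations, pd.DataFrame):
        classes = list(annotations["feature_class"])
    else:
        classes = [a.feature_class for a in annotations]
    if not classes:
        raise ValueError("empty annotation list")
    n = len(classes)
    out: dict[str, float] = {}
    for cls in classes:
        out[cls] = out.get(cls, 0.0) + 1.0
    return {cls: cnt / n for cls, cnt in sorted(out.items(), key=lambda kv: _RANK[kv[0]])}
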