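"""Annotation priority, windows, and equivalence with a brute-force oracle."""

import numpy as np
import pytest

from chromdyn import (
    GeneModel,
    PeakRecord,
    annotate_peak,
    annotate_peaks,
    build_feature_index,
    feature_distribution,
    generate_gene_models,
)
from chromdyn.annotation import FEATURE_PRIORITY, PeakAnnotation, tss_distance
from chromdyn.simulate import default_chrom_lengths

_RANK = {cls: i for i, cls in enumerate(FEATURE_PRIORITY)}


def _plus_gene(gene_id="gA", chrom="chr1", start=10_000, end=20_000):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        tss=start,
        tes=end,
        exons=((start, start + 1000), (end - 1000, end)),
        utr5=((start, start + 200),),
        utr3=((end - 200, end),),
    )


def _minus_gene(gene_id="gB", chrom="chr1", start=40_000, end=50_000):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="-",
        tss=end,
        tes=start,
        exons=((start, start + 1000), (end - 1000, end)),
        utr5=((end - 200, end),),
        utr3=((start, start + 200),),
    )


def test_plus_strand_promoter_window_arithmetic():
    g = _plus_gene()
    idx = build_feature_index([g], promoter_window=(3000, 3000))
    # inside [tss-3000, tss+3000): promoter
    ann = annotate_peak(PeakRecord("chr1", 7_100, 7_200, "p1"), idx)
    assert ann.feature_class == "promoter"
    # just upstream of the window: intergenic fallback
    ann = annotate_peak(PeakRecord("chr1", 6_000, 6_900, "p2"), idx)
    assert ann.feature_class == "intergenic"
    assert ann.gene_id == "gA"


def test_minus_strand_promoter_centered_on_high_coordinate():
    g = _minus_gene()
    idx = build_feature_index([g], promoter_window=(3000, 3000))
    ann = annotate_peak(PeakRecord("chr1", 52_000, 52_400, "p1"), idx)
    assert ann.feature_class == "promoter"
    # distance is negative upstream in transcription orientation (right of TSS)
    assert ann.distance_to_tss < 0


def test_priority_promoter_beats_intron():
    a = _plus_gene("gA", start=10_000, end=20_000)
    # gene whose promoter window covers gA's intron region
    b = GeneModel(
        gene_id="gB",
        chrom="chr1",
        strand="+",
        tss=18_000,
        tes=30_000,
        exons=((18_000, 18_500), (29_000, 30_000)),
    )
    idx = build_feature_index([a, b], promoter_window=(3000, 3000))
    # 15_500-15_600 is inside gA's intron and inside gB's promoter window
    ann = annotate_peak(PeakRecord("chr1", 15_500, 15_600, "p"), idx)
    assert ann.feature_class == "promoter"
    assert ann.gene_id == "gB"


def test_intergenic_fallback_with_distance():
    g = _plus_gene(start=100_000, end=110_000)
    idx = build_feature_index([g])
    ann = annotate_peak(PeakRecord("chr1", 49_950, 50_050, "far"), idx)
    assert ann.feature_class == "intergenic"
    assert ann.gene_id == "gA"
    assert ann.distance_to_tss == 50_000 - 100_000


def test_unknown_chromosome_and_empty_index_raise():
    g = _plus_gene()
    idx = build_feature_index([g])
    with pytest.raises(ValueError):
        annotate_peak(PeakRecord("chr9", 0, 100, "p"), idx)
    with pytest.raises(ValueError):
        annotate_peak(PeakRecord("chr1", 0, 100, "p"), FeatureIndex_empty())


def FeatureIndex_empty():
    from chromdyn.annotation import FeatureIndex

    return FeatureIndex()


def test_duplicate_gene_id_rejected():
    with pytest.raises(ValueError):
        build_feature_index([_plus_gene("dup"), _plus_gene("dup", start=30_000, end=38_000)])


def _oracle_features(gene, up=3000, down=3000, dstr=3000):
    """Independent enumeration of one gene's feature intervals."""
    feats = []
    if gene.strand == "+":
        feats.append(("promoter", max(0, gene.tss - up), gene.tss + down))
        feats.append(("downstream", gene.tes, gene.tes + dstr))
    else:
        feats.append(("promoter", max(0, gene.tss - down), gene.tss + up))
        feats.append(("downstream", max(0, gene.tes - dstr), gene.tes))
    for s, e in gene.utr5:
        feats.append(("utr5", s, e))
    for s, e in gene.utr3:
        feats.append(("utr3", s, e))
    ex = sorted(gene.exons)
    for s, e in ex:
        feats.append(("exon", s, e))
    for (s1, e1), (s2, e2) in zip(ex[:-1], ex[1:]):
        if e1 < s2:
            feats.append(("intron", e1, s2))
    return feats


def _oracle_annotate(peak, genes):
    """Exhaustive overlap enumeration + priority, written independently."""
    mid = (peak.start + peak.end) // 2
    candidates = []
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = mid - g.tss if g.strand == "+" else g.tss - mid
        for cls, s, e in _oracle_features(g):
            if peak.start < e and s < peak.end and s < e:
                candidates.append((_RANK[cls], abs(d), g.gene_id, cls, d))
    if candidates:
        _, _, gid, cls, d = min(candidates)
        return cls, gid, d
    same = [g for g in genes if g.chrom == peak.chrom]
    g = min(same, key=lambda g: (abs(g.tss - mid), g.gene_id))
    d = mid - g.tss if g.strand == "+" else g.tss - mid
    return "intergenic", g.gene_id, d


def test_oracle_equivalence_on_random_peaks():
    genes = generate_gene_models(40, default_chrom_lengths(40), seed=21)
    idx = build_feature_index(genes)
    rng = np.random.default_rng(21)
    span = max(g.end for g in genes) + 10_000
    chroms = sorted({g.chrom for g in genes})
    for i in range(200):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        peak = PeakRecord(chrom, start, start + int(rng.integers(50, 800)), f"p{i}")
        got = annotate_peak(peak, idx)
        cls, gid, dist = _oracle_annotate(peak, genes)
        assert (got.feature_class, got.gene_id, got.distance_to_tss) == (cls, gid, dist)


def test_translation_invariance():
    genes = generate_gene_models(15, {"chr1": 600_000}, seed=3)
    shift = 12_345
    shifted = [
        GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            strand=g.strand,
            tss=g.tss + shift,
            tes=g.tes + shift,
            exons=tuple((s + shift, e + shift) for s, e in g.exons),
            utr5=tuple((s + shift, e + shift) for s, e in g.utr5),
            utr3=tuple((s + shift, e + shift) for s, e in g.utr3),
        )
        for g in genes
    ]
    idx = build_feature_index(genes)
    idx_s = build_feature_index(shifted)
    rng = np.random.default_rng(8)
    for i in range(100):
        start = int(rng.integers(0, 580_000))
        p = PeakRecord("chr1", start, start + 300, f"p{i}")
        ps = PeakRecord("chr1", start + shift, start + shift + 300, f"p{i}")
        a, b = annotate_peak(p, idx), annotate_peak(ps, idx_s)
        assert (a.feature_class, a.gene_id, a.distance_to_tss) == (
            b.feature_class,
            b.gene_id,
            b.distance_to_tss,
        )


def test_feature_distribution_hand_counts():
    anns = [PeakAnnotation(f"p{i}", "promoter", "g", 0) for i in range(4)]
    anns += [PeakAnnotation(f"q{i}", "intron", "g", 0) for i in range(5)]
    anns += [PeakAnnotation("r0", "intergenic", "g", 0)]
    dist = feature_distribution(anns)
    assert dist == {"promoter": 0.4, "intron": 0.5, "intergenic": 0.1}
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
    only = feature_distribution([PeakAnnotation("x", "promoter", "g", 0)])
    assert only == {"promoter": 1.0}
    with pytest.raises(ValueError):
        feature_distribution([])
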