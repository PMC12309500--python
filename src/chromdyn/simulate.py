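"""Synthetic genomes, peak sets, count matrices, expression and motif data.

The generator plants the effect structure the downstream analysis is designed
to detect: negative-binomial fragment counts per peak with group means shifted
by a planted log2 fold change relative to the sedentary baseline, chromatin
closing at 0 h amplified in the trained state, an untrained gain wave peaking
at 6 h with a configurable de-novo share, a reversal subset (gained in
untrained / lost in trained at 0 h), state-specific survival of effects into
later time points, expression changes confined to a myonuclear-responsive
gene subset, and motif-count/activity structure with an immediate-early motif
group peaking at trained 0 h and untrained 6 h.

Each output artifact draws from its own RNG stream derived from the master
seed by a fixed offset, so adding artifacts never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    CONDITION_LABELS,
    CONDITIONS,
    SEDENTARY,
    STATES,
    TIMES,
    CountMatrix,
    EffectSpec,
    GeneModel,
    PeakRecord,
    SyntheticTruth,
    condition_label,
)

# fixed per-artifact RNG stream offsets (master seed is spawned with these)
_STREAM_GENES = 1
_STREAM_PEAKS = 2
_STREAM_EXPR = 3
_STREAM_MOTIF = 4

#: immediate-early transcription-factor motif names used for the planted subset
IEG_MOTIFS = ("Fos", "Jun", "Junb_Jund", "Atf3", "Egr1", "Egr3", "Cebpb", "Nr4a2")

_MIN_GENE_LEN = 2000


def make_design(n_per_group: int = 3) -> pd.DataFrame:
    """Sample design table: sedentary baseline plus the 2x3 exercised grid."""
    rows = []
    for r in range(1, n_per_group + 1):
        rows.append((f"sedentary_rep{r}", SEDENTARY, "NA"))
    for state, time in CONDITIONS:
        for r in range(1, n_per_group + 1):
            rows.append((f"{state}_{time}_rep{r}", state, time))
    design = pd.DataFrame(rows, columns=["sample_id", "state", "time"])
    return design.set_index("sample_id")


def generate_gene_models(
    n_genes: int,
    chrom_lengths: dict[str, int],
    seed: int,
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes across the given chromosomes.

    Genes are laid down sequentially per chromosome with random inter-gene
    gaps; each gene gets 3-8 exons (first/last flush with the body ends),
    strand-aware 5'/3' UTRs carved from the terminal exons, and a random
    strand.  Output is sorted by coordinate and deterministic for a seed.
    Raises ``ValueError`` if the chromosomes cannot host all genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([_STREAM_GENES, seed])
    chroms = sorted(chrom_lengths)
    cursors = {c: 0 for c in chroms}
    placed: list[tuple[str, int, int]] = []  # (chrom, start, end)
    active = list(chroms)
    while len(placed) < n_genes:
        if not active:
            raise ValueError(
                f"cannot place {n_genes} genes on chromosomes of total length "
                f"{sum(chrom_lengths.values())}"
            )
        for chrom in list(active):
            if len(placed) == n_genes:
                break
            rem = chrom_lengths[chrom] - cursors[chrom]
            if rem < _MIN_GENE_LEN + 200:
                active.remove(chrom)
                continue
            gap_hi = min(10000, rem - _MIN_GENE_LEN)
            gap = int(rng.integers(200, gap_hi + 1)) if gap_hi > 200 else 200
            rem2 = chrom_lengths[chrom] - (cursors[chrom] + gap)
            if rem2 < _MIN_GENE_LEN:
                active.remove(chrom)
                continue
            length = int(rng.integers(_MIN_GENE_LEN, min(24000, rem2) + 1))
            start = cursors[chrom] + gap
            placed.append((chrom, start, start + length))
            cursors[chrom] = start + length
    placed.sort()

    genes: list[GeneModel] = []
    width = max(4, len(str(n_genes)))
    for i, (chrom, start, end) in enumerate(placed):
        length = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(3, 9))
        k = 2 * n_ex - 1  # exon/intron/exon/... segments
        cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False))
        bounds = np.concatenate(([0], cuts, [length])) + start
        segments = [(int(bounds[j]), int(bounds[j + 1])) for j in range(k)]
        exons = tuple(segments[::2])
        first, last = (exons[0], exons[-1]) if strand == "+" else (exons[-1], exons[0])
        u5_len = int(rng.integers(30, max(31, min(300, first[1] - first[0]))))
        u3_len = int(rng.integers(30, max(31, min(300, last[1] - last[0]))))
        if strand == "+":
            utr5 = ((first[0], first[0] + u5_len),)
            utr3 = ((last[1] - u3_len, last[1]),)
            tss, tes = start, end
        else:
            utr5 = ((first[1] - u5_len, first[1]),)
            utr3 = ((last[0], last[0] + u3_len),)
            tss, tes = end, start
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:0{width}d}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                tes=tes,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def _introns(gene: GeneModel) -> list[tuple[int, int]]:
    ex = sorted(gene.exons)
    return [(ex[j][1], ex[j + 1][0]) for j in range(len(ex) - 1) if ex[j][1] < ex[j + 1][0]]


def _place_peaks(
    genes: list[GeneModel],
    n_peaks: int,
    rng: np.random.Generator,
    weights: np.ndarray,
    placement_fracs: tuple[float, float, float],
    peak_width: tuple[int, int],
) -> tuple[list[tuple[str, int, int]], list[str]]:
    """Place peaks in promoter / intron / intergenic / exon compartments.

    Returns raw (chrom, start, end) triples plus the owning/nearest gene id
    for each peak, in placement order.
    """
    prom_f, intron_f, inter_f = placement_fracs
    exon_f = 1.0 - prom_f - intron_f - inter_f
    if exon_f < -1e-9:
        raise ValueError("placement fractions exceed 1")
    probs = np.array([prom_f, intron_f, inter_f, max(0.0, exon_f)])
    probs = probs / probs.sum()

    # intergenic gaps: space outside gene bodies extended by the promoter /
    # downstream windows, so intergenic placements annotate as intergenic
    margin = 3200
    gaps: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs[:-1], gs[1:]):
            lo, hi = a.end + margin, b.start - margin
            if hi - lo >= peak_width[1] + 100:
                gaps.append((chrom, lo, hi))
    gap_lens = np.array([hi - lo for _, lo, hi in gaps], dtype=float)

    # per-gene intron/exon intervals far enough from the TSS to keep their class
    intron_pool: list[list[tuple[int, int]]] = []
    exon_pool: list[list[tuple[int, int]]] = []
    for g in genes:
        far = lambda s, e: min(abs(s - g.tss), abs(e - g.tss)) > margin
        intron_pool.append([iv for iv in _introns(g) if far(*iv) and iv[1] - iv[0] >= 700])
        exon_pool.append([iv for iv in sorted(g.exons) if far(*iv) and iv[1] - iv[0] >= 80])

    tss_by_chrom = {
        chrom: sorted((g.tss, g.gene_id) for g in gs) for chrom, gs in by_chrom.items()
    }

    raw: list[tuple[str, int, int]] = []
    owners: list[str] = []
    categories = rng.choice(4, size=n_peaks, p=probs)
    for cat in categories:
        w = int(rng.integers(peak_width[0], peak_width[1] + 1))
        placed = False
        if cat in (0, 1, 3):  # gene-anchored
            for _ in range(60):
                gi = int(rng.choice(len(genes), p=weights))
                g = genes[gi]
                if cat == 0:  # promoter
                    center = g.tss + int(rng.integers(-800, 801))
                    start = max(0, center - w // 2)
                    raw.append((g.chrom, start, start + w))
                    owners.append(g.gene_id)
                    placed = True
                    break
                pool = intron_pool[gi] if cat == 1 else exon_pool[gi]
                if not pool:
                    continue
                s, e = pool[int(rng.integers(len(pool)))]
                ww = min(w, e - s - 2)
                start = int(rng.integers(s, e - ww))
                raw.append((g.chrom, start, start + ww))
                owners.append(g.gene_id)
                placed = True
                break
        if cat == 2 or not placed:  # intergenic (also the fallback)
            if not gaps:
                raise ValueError("no intergenic space available; enlarge chromosomes")
            gi = int(rng.choice(len(gaps), p=gap_lens / gap_lens.sum()))
            chrom, lo, hi = gaps[gi]
            start = int(rng.integers(lo, hi - w))
            raw.append((chrom, start, start + w))
            tss_list = tss_by_chrom[chrom]
            mid = start + w // 2
            owners.append(min(tss_list, key=lambda t: abs(t[0] - mid))[1])
    return raw, owners


def _survive(rng: np.random.Generator, ids: list[str], p: float) -> list[str]:
    if p >= 1.0:
        return list(ids)
    keep = rng.random(len(ids)) < p
    return [pid for pid, k in zip(ids, keep) if k]


def generate_peaks_and_counts(
    genes: list[GeneModel],
    n_peaks: int,
    design: pd.DataFrame,
    spec: EffectSpec,
    seed: int,
    *,
    placement_fracs: tuple[float, float, float] = (0.105, 0.45, 0.318),
    peak_width: tuple[int, int] = (200, 600),
    base_mean: float = 80.0,
    base_sigma: float = 0.6,
    lib_sigma: float = 0.2,
) -> tuple[list[PeakRecord], CountMatrix, SyntheticTruth]:
    """Generate peaks, NB fragment counts and the planted ground truth.

    ``placement_fracs`` gives the (promoter, intron, intergenic) placement
    probabilities; the remainder lands in exons.  Counts follow
    NB(mean mu, var mu + alpha*mu^2): sedentary keeps the baseline mean, and
    a planted peak's mean is shifted by ``2**(+/- lfc_magnitude)`` in each
    affected (state, time) group.  Per-sample library factors are drawn
    log-normal(0, ``lib_sigma``).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if design is None or len(design) == 0:
        raise ValueError("design must be non-empty")
    if not genes:
        raise ValueError("at least one gene model is required")
    rng = np.random.default_rng([_STREAM_PEAKS, seed])

    gene_ids = [g.gene_id for g in genes]
    n_resp = int(round(spec.myonuclear_frac * len(genes)))
    responsive = set(rng.choice(gene_ids, size=n_resp, replace=False)) if n_resp else set()
    # responsive genes attract more peaks so planted effects can concentrate
    # on them; the gene-level myonuclear share is unaffected
    weights = np.array([2.0 if g in responsive else 1.0 for g in gene_ids])
    weights /= weights.sum()

    raw, owners = _place_peaks(genes, n_peaks, rng, weights, placement_fracs, peak_width)
    order = sorted(range(n_peaks), key=lambda i: raw[i])
    width = max(5, len(str(n_peaks)))
    peaks = [
        PeakRecord(raw[i][0], raw[i][1], raw[i][2], f"peak_{rank + 1:0{width}d}")
        for rank, i in enumerate(order)
    ]
    peak_ids = [p.peak_id for p in peaks]
    peak_gene = pd.Series([owners[i] for i in order], index=peak_ids, name="gene_id")

    # --- plant effects -----------------------------------------------------
    n_loss_u = int(round(spec.frac_loss_0h_untrained * n_peaks))
    n_loss_t = int(round(spec.amplification_trained * n_loss_u))
    n_gain6 = int(round(spec.frac_gain_6h_untrained * n_peaks))
    n_gain0 = int(round((1.0 - spec.frac_de_novo_6h) * n_gain6))
    n_rev = int(round(spec.reversal_frac * n_gain0))
    n_extra = max(0, n_loss_t - n_loss_u - n_rev)

    eligible = [pid for pid in peak_ids if peak_gene[pid] in responsive]
    if not responsive:
        eligible = list(peak_ids)
    needed = n_loss_u + n_extra + n_gain6
    if needed > len(eligible):
        raise ValueError(
            f"planting needs {needed} peaks near responsive genes but only "
            f"{len(eligible)} are available; raise n_peaks or myonuclear_frac"
        )
    pool = list(rng.permutation(eligible))
    loss_u = pool[:n_loss_u]
    gain6 = pool[n_loss_u : n_loss_u + n_gain6]
    gain0 = gain6[:n_gain0]
    reversal = gain0[:n_rev]
    extra = pool[n_loss_u + n_gain6 : n_loss_u + n_gain6 + n_extra]
    loss_t = (loss_u + reversal + extra)[:n_loss_t]

    directions = pd.DataFrame("none", index=peak_ids, columns=list(CONDITION_LABELS))

    def _set(ids: list[str], state: str, time: str, direction: str) -> None:
        if ids:
            directions.loc[ids, condition_label(state, time)] = direction

    pu1, pu2 = spec.retention_profile.get("untrained", (0.5, 0.0))
    pt1, pt2 = spec.retention_profile.get("trained", (0.75, 0.6))
    _set(loss_u, "untrained", "0h", "loss")
    lu6 = _survive(rng, loss_u, pu1)
    _set(lu6, "untrained", "6h", "loss")
    _set(_survive(rng, lu6, pu2), "untrained", "72h", "loss")
    _set(loss_t, "trained", "0h", "loss")
    lt6 = _survive(rng, loss_t, pt1)
    _set(lt6, "trained", "6h", "loss")
    _set(_survive(rng, lt6, pt2), "trained", "72h", "loss")
    _set(gain0, "untrained", "0h", "gain")
    _set(gain6, "untrained", "6h", "gain")
    _set(_survive(rng, gain6, pu2), "untrained", "72h", "gain")

    planted_mask = (directions != "none").any(axis=1)
    planted_owner_genes = set(peak_gene[planted_mask])
    if responsive:
        planted_owner_genes &= responsive
    planted_genes = frozenset(planted_owner_genes)

    # --- draw counts -------------------------------------------------------
    samples = list(design.index)
    lib = pd.Series(rng.lognormal(0.0, lib_sigma, len(samples)), index=samples)
    mu0 = rng.lognormal(np.log(base_mean), base_sigma, n_peaks)

    lfc = np.zeros((n_peaks, len(samples)))
    sample_cond = [
        condition_label(design.loc[s, "state"], None if design.loc[s, "state"] == SEDENTARY else design.loc[s, "time"])
        for s in samples
    ]
    dir_arr = directions.to_numpy()
    cond_index = {c: j for j, c in enumerate(CONDITION_LABELS)}
    for j, cond in enumerate(sample_cond):
        if cond == SEDENTARY:
            continue
        col = dir_arr[:, cond_index[cond]]
        lfc[col == "gain", j] = spec.lfc_magnitude
        lfc[col == "loss", j] = -spec.lfc_magnitude

    mu = mu0[:, None] * np.exp2(lfc) * lib.to_numpy()[None, :]
    if spec.dispersion > 0:
        r = 1.0 / spec.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=peak_ids, columns=samples)

    truth = SyntheticTruth(
        directions=directions,
        myonuclear_genes=planted_genes,
        peak_gene=peak_gene,
        atac_lib_factors=lib,
    )
    return peaks, CountMatrix(counts=counts_df, design=design.copy()), truth


def generate_expression(
    genes: list[GeneModel],
    design: pd.DataFrame,
    truth: SyntheticTruth,
    seed: int,
    *,
    expr_lfc: float = 1.2,
    align_prob: float = 0.7,
    dispersion: float = 0.05,
    base_mean: float = 50.0,
    base_sigma: float = 1.0,
    lib_sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk expression (TPM and integer gene counts) aligned with the truth.

    Myonuclear-flagged genes whose chromatin has a planted direction in a
    condition receive a planted expression log2FC of magnitude ``expr_lfc``
    whose sign agrees with the accessibility direction with probability
    ``align_prob`` (the coupling is deliberately loose).  TPM columns each
    sum to 1e6.  The planted expression table and RNA library factors are
    recorded on ``truth``.
    """
    gene_ids = [g.gene_id for g in genes]
    gene_set = set(gene_ids)
    if not set(truth.peak_gene) <= gene_set or not set(truth.myonuclear_genes) <= gene_set:
        raise ValueError("truth refers to genes absent from the gene models")
    rng = np.random.default_rng([_STREAM_EXPR, seed])

    # gene-level accessibility direction per condition
    gene_dir = {}
    for cond in CONDITION_LABELS:
        col = truth.directions[cond]
        by_gene: dict[str, set[str]] = {}
        for pid, d in col.items():
            if d != "none":
                by_gene.setdefault(truth.peak_gene[pid], set()).add(d)
        gene_dir[cond] = by_gene

    lfc = pd.DataFrame(0.0, index=gene_ids, columns=list(CONDITION_LABELS))
    for cond in CONDITION_LABELS:
        for gid, ds in gene_dir[cond].items():
            if gid not in truth.myonuclear_genes:
                continue
            if ds == {"gain"}:
                sign = 1.0
            elif ds == {"loss"}:
                sign = -1.0
            else:
                sign = 1.0 if rng.random() < 0.5 else -1.0
            if rng.random() >= align_prob:
                sign = -sign
            lfc.loc[gid, cond] = sign * expr_lfc

    samples = list(design.index)
    lib = pd.Series(rng.lognormal(0.0, lib_sigma, len(samples)), index=samples)
    mu0 = rng.lognormal(np.log(base_mean), base_sigma, len(gene_ids))
    lfc_mat = np.zeros((len(gene_ids), len(samples)))
    for j, s in enumerate(samples):
        state = design.loc[s, "state"]
        if state == SEDENTARY:
            continue
        cond = condition_label(state, design.loc[s, "time"])
        lfc_mat[:, j] = lfc[cond].to_numpy()
    mu = mu0[:, None] * np.exp2(lfc_mat) * lib.to_numpy()[None, :]
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    gene_counts = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=samples)
    colsum = gene_counts.sum(axis=0).replace(0, 1).astype(float)
    tpm = gene_counts / colsum * 1e6

    truth.expression_lfc = lfc
    truth.rna_lib_factors = lib
    return tpm, gene_counts


def generate_motif_structure(
    peaks: list[PeakRecord],
    n_motifs: int,
    design: pd.DataFrame,
    seed: int,
    *,
    noise_sd: float = 0.1,
    site_rate: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Motif-count matrix, planted per-group activities, and the peak signal.

    The expected peak signal is ``motif_counts @ planted_activity`` for each
    sample's group, plus Gaussian noise of sd ``noise_sd``.  A designated
    immediate-early motif subset gets activity peaking at trained 0 h and
    untrained 6 h.  Activity rows are centered across groups.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = np.random.default_rng([_STREAM_MOTIF, seed])
    n_ieg = min(len(IEG_MOTIFS), max(1, int(round(0.3 * n_motifs))))
    motif_ids = list(IEG_MOTIFS[:n_ieg]) + [
        f"motif_{i + 1:02d}" for i in range(n_motifs - n_ieg)
    ]
    peak_ids = [p.peak_id for p in peaks]
    counts = pd.DataFrame(
        rng.poisson(site_rate, (len(peak_ids), n_motifs)).astype(np.int64),
        index=peak_ids,
        columns=motif_ids,
    )

    groups = [SEDENTARY] + list(CONDITION_LABELS)
    ieg_template = {
        SEDENTARY: -0.5,
        "untrained_0h": 0.4,
        "untrained_6h": 1.8,
        "untrained_72h": -0.5,
        "trained_0h": 2.0,
        "trained_6h": 0.5,
        "trained_72h": -0.5,
    }
    act = np.empty((n_motifs, len(groups)))
    for i in range(n_motifs):
        if i < n_ieg:
            scale = rng.uniform(0.8, 1.2)
            act[i] = [scale * ieg_template[g] for g in groups]
            act[i] += rng.normal(0.0, 0.1, len(groups))
        else:
            act[i] = rng.normal(0.0, 0.4, len(groups))
    act -= act.mean(axis=1, keepdims=True)
    activity = pd.DataFrame(act, index=motif_ids, columns=groups)

    samples = list(design.index)
    sig = np.empty((len(peak_ids), len(samples)))
    cmat = counts.to_numpy(dtype=float)
    for j, s in enumerate(samples):
        state = design.loc[s, "state"]
        cond = SEDENTARY if state == SEDENTARY else condition_label(state, design.loc[s, "time"])
        sig[:, j] = cmat @ activity[cond].to_numpy()
        if noise_sd > 0:
            sig[:, j] += rng.normal(0.0, noise_sd, len(peak_ids))
    signal = pd.DataFrame(sig, index=peak_ids, columns=samples)
    return counts, activity, signal


@dataclass
class SimulatedDataset:
    """One full synthetic study, bundling every generated artifact."""

    genes: list[GeneModel]
    peaks: list[PeakRecord]
    counts: CountMatrix
    truth: SyntheticTruth
    tpm: pd.DataFrame
    gene_counts: pd.DataFrame
    motif_counts: pd.DataFrame
    motif_activity: pd.DataFrame
    motif_signal: pd.DataFrame
    spec: EffectSpec = field(default_factory=EffectSpec)


def default_chrom_lengths(n_genes: int, n_chroms: int = 2) -> dict[str, int]:
    """Chromosome sizes comfortably hosting ``n_genes`` synthetic genes."""
    per = math.ceil(n_genes / n_chroms)
    length = per * 40000 + 20000
    return {f"chr{i + 1}": length for i in range(n_chroms)}


def simulate_dataset(
    seed: int,
    *,
    n_genes: int = 300,
    n_peaks: int = 2000,
    n_motifs: int = 20,
    spec: EffectSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
    motif_noise_sd: float = 0.1,
) -> SimulatedDataset:
    """Generate a complete synthetic study with the default effect structure."""
    spec = spec if spec is not None else EffectSpec()
    chrom_lengths = chrom_lengths or default_chrom_lengths(n_genes)
    genes = generate_gene_models(n_genes, chrom_lengths, seed)
    design = make_design(spec.n_per_group)
    peaks, counts, truth = generate_peaks_and_counts(genes, n_peaks, design, spec, seed)
    tpm, gene_counts = generate_expression(genes, design, truth, seed)
    mcounts, mactivity, msignal = generate_motif_structure(
        peaks, n_motifs, design, seed, noise_sd=motif_noise_sd
    )
    truth.motif_activity = mactivity
    return SimulatedDataset(
        genes=genes,
        peaks=peaks,
        counts=counts,
        truth=truth,
        tpm=tpm,
        gene_counts=gene_counts,
        motif_counts=mcounts,
        motif_activity=mactivity,
        motif_signal=msignal,
        spec=spec,
    )
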