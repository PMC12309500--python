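# chromdyn

Temporal chromatin-accessibility dynamics in skeletal-muscle myonuclei.

Endurance-trained and untrained muscle respond differently to a single
exhaustive exercise bout: training amplifies the rapid closing of chromatin
immediately post-exercise and stabilizes those changes for days, while an
untrained accessibility gain peaks hours later and fades. `chromdyn`
implements the downstream analysis that quantifies this: per-peak
differential accessibility of every (training state × time) condition
against a sedentary baseline, priority-ordered peak-to-gene annotation,
temporal gain/loss set algebra (overlaps, reversal, de-novo emergence,
retention taxonomy), ATAC-guided stratification of bulk RNA-seq into a
myonuclear gene subset, z-score expression summaries, and a linear
motif-activity model for transcription-factor inference. A synthetic-data
generator plants the full effect structure so every stage runs and is
tested without any sequencing download.

It is written for computational biologists analysing ATAC-seq / RNA-seq
time courses with a factorial design and a common baseline.

## The model in brief

Fragment counts for peak *i* in sample *j* follow a negative binomial,

```
y_ij ~ NB(mu_ij, alpha_i),   mu_ij = s_j * q_g(j),   Var = mu + alpha * mu^2
```

with median-of-ratios size factors `s_j`, per-peak dispersion `alpha_i`
(method of moments, shrunk toward a mean trend), and per-group abundances
`q_g` fitted by maximum likelihood. Each exercised condition is Wald-tested
against sedentary (`log2FC = log2(q_cond/q_sed)`, SE from Fisher
information), with Benjamini–Hochberg FDR per contrast and gain/loss calls
at FDR < 0.05. Gene-level direction sets feed the set algebra; expression
uses the same machinery on gene counts with `|log2FC| >= 0.585`. Motif
activities `A` solve `min_A ||signal - C A||^2 + lambda ||A||^2` for the
peaks × motifs site-count matrix `C`. Details and assumptions:
[docs/methods.md](docs/methods.md).

## Worked example

The `chromdyn` CLI chains the whole pipeline on a simulated study
(300 genes, 2 000 peaks, 3 replicates in each of 7 groups):

```bash
printf 'n_genes: 300\nn_peaks: 2000\nn_motifs: 20\n' > config.yaml
chromdyn simulate  --config config.yaml --seed 1 --outdir run
chromdyn annotate  --genes run/genes.tsv --peaks run/peaks.bed --out run/annotations.tsv
chromdyn diff      --counts run/counts.tsv --design run/design.tsv --outdir run
chromdyn dynamics  --diff-dir run --annotations run/annotations.tsv --outdir run
chromdyn stratify  --gene-counts run/gene_counts.tsv --design run/design.tsv \
                   --direction-sets run/direction_sets.json --tpm run/tpm.tsv --outdir run
chromdyn summarize --tpm run/tpm.tsv --design run/design.tsv \
                   --genes run/regulated_genes.json --outdir run
chromdyn motifs    --motif-counts run/motif_counts.tsv --signal run/motif_signal.tsv \
                   --design run/design.tsv --annotations run/annotations.tsv --outdir run
```

which prints (seed 1):

```
feature distribution: promoter=0.129, utr3=0.016, exon=0.106, intron=0.455, intergenic=0.294
untrained_0h: 80 gain / 202 loss peaks at FDR<0.05
untrained_6h: 145 gain / 110 loss peaks at FDR<0.05
untrained_72h: 0 gain / 0 loss peaks at FDR<0.05
trained_0h: 34 gain / 283 loss peaks at FDR<0.05
trained_6h: 9 gain / 204 loss peaks at FDR<0.05
trained_72h: 5 gain / 111 loss peaks at FDR<0.05
myonuclear share of expressed genes: 40.3% (121 genes); regulated in >=1 condition: 65
6 motifs, top-200 target union: 268 genes
```

Reading this: chromatin closing dominates at 0 h and is amplified ~1.4-fold
in the trained state (283 vs 202 loss peaks); untrained changes vanish by
72 h while trained losses persist (111 peaks); the untrained gain wave peaks
at 6 h (145 peaks, a majority de novo — `run/dynamics_summary.tsv` holds the
de-novo fractions, reversal overlap and retention counts); and 121 genes
carry myonuclear chromatin evidence and stratify the bulk expression
results. `run/` also contains the z-score matrix with cluster labels, a
heatmap, per-motif activity traces and ranked target lists.

Everything is also available as a library — `simulate_dataset`,
`run_all_contrasts`, `annotate_peaks`, `build_direction_sets`,
`classify_retention`, `stratify_de`, `zscore_by_group`, `infer_activities` —
see the module docstrings.

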