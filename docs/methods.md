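# Methods

`chromdyn` analyses chromatin accessibility in skeletal-muscle myonuclei
across a 2 (training state: untrained, trained) × 3 (time post-exercise:
0 h, 6 h, 72 h) design plus a sedentary baseline, and couples those chromatin
changes to bulk gene expression and transcription-factor motif activity. The
package is exercised entirely on a synthetic-data generator that plants the
effect structure the analysis assumes, so every stage is testable without any
sequencing download. This note records the models, their assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Coordinate conventions

All genomic intervals are 0-based half-open (BED). Gene models carry a
strand-aware TSS and TES: for a plus-strand gene `tss < tes` and the body is
`[tss, tes)`; for a minus-strand gene the TSS coordinate equals the gene-body
*end* (the exclusive bound), matching the BED convention that the 5′ end of a
minus-strand feature is its `end`.

## Differential accessibility

Counts for peak *i* in sample *j* are modelled as negative binomial with mean
`mu_ij = s_j * q_g(j)` and variance `mu + alpha_i * mu^2`, where `s_j` is a
per-sample size factor, `q_g` the abundance of the sample's condition group,
and `alpha_i` the per-peak dispersion (`alpha = 0` degenerates to Poisson).

* **Size factors** are median-of-ratios: for sample *j*, the median over
  zero-free peaks of `counts[i, j]` divided by the peak's geometric mean
  across samples. Note that this normalization is defined only up to the
  geometric-mean reference: rescaling one sample's counts by *c* moves its
  factor by `c^((n-1)/n)` and every other factor by `c^(-1/n)`; all
  downstream quantities depend only on factor ratios.
* **Dispersion** is estimated per peak by pooled within-group method of
  moments, `alpha_hat = sum_g (n_g-1)(s2_g - mu_g) / sum_g (n_g-1) mu_g^2`
  on normalized counts (clipped at 0), then shrunk with weight 0.5 toward a
  mean-dispersion trend `a0 + a1/mu` fitted across all peaks. This is a
  deliberate simplification of empirical-Bayes shrinkage estimators; the
  weight is configurable.
* **The Wald test** contrasts each exercised condition against sedentary.
  Group abundances are per-group NB maximum-likelihood estimates obtained by
  a vectorized Newton iteration on the profile score
  `sum_j (y_j - s_j q) / (1 + alpha s_j q) = 0`; `log2FC = log2(q_cond /
  q_sed)`, and the standard error comes from the Fisher information of
  `log q`, `I_g = sum_j mu_j / (1 + alpha mu_j)`. A group with all-zero
  counts receives the half-count stabilizer `q = 0.5 / sum_j s_j` so fold
  changes stay finite; peaks empty in both groups are flagged and reported
  as `log2FC = 0, p = 1`. In the Poisson limit the fit coincides (to 1e-6
  and better) with a generic Poisson GLM with log link and offset.
* **FDR** is Benjamini–Hochberg, controlled within each contrast separately
  (six contrasts versus sedentary). Directions are called strictly:
  gain/loss require `fdr < 0.05` (a peak at exactly 0.05 is `none`).

**Calibration.** With three replicates per group the Wald test is mildly
anti-conservative: on a 5 000-peak null simulation the fraction of p < 0.05
is ≈ 0.05–0.065 depending on the realization, and the inflation is larger in
the deep tail that matters after BH thresholding. This is the familiar
small-sample behaviour of Wald statistics with plug-in dispersions; it is
measured by the test suite and accepted rather than patched with ad-hoc
corrections. Power on planted two-fold effects at n = 3/group exceeds 95%.

## Peak annotation

Each peak is assigned the single highest-priority feature class it overlaps:
promoter > 5′UTR > 3′UTR > exon > intron > downstream > intergenic. Overlap
means ≥ 1 bp intersection of the full peak interval. The promoter window
defaults to TSS −3000/+3000 bp (strand-aware, configurable) and the
downstream window to 3000 bp past the TES; both are free parameters because
only the priority order, not the windows, is fixed by the analysis
definition. Ties within a class are broken by the smallest absolute
midpoint-to-TSS distance, then gene id; peaks overlapping nothing become
intergenic with the nearest-TSS gene. Distances are signed, negative
upstream in transcription orientation. The implementation is checked
against an exhaustive overlap-enumeration oracle on random toy genomes and
is translation invariant.

## Temporal set algebra

Direction sets key genes by (state, time, direction); a gene enters a set
when at least one of its peaks is called in that direction, so a gene with
several peaks may legitimately sit in both the gain and the loss set of one
condition. Region-level (peak-id) sets are also available: de-novo emergence
is a region-level notion in the source analysis, while Venn overlaps,
reversal and retention are gene-level. Reported percentages are rounded to
whole percent.

* **Overlap / excess / reversal** are plain set cardinalities:
  `excess = |trained| - |untrained|`, reversal fraction
  `|gain ∩ loss| / |gain|`, reversal share `|gain ∩ loss| / |loss|`.
* **De novo** at time *t* is `|S_t \ union of earlier S| / |S_t|`, with
  earlier = {0h} for 6 h and {0h, 6h} for 72 h.
* **Retention** compares, per gene, the prefix-chain length of its
  membership pattern starting at 0 h (0h → 0h+6h → 0h+6h+72h) between the
  two states; a gene appearing only at later time points is compared by raw
  pattern cardinality. Labels: `trained_longer`, `untrained_longer`,
  `equal`, `absent` (both patterns empty). The classifier is total and is
  checked against an independent hand enumeration of all 64 pattern pairs.

## Myonuclear stratification

"Deconvolution" is list-based stratification, not statistical mixture
deconvolution: the myonuclear gene list is the union of genes with ≥ 1
differentially accessible peak in any condition, annotated with its global
accessibility association (gain, loss, or gain_and_loss when both occur
anywhere). Bulk RNA-seq differential expression (same NB machinery on gene
counts, thresholds `|log2FC| ≥ 0.585`, `FDR < 0.05`, boundary log2FC
inclusive) is restricted to that list and tallied per condition as
up/down × association. The myonuclear fraction divides by genes detected in
bulk (TPM > 0 in ≥ 1 sample by default; the detection rule is configurable).

At desk scale this recovered fraction overshoots the planted one: with six
contrasts over a few thousand peaks but only a few hundred genes, the
false-discovery allowance accumulates distinct false-positive genes into the
union list (≈ 40% recovered vs 23% planted under the defaults). At realistic
peak-to-gene ratios the relative inflation is minor. The acceptance script
reports both numbers.

## Expression summaries

z-scores standardize, per gene, the group means of `log2(TPM + 1)` across
the seven groups (sd with n−1; the pseudocount avoids log of zero, which the
plain mean-log-TPM definition would hit). Zero-variance genes become
all-zero rows and are flagged. Clustering is SciPy hierarchical clustering
on Euclidean distances with complete linkage by default (only the metric is
fixed by the analysis definition; linkage and the cut level k are free
parameters). Motif-target subsets take the union of each selected motif's
top-200 ranked target genes.

## Motif activity

This module is an explicit surrogate for external motif-activity web
services whose internals are not published: it implements the standard
linear motif-activity model. Site counts come from log2-odds PWM scanning of
both strands (N scores as background, i.e. contributes 0); per-sample
activities solve the ridge problem
`min_A ||signal[:, s] - C A||^2 + lambda ||A||^2` with `C` the peaks × motifs
site-count matrix, solved by dense Cholesky on the normal equations.
Activity rows are centered across samples (the natural gauge: only activity
*differences* are identified, and doubling `C` while halving `A` leaves the
fit unchanged — activities are always reported for the given counts).
`lambda` defaults to 1.0 on column-standardized counts; `lambda = 0` with a
rank-deficient `C` raises and advises a positive penalty. Target ranking
scores a gene by its summed site count times the motif's absolute activity
range across samples — a repository convention, since no published ranking
exists for the surrogate's reference tools.

## Synthetic-data generator

The generator is first-class, tested code. It emulates the study's
structure: 7 groups (sedentary + 2 states × 3 times), n = 3 replicates per
group, and the planted effect grammar of the `EffectSpec`:

| parameter | default | meaning |
|---|---|---|
| `frac_loss_0h_untrained` | 0.10 | fraction of peaks closing in untrained at 0 h |
| `amplification_trained` | 1.4 | trained 0 h losses = 1.4 × untrained (exact by construction) |
| `frac_gain_6h_untrained` | 0.07 | fraction of peaks opening in untrained, peaking at 6 h |
| `frac_de_novo_6h` | 0.55 | share of 6 h gains absent at 0 h |
| `reversal_frac` | 0.76 | share of untrained 0 h gains also planted as trained 0 h losses |
| `retention_profile` | untrained (0.5, 0.0); trained (0.75, 0.6) | per-state survival of losses 0h→6h and 6h→72h |
| `lfc_magnitude` | 2.0 | planted |log2FC| |
| `dispersion` | 0.05 | NB dispersion alpha |
| `n_per_group` | 3 | replicates |
| `myonuclear_frac` | 0.23 | fraction of genes designated responsive |

Reversal peaks count inside the amplified trained-loss budget so the planted
trained/untrained loss ratio equals `amplification_trained` exactly.
Untrained gains carry the 6 h → 72 h survival of the untrained retention
profile (0 by default, so they vanish at 72 h). Only the responsive gene
subset can receive planted peaks; peak placement weights responsive genes
2× so enough eligible peaks exist, which concentrates effects without
changing the gene-level responsive share. Placement draws promoter / intron
/ intergenic / exon compartments at (0.105, 0.45, 0.318, 0.127); the
realized annotated distribution lands near 12–13% promoter and ~75% distal
because intronic placements inside a neighbouring gene's promoter window
take promoter class by priority.

Counts are NB draws (`mu`, `mu + alpha mu^2`; `alpha = 0` is Poisson) around
log-normal baseline means (median ≈ 80 fragments), with per-sample library
factors drawn log-normal(0, 0.2) so size-factor estimation is non-trivial.
Expression: myonuclear genes with a planted chromatin direction in a
condition receive a ±1.2 expression log2FC whose sign agrees with the
chromatin direction with probability 0.7 — the coupling is deliberately
loose. TPM columns are normalized to 1e6. Motif structure: Poisson(0.5)
site counts, planted per-group activities (rows centered) with an
immediate-early subset (Fos, Jun, Junb_Jund, Atf3, Egr1, Egr3, Cebpb,
Nr4a2) peaking at trained 0 h and untrained 6 h, and a peaks × samples
signal equal to `counts @ activity` plus Gaussian noise (sd 0.1 by
default). Each artifact draws from its own RNG stream derived from the
master seed by a fixed offset, so adding artifacts never perturbs earlier
ones; fixed seed ⇒ bit-identical outputs.

**What the generator does not emulate:** raw reads, fragment-length
distributions, Tn5 insertion bias, mononuclear contamination, GC effects,
correlated peaks within a locus, multi-isoform TSSs, or realistic
peak/gene counts. Passing tests therefore demonstrate correctness of the
statistical machinery and the set algebra under the assumed model, not
performance on real sequencing data.

## Problem sizes

Default desk-scale sizes, chosen as the package's own working defaults:
300 genes on two ~6 Mb synthetic chromosomes, 2 000 peaks, 20 motifs for
the command-line pipeline; 5 000 peaks for null-calibration runs. All
simulations and the full test suite complete in well under a minute on one
CPU.

## Known limitations

* Wald small-sample anti-conservatism at n = 3/group (see above).
* Method-of-moments dispersion is noisier than empirical-Bayes shrinkage;
  the 0.5 trend-shrinkage weight is a blunt instrument.
* Exact per-sample normalization invariance of log2FC is unattainable for a
  count likelihood (the model sees raw counts, not normalized ones); the
  group-level Poisson-limit invariance is what holds and is what the tests
  assert.
* Gene-level direction sets inherit nearest-gene annotation mistakes;
  region-level sets avoid this and are used where the quantity is a
  region-level notion.
* The motif module is a linear surrogate; its activities are comparable
  only in arbitrary units and only within a run.
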