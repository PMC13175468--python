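# Methods

## Overview

`tcratl` implements a tissue-specific transfer-learning (TL) workflow for
sequence-to-profile models and its downstream variant- and gene-level
analyses. The workflow has five stages:

1. **Data preparation** — genomic windows are one-hot encoded and per-bp
   track coverage is cropped, clipped, scaled and averaged into 128-bp bins.
2. **Transfer learning** — a pretrained trunk (convolution stem →
   transformer blocks → pointwise convolution) has its output head replaced
   by a fresh linear + softplus layer sized to the k tissue-specific TF
   tracks, and a level-dependent subset of parameters is fine-tuned under a
   Poisson likelihood.
3. **Variant scoring** — each SNV receives a tissue-based cis-regulatory
   activity (tCRA) score: the mean over tracks of the absolute difference
   between alt- and ref-allele predictions read out at the center of the
   output window. SNVs are ranked by tCRA into nested top-N subsets.
4. **Functional enrichment** — prioritized subsets are evaluated for
   enhancer-state overlap (tissue vs unrelated cell lines), genome-wide
   significant GWAS hits (P < 5e-8), and pathogenic/germline variant
   overlap.
5. **TWAS and gene annotation** — a two-step summary-statistic TWAS
   (elastic-net expression models on cis-SNVs restricted to the prioritized
   set, then gene-level Z from GWAS summary statistics), followed by
   essentiality (CERES), druggability, and disease-listing annotation of
   significant genes.

Everything is testable at desk scale against the synthetic-data module,
which plants known ground truth at every stage.

## Preprocessing

A window of length L is one-hot encoded with column order A, C, G, T and N
as a zero row. Targets are produced in the fixed order **crop → clip →
scale → bin-average**: the coverage vector is cropped by `crop` bp at each
end, clipped at `clip_max` (32), multiplied by `scale` (2), and averaged
over consecutive `bin_size` (128 bp) windows. At full scale
(L = 196,608, crop = 40,960) this yields (196,608 − 2·40,960)/128 = 896
values per track, bounded above by clip_max·scale = 64. We treat
clip/scale/bin as the entirety of target normalization; no additional
library-size normalization is applied. Coordinates are 0-based half-open
internally; 1-based VCF/variant positions are converted at the boundary.
All windows are taken on the forward strand without reverse-complement
augmentation.

The **desk-scale geometry** used throughout the tests is L = 4,096,
crop = 512, bin = 128 → 24 bins; the full-scale geometry remains the
config default. A smaller tier (L = 2,048 → 12 bins) backs the fast unit
tests.

## Models

**Surrogate trunk.** The pluggable trunk interface expects
(L × 4) → (n_bins × C). The provided surrogate is deliberately small
(C = 64): a four-layer strided convolution stem (kernel 15 then 5/5/5,
strides 2·4·4·4 = 128, so one embedding position per 128-bp bin), two
pre-norm single-head self-attention blocks with position-wise MLPs, and a
pointwise (1×1) convolution block, followed by cropping `crop`/128 bins per
side. Attention output projections are initialized at 0.1× scale so the
residual branches start near identity; without this the content-addressable
attention path memorizes training windows before the convolution stem has
discovered motif features, and held-out performance never rises (we
observed exactly this failure mode at full init scale).

**Head.** A linear map C → k plus softplus, giving strictly positive
predictions with C·k + k parameters. `replace_head` deep-copies the trunk
and attaches a freshly initialized head.

**Fine-tuning levels.** Level 1 trains the head only; level 2 adds the
pointwise convolution; level 3 adds the last transformer block; level 4
adds the last 11 transformer blocks (all of them when fewer exist, as with
the 2-block surrogate). The optimizer is constructed over exactly the
designated parameter set, so frozen parameters are bit-identical before and
after training by construction — the tests verify this with content hashes.

**Loss and optimization.** Poisson negative log-likelihood
`mean(pred − target·log(pred))`; the log-factorial constant is omitted as
it does not depend on the prediction. The mean (not sum) over elements
makes loss magnitudes geometry-independent. Adam with learning rate 1e-4
and batch 64 are the full-scale defaults. Validation loss is evaluated
every `eval_interval` steps (default one evaluation per epoch); training
stops when the improvement is below 0.001 for five consecutive
evaluations, and the checkpoint with minimal validation loss is restored.
"Steps" in the stopping rule are validation evaluations, since validation
loss is only defined at evaluation points.

**Desk-scale training preset.** The desk preset uses lr 5e-3, batch 16 and
an evaluation every 25 steps. The rationale is Adam's step-size arithmetic:
with Adam the total parameter displacement over a training run is roughly
steps × lr, and at lr 1e-4 a freshly initialized head cannot traverse the
distance from init to the Poisson-rate scale of the synthetic targets
within a few hundred steps. The full-scale defaults are unchanged.

**Baseline CNN.** Four convolutions (kernel 15; strides 2, 4, 4, 4) over
the input symmetrically cropped to L − 2·crop bp (114,688 bp at full
scale → 896 bins), then a linear projection + softplus. Full-scale channel
widths are 128/256/512/512; the desk preset shrinks channels to
32/64/64/64 (the stride/crop geometry, which is what the tests assert, is
never changed). The CNN trains de novo through the same loop with every
parameter trainable.

**Pretraining.** The surrogate trunk stands in for a large pretrained
model: it is trained once, end to end, on a six-track pretraining task
whose motif set is a superset of the fine-tuning tracks' motifs — the
analogue of a foundation model having seen related TF families. 3,000
steps at lr 5e-3 suffice for the trunk to discover all six motifs
(held-out r ≈ 0.9–0.98 per track).

## Synthetic data

The generator defines the study conditions; its defaults are fixed.

**Genome.** Uniform-random A/C/G/T sequence, one 3-Mb chromosome by
default (733 non-overlapping 4,096-bp windows; 70/15/15 train/valid/test).
N bases are never generated by default; `inject_n_runs` adds them for
encoder tests.

**Tracks.** Per-track consensus motifs of length 4. Real TF motifs are
longer but degenerate; a 4-mer's ~8 bits of information content is in the
range of effective PWM information, and — decisive at desk scale — it
occurs ~16 times per window, giving the surrogate enough examples to learn
from within the step budget. Occupancy is PWM-like and graded: a full
consensus match contributes credit 1, a one-mismatch site contributes 0.25
(weak-affinity binding). Credits at motif centers are spread by an
unnormalized 50-bp boxcar, so peaks rise peak_rate = 8 counts above a
background of 0.5 — the 10–30× fold enrichment typical of ChIP-seq — and
span a sizeable fraction of a 128-bp bin. The graded component matters for
learnability: with exact-match-only signal, gradient descent has no path
from random convolution filters to a sharp 4-mer detector, and we observed
motif-dependent discovery failures; partial credit restores a smooth path
(composition → partial site → full site). Signal is Poisson-sampled from
the resulting rate.

**Variants.** Regulatory variants are placed inside existing motif
occurrences with an alt allele that destroys the exact match; neutral
variants are rejection-sampled so that neither allele changes any exact
occurrence count. Flags are verified by re-scanning both alleles, and an
independent brute-force re-scan backs the tests. Neutral variants can still
touch one-mismatch sites (changing the graded signal slightly) — a
realistic source of low-grade background effect.

**Cohort.** Dosages are Binomial(2, maf) with maf ~ U(0.1, 0.5), i.e. no
linkage disequilibrium (a stated non-goal). Expression = Σ effect·dosage +
covariate effects + Gaussian noise, with the noise scaled so the genetic
fraction of the **non-covariate** variance equals h² (default 0.5, at the
upper end of strong cis-heritability); the cis-R² ground-truth test
residualizes covariates first, mirroring how the TWAS step consumes
expression.

**GWAS summary statistics.** Analytic by default: se from allele frequency
and effective sample size (n_eff = n_cases·n_controls/n), beta ~
Normal(true effect, se), two-sided normal P. Default 50,000 cases and
50,000 controls with per-variant log-odds effects of ±0.15 at causal-gene
variants — large effects by design so end-to-end recovery measures the
pipeline, not GWAS power. A slow individual-level logistic mode
(`method="individual"`) is retained and validated on a small case.

**Annotation fixtures.** Tissue cell lines cover regulatory variants with
enhancer-state intervals at probability enrichment × p_base (default 3 ×
0.15) and neutral variants at p_base; unrelated cell lines cover everything
at p_base. Essential genes' CERES scores are drawn from N(−1, 0.2) clipped
to ≤ −0.55, so the median is below −0.5 by construction. Drug-target rows
use the fixed vocabulary {approved, phase II, phase III, other}.

**What the generator does not emulate:** linkage disequilibrium and
recombination maps, population structure, indels, strand asymmetry,
degenerate PWMs beyond one mismatch, mappability artifacts, batch effects
across tracks. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery at desk scale, not performance on
real genomes.

## tCRA scoring

The SNV is placed one base to the right of the window midpoint — 0-based
offset L/2 (98,304 at full scale) — and the effect is read from the mean of
the two central output bins (1-based n/2 and n/2 + 1; bins 448 and 449 at
full scale). The score is the **mean of absolute per-track differences**
between alt and ref central values; the alternative reading (absolute value
of the mean difference) is available as `mode="abs_mean"` for sensitivity
checks but is not the default, because signed effects across tracks would
cancel. Ranking is by descending tCRA with (chrom, pos) tie-breaks, making
prioritization deterministic; subsets are nested by construction.

## TWAS

QC excludes variants with MAF < 0.01, missingness > 10%, or HWE P < 1e-6
(1-df chi-square without continuity correction; monomorphic sites pass).
Cis predictors are variants within ±1 Mb of the TSS (closed bounds, same
chromosome) intersected with the prioritized SNV set (or unrestricted in
baseline mode). Expression is residualized on known covariates by least
squares — a generic stand-in for factor-based normalization. The per-gene
elastic net uses mixing parameter 0.5 (the standard TWAS convention) with
the penalty strength chosen by seeded 5-fold cross-validation; CV R² is the
squared out-of-fold correlation at the selected penalty, and models are
retained only when CV R² > 0.01 (strict).

The gene-level statistic is

    Z_g = Σ_i w_ig · (σ_i / σ_g) · β_i / se(β_i)

with σ_i the training-panel genotype SD and σ_g = √(wᵀ Σ̂ w) the SD of
predicted expression under the reference-panel LD matrix Σ̂. The training
genotypes serve as the reference panel (an in-sample-prediction-SD mode
exists behind a flag). For a single predictor the formula collapses to
Z = sign(w)·β/se exactly; this identity is fuzz-tested. P = 2·Φ(−|Z|), and
genes with P < 0.05/m over the m retained models are reported significant.

## Gene annotation

Essential: median CERES across cell lines strictly below −0.5. Druggable: at
least one approved / phase II / phase III drug row; rate = count/|genes|·100.
Disease-listed: at least one disease-table row (denominator: all significant
genes, not only annotatable ones). Gene identifiers are case- and
whitespace-normalized before joining.

## Pipeline

`run_pipeline` executes simulate → pretrain → fine-tune → (optional CNN) →
evaluate → score → prioritize → enrich → TWAS → annotate into a run
directory, recording a manifest with the config hash, per-file SHA-256
checksums, and per-stage wall times. A rerun with an identical config whose
outputs are intact is served from the manifest; `--force` recomputes.
Caching is at whole-run granularity (config hash + output existence), not a
content-addressed per-stage DAG. A stage failure names the failing stage
and keeps partial outputs. Configuration is YAML over layered defaults
(defaults ← preset ← file ← CLI flags), with cross-stanza geometry checked
before any compute.

## Problem sizes and numerical choices

The default demo ("small" preset) uses a 3-Mb genome, 6 pretraining and 4
fine-tuning tracks, 120 panel SNVs (30% regulatory), a 300-sample cohort
with 12 genes, and 3,000/300 pretrain/fine-tune steps — chosen so the full
demo completes in a few minutes on one CPU while leaving clear headroom
between the planted signal and its recovery thresholds. Network compute is
float32; statistics (Pearson, KS, chi-square, Z) are float64. Ties in
prioritization break by genome position; zero-variance tracks yield
undefined r, are flagged, and are excluded from means; an all-zero
elastic-net solution is retained with CV R² = 0; σ_g = 0 marks a gene
untestable rather than raising.

## Known limitations

- The surrogate trunk is a stand-in: absolute performance numbers at desk
  scale say nothing about full-scale models on real data.
- No LD in the cohort simulator means TWAS operates in a friendlier regime
  than real reference panels; the recovery property measures plumbing
  correctness, not statistical power under confounding.
- Single-head attention without positional encodings limits the trunk to
  content-based long-range interactions; sufficient here, not generally.
- KS P values use the asymptotic two-sided distribution (exact mode
  available); group sizes below ~50 should prefer the exact mode.
- The manifest cache does not detect manual edits to intermediate files
  beyond their presence.
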