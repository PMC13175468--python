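# tcratl

Tissue-specific transfer learning for sequence-to-profile models, variant
effect scoring, and summary-statistic TWAS — with a synthetic-data module
that makes the whole workflow testable on a laptop.

## The problem

General-purpose sequence-to-profile models predict thousands of epigenomic
tracks from DNA sequence, but a model trained on heterogeneous tissues is
not optimal for any one of them. `tcratl` implements the transfer-learning
recipe for adapting such a model to a set of tissue-specific transcription
factor (TF) ChIP-seq tracks, and carries the adapted model through to the
analyses a cancer-genetics group would run with it:

1. **Head replacement + partial fine-tuning.** A pretrained trunk
   (convolution stem → transformer blocks → pointwise convolution) keeps its
   weights; the output head is replaced by a fresh linear + softplus layer
   with k outputs (one per tissue track). Four fine-tuning levels control
   how much of the trunk re-trains: (1) head only, (2) + pointwise
   convolution, (3) + last transformer block, (4) + last 11 transformer
   blocks. Training minimizes the Poisson negative log-likelihood

       L(pred, y) = mean( pred − y · log pred )

   with Adam (lr 1e-4, batch 64 at full scale) and early stopping when the
   validation improvement stays below 0.001 for five consecutive
   evaluations.

2. **tCRA variant scores.** For SNV i, with the variant placed one base
   right of the input-window midpoint and predictions read from the two
   central 128-bp output bins (bins 448/449 at full scale),

       tCRA_i = (1/k) Σ_j | Pred_alt(i,j) − Pred_ref(i,j) |

   SNVs ranked by tCRA form nested top-N subsets for downstream analysis.

3. **Functional enrichment.** Subset overlap with enhancer chromatin states
   (15-state segmentation; tissue vs unrelated cell lines), genome-wide
   significant GWAS variants (P < 5×10⁻⁸), and pathogenic/germline
   variants.

4. **Two-step TWAS.** Per gene g, an elastic net over cis-SNV dosages
   (±1 Mb of the TSS, restricted to the prioritized subset, after
   MAF/missingness/HWE QC) predicts residualized expression,
   E_g ~ Σ_i w_ig X_i + ε; models with cross-validated R² > 0.01 are
   combined with GWAS summary statistics into

       Z_g = Σ_i ŵ_ig (σ̂_i / σ̂_g) β̂_i / se(β̂_i),   σ̂_g = √(ŵᵀ Σ̂ ŵ)

   and genes with Bonferroni-corrected P < 0.05 are reported.

5. **Gene annotation.** Significant genes are joined to CRISPR-dependency
   scores (essential: median CERES < −0.5), drug-target tables (druggable:
   ≥1 approved/phase II/phase III drug), and disease-gene tables.

Because the full-scale inputs (pretrained foundation-model weights, ChIP-seq
compendia, biobank GWAS) are far beyond a desk machine, the package ships a
first-class **synthetic-data module**: a random genome with motif-driven
Poisson track signal, SNV panels whose regulatory status is known by
construction, an eQTL-structured expression cohort, analytic case-control
summary statistics, and annotation tables with planted enrichment. A small
surrogate trunk (C = 64, two attention blocks) is pretrained on a superset
of motifs and stands in for the foundation model. See `docs/methods.md`.

## Worked example

```python
import numpy as np
from tcratl.pipeline import DEFAULT_CONFIG, simulate_study
from tcratl.model import (pretrain_surrogate_trunk, replace_head, fine_tune,
                          FineTuneConfig, build_baseline_cnn)
from tcratl.evaluation import per_track_pearson, rank_auc
from tcratl.tcra import tcra_score_batch

study = simulate_study(dict(DEFAULT_CONFIG), seed=1)

# pretrained surrogate (stands in for the foundation model)
trunk, _ = pretrain_surrogate_trunk(study.pretrain_splits["train"],
                                    study.pretrain_splits["valid"],
                                    study.prep, steps=3000, seed=11)

# transfer learning: replace the head, fine-tune level 1 (head only)
tl = replace_head(trunk, study.finetune_truth.k, seed=21)
tl, hist = fine_tune(tl, study.finetune_splits["train"],
                     study.finetune_splits["valid"],
                     FineTuneConfig.desk(level=1), seed=22)

test = study.finetune_splits["test"]
r_tl = per_track_pearson(tl.predict_batch(test.inputs()), test.targets())
print("TL   held-out r per track:", np.round(r_tl, 2), "mean", round(r_tl.mean(), 3))

# from-scratch CNN under the identical step budget
cnn = build_baseline_cnn(study.finetune_truth.k, study.prep,
                         channels=(32, 64, 64, 64), seed=21)
cnn, _ = fine_tune(cnn, study.finetune_splits["train"],
                   study.finetune_splits["valid"],
                   FineTuneConfig.desk(level=1), seed=23)
r_cnn = per_track_pearson(cnn.predict_batch(test.inputs()), test.targets())
print("CNN  held-out r per track:", np.round(r_cnn, 2), "mean", round(r_cnn.mean(), 3))

# tCRA scores separate planted regulatory variants from neutral ones
records = tcra_score_batch(tl, study.genome, study.panel.variants, study.prep)
scores = np.array([rec.tcra for rec in records])
print("tCRA rank AUC (regulatory vs neutral):",
      round(rank_auc(scores, study.panel.is_regulatory), 3))
```

Output (about seven minutes on one CPU, dominated by pretraining):

```
TL   held-out r per track: [0.75 0.68 0.96 0.66] mean 0.765
CNN  held-out r per track: [0.09 0.23 0.13 0.26] mean 0.181
tCRA rank AUC (regulatory vs neutral): 0.944
```

The transfer-learned model reads out the trunk's motif features with a
freshly trained head and reaches r ≈ 0.77 on held-out windows, while the
same architecture family trained from scratch under the identical step
budget stays near r ≈ 0.18 — the core transfer-learning effect. The rank
AUC shows that SNVs destroying a motif occurrence receive systematically
higher tCRA scores than neutral SNVs.

The same workflow runs end to end from the shell:

```bash
tcra-tl run --preset small --seed 1 --outdir runs/demo
tcra-tl evaluate --outdir runs/demo
```

which writes every stage output (FASTA, bedGraph, TSV tables, training log,
tCRA ranking, enrichment report, TWAS results, gene report) plus a manifest
with config hash and checksums into `runs/demo/`.

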