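"""End-to-end orchestration of the demo study on synthetic data.

``simulate_study`` materializes every input the stages need (genome, track
signal, pretraining and fine-tuning datasets, variant panel, cohort,
GWAS summary statistics, annotation fixtures) from one config + seed;
``run_pipeline`` then trains the transfer-learning model, scores and
prioritizes variants, runs the enrichment and TWAS stages, annotates the
resulting genes, and writes every stage output plus a manifest (config hash,
file checksums, stage wall times) into a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import gene_annotation as ganno
from . import synthetic_data as syn
from . import twas as twas_mod
from .data_prep import PrepConfig, build_dataset, tiling_regions
from .evaluation import evaluation_table, per_track_pearson
from .io import write_bed, write_bedgraph, write_fasta, write_tsv
from .model import (
    FineTuneConfig,
    build_baseline_cnn,
    fine_tune,
    pretrain_surrogate_trunk,
    replace_head,
    save_checkpoint,
)
from .tcra import prioritize, records_to_frame, tcra_score_batch

#: desk-scale demo conditions (the "small" preset)
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "prep": {"L": 4096, "crop": 512, "bin_size": 128, "clip_max": 32.0, "scale": 2.0},
    "genome": {"n_chrom": 1, "length_per_chrom": 3_000_000},
    "tracks": {
        "background_rate": 0.5,
        "peak_rate": 8.0,
        "smooth_width": 50,
        "finetune_motifs": ["TGAC", "GGAT", "CACG", "TTGC"],
        "pretrain_motifs": ["TGAC", "GGAT", "CACG", "TTGC", "GATA", "CCAA"],
    },
    "split_fractions": [0.7, 0.15, 0.15],
    "pretrain": {"steps": 3000, "learning_rate": 5e-3, "batch_size": 16, "C": 64, "n_blocks": 2},
    "finetune": {
        "level": 1,
        "learning_rate": 5e-3,
        "batch_size": 16,
        "max_steps": 300,
        "early_stop_delta": 1e-3,
        "early_stop_patience": 5,
        "eval_interval": 25,
    },
    "baseline_cnn": {"enabled": False, "channels": [32, 64, 64, 64], "steps": 300},
    "variants": {"n": 120, "frac_regulatory": 0.3},
    "subset_sizes": [20, 40, 60],
    "cohort": {
        "n_samples": 300,
        "maf_range": [0.1, 0.5],
        "n_genes": 12,
        "n_causal": 2,
        "causal_genes": 3,
        "effect_size": 1.0,
        "h2": 0.5,
    },
    "gwas": {"n_cases": 50_000, "n_controls": 50_000, "effect": 0.15},
    "enrichment": {"enhancer_enrichment": 3.0, "p_base": 0.15, "gwas_threshold": 5e-8},
    "twas": {"window": 1e6, "r2_min": 0.01, "maf_min": 0.01, "missing_max": 0.10,
             "hwe_p_min": 1e-6},
}

PRESETS = {
    "small": {},
    "medium": {
        "genome": {"n_chrom": 1, "length_per_chrom": 6_000_000},
        "variants": {"n": 240, "frac_regulatory": 0.3},
        "pretrain": {"steps": 3000, "learning_rate": 5e-3, "batch_size": 16, "C": 64, "n_blocks": 2},
        "finetune": {"level": 2, "learning_rate": 5e-3, "batch_size": 16, "max_steps": 500,
                     "early_stop_delta": 1e-3, "early_stop_patience": 5, "eval_interval": 25},
        "cohort": {"n_samples": 500, "maf_range": [0.1, 0.5], "n_genes": 20, "n_causal": 2,
                   "causal_genes": 3, "effect_size": 1.0, "h2": 0.5},
        "subset_sizes": [40, 80, 120],
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | None = None, preset: str = "small",
                overrides: dict | None = None) -> dict:
    """Merge defaults <- preset <- YAML file <- explicit overrides, validate."""
    cfg = _deep_update(DEFAULT_CONFIG, PRESETS[preset])
    if path is not None:
        with open(path) as fh:
            cfg = _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _deep_update(cfg, overrides)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> PrepConfig:
    """Cross-stanza consistency checks, before any compute."""
    prep = PrepConfig(**cfg["prep"])  # raises on bad geometry
    if cfg["genome"]["length_per_chrom"] < prep.L:
        raise ValueError("chromosomes shorter than one input window")
    FineTuneConfig(**cfg["finetune"])  # raises on bad level
    fracs = cfg["split_fractions"]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    sizes = cfg["subset_sizes"]
    if sizes != sorted(sizes):
        raise ValueError("subset sizes must be ascending")
    if any(s > cfg["variants"]["n"] for s in sizes):
        raise ValueError("subset size exceeds the variant panel")
    motifs = cfg["tracks"]["finetune_motifs"]
    if not set(motifs) <= set(cfg["tracks"]["pretrain_motifs"]):
        raise ValueError("fine-tune motifs must be drawn from the pretraining set")
    return prep


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclasses.dataclass
class StudyData:
    """Everything the pipeline stages consume, generated from one seed."""

    prep: PrepConfig
    genome: syn.SyntheticGenome
    pretrain_truth: syn.TrackTruthModel
    finetune_truth: syn.TrackTruthModel
    pretrain_splits: dict
    finetune_splits: dict
    finetune_tracks: dict[str, np.ndarray]
    panel: syn.PlantedVariantPanel
    gene_defs: list[syn.GeneDef]
    cohort: syn.CohortTruth
    genotypes: pd.DataFrame
    expression: pd.DataFrame
    summary_stats: pd.DataFrame
    fixtures: syn.AnnotationFixtures
    gwas_causal_effects: dict[str, float]


def simulate_study(cfg: dict, seed: int | None = None) -> StudyData:
    """Generate the full synthetic study from the config (and optional seed
    override). Deterministic: same config + seed => identical data."""
    prep = validate_config(cfg)
    seed = cfg["seed"] if seed is None else seed
    tr = cfg["tracks"]
    genome = syn.make_genome(cfg["genome"]["n_chrom"], cfg["genome"]["length_per_chrom"],
                             seed=seed)
    pre_truth = syn.TrackTruthModel(
        k=len(tr["pretrain_motifs"]), motifs=list(tr["pretrain_motifs"]),
        background_rate=tr["background_rate"], peak_rate=tr["peak_rate"],
        smooth_width=tr["smooth_width"], seed=seed + 1,
    )
    fin_truth = syn.TrackTruthModel(
        k=len(tr["finetune_motifs"]), motifs=list(tr["finetune_motifs"]),
        background_rate=tr["background_rate"], peak_rate=tr["peak_rate"],
        smooth_width=tr["smooth_width"], seed=seed + 2,
    )
    pre_tracks = syn.simulate_tracks(genome, pre_truth)
    fin_tracks = syn.simulate_tracks(genome, fin_truth)
    regions = tiling_regions(genome, prep)
    fracs = tuple(cfg["split_fractions"])
    pre_splits = build_dataset(genome, pre_tracks, regions, prep, fracs, seed=seed + 3)
    fin_splits = build_dataset(genome, fin_tracks, regions, prep, fracs, seed=seed + 3)

    panel = syn.plant_variants(
        genome, fin_truth, cfg["variants"]["n"], cfg["variants"]["frac_regulatory"],
        seed=seed + 4, edge_margin=prep.L // 2 + 1,
    )
    co = cfg["cohort"]
    gene_defs = syn.define_genes(
        panel, co["n_genes"], co["n_causal"], co["effect_size"], seed=seed + 5,
        causal_genes=co["causal_genes"],
    )
    cohort, geno_df, expr_df = syn.simulate_cohort(
        panel, co["n_samples"], tuple(co["maf_range"]), gene_defs, co["h2"], seed=seed + 6,
    )
    # GWAS effects: causal-gene variants carry signal whose sign follows the
    # expression effect, so gene-level Z scores accumulate coherently
    gw = cfg["gwas"]
    causal_effects: dict[str, float] = {}
    for gd in gene_defs:
        for vid, eff in gd.causal:
            causal_effects[vid] = float(np.sign(eff) * gw["effect"])
    freqs = dict(zip(cohort.variant_ids, cohort.mafs))
    sumstats = syn.simulate_gwas_summary(
        panel, causal_effects, gw["n_cases"], gw["n_controls"], seed=seed + 7, freqs=freqs,
    )
    en = cfg["enrichment"]
    fixtures = syn.make_annotation_fixtures(
        panel, [gd.gene for gd in gene_defs], seed=seed + 8,
        enhancer_enrichment=en["enhancer_enrichment"], p_base=en["p_base"],
    )
    return StudyData(
        prep=prep, genome=genome, pretrain_truth=pre_truth, finetune_truth=fin_truth,
        pretrain_splits=pre_splits, finetune_splits=fin_splits, finetune_tracks=fin_tracks,
        panel=panel, gene_defs=gene_defs, cohort=cohort, genotypes=geno_df,
        expression=expr_df, summary_stats=sumstats, fixtures=fixtures,
        gwas_causal_effects=causal_effects,
    )


def write_study_inputs(study: StudyData, outdir: Path) -> None:
    """Write every simulated input class as plain-text files."""
    write_fasta(study.genome.as_dict(), outdir / "genome.fa")
    write_bedgraph(study.finetune_tracks, outdir / "track0.bedgraph", track_index=0)
    write_tsv(study.panel.frame(), outdir / "variants.tsv")
    write_tsv(study.summary_stats, outdir / "summary_stats.tsv")
    write_tsv(study.genotypes.reset_index(names="sample"), outdir / "genotypes.tsv")
    write_tsv(study.expression.reset_index(names="sample"), outdir / "expression.tsv")
    for cl, df in study.fixtures.states.items():
        write_bed(df, outdir / f"states_{cl}.bed")
    write_tsv(study.fixtures.pathogenic, outdir / "pathogenic.tsv")
    write_tsv(study.fixtures.ceres, outdir / "ceres.tsv")
    write_tsv(study.fixtures.drug_targets, outdir / "drug_targets.tsv")
    write_tsv(study.fixtures.disease_genes, outdir / "disease_genes.tsv")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: dict, outdir: str | Path, force: bool = False) -> dict:
    """Execute simulate -> prep -> train -> evaluate -> score -> prioritize ->
    enrich -> twas -> annotate, writing stage outputs and a manifest.

    Rerunning with an identical config reuses the completed run (the manifest
    stores the config hash); ``force=True`` recomputes. Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash and all(
            (outdir / f).exists() for f in old.get("files", {})
        ):
            return old

    manifest: dict[str, Any] = {"config_hash": chash, "config": cfg, "stages": {}, "files": {}}
    stage_t0 = time.time()

    def finish_stage(name: str) -> None:
        nonlocal stage_t0
        manifest["stages"][name] = round(time.time() - stage_t0, 3)
        stage_t0 = time.time()

    try:
        study = simulate_study(cfg)
        write_study_inputs(study, outdir)
        finish_stage("simulate")

        seed = cfg["seed"]
        pt = cfg["pretrain"]
        trunk, _ = pretrain_surrogate_trunk(
            study.pretrain_splits["train"], study.pretrain_splits["valid"], study.prep,
            C=pt["C"], n_blocks=pt["n_blocks"], steps=pt["steps"],
            learning_rate=pt["learning_rate"], batch_size=pt["batch_size"], seed=seed + 10,
        )
        finish_stage("pretrain")

        k = study.finetune_truth.k
        tl = replace_head(trunk, k, seed=seed + 11)
        ft_cfg = FineTuneConfig(**cfg["finetune"])
        tl, history = fine_tune(
            tl, study.finetune_splits["train"], study.finetune_splits["valid"], ft_cfg,
            seed=seed + 12,
        )
        save_checkpoint(tl, outdir / "tl_model.npz", {"config_hash": chash})
        pd.DataFrame(
            {"step": history.steps, "train_loss": history.train_losses,
             "valid_loss": history.valid_losses}
        ).to_csv(outdir / "training_log.tsv", sep="\t", index=False)
        finish_stage("train_tl")

        models = {"tl": tl}
        if cfg["baseline_cnn"]["enabled"]:
            cnn = build_baseline_cnn(k, study.prep,
                                     channels=tuple(cfg["baseline_cnn"]["channels"]),
                                     seed=seed + 13)
            cnn_cfg = dataclasses.replace(ft_cfg, max_steps=cfg["baseline_cnn"]["steps"])
            cnn, _ = fine_tune(cnn, study.finetune_splits["train"],
                               study.finetune_splits["valid"], cnn_cfg, seed=seed + 14)
            models["cnn"] = cnn
        finish_stage("train_cnn")

        test = study.finetune_splits["test"]
        targets = test.targets()
        eval_rows = []
        for name, m in models.items():
            preds = m.predict_batch(test.inputs())
            r = per_track_pearson(preds, targets)
            tf_names = [f"TF{j}" for j in range(k)]
            tbl = evaluation_table(r, tf_names, [f"{name}_track{j}" for j in range(k)])
            tbl.insert(0, "model", name)
            eval_rows.append(tbl)
        eval_table = pd.concat(eval_rows, ignore_index=True)
        write_tsv(eval_table, outdir / "evaluation.tsv")
        finish_stage("evaluate")

        records = tcra_score_batch(tl, study.genome, study.panel.variants, study.prep)
        write_tsv(records_to_frame(records, per_track=True), outdir / "tcra.tsv")
        subsets = prioritize(records, cfg["subset_sizes"])
        write_tsv(
            pd.DataFrame({"rank": range(1, len(subsets.ranked_ids) + 1),
                          "id": subsets.ranked_ids}),
            outdir / "prioritized.tsv",
        )
        finish_stage("score")

        top_ids = set(subsets.subset(cfg["subset_sizes"][0]))
        vmap = {v.id: v for v in study.panel.variants}
        top_variants = [vmap[i] for i in subsets.subset(cfg["subset_sizes"][0])]
        tissue_ann = [enr.StateAnnotation(cl, study.fixtures.states[cl])
                      for cl in study.fixtures.tissue_cell_lines]
        other_ann = [enr.StateAnnotation(cl, study.fixtures.states[cl])
                     for cl in study.fixtures.other_cell_lines]
        report = enr.evaluate_subset(
            top_variants, tissue_ann, other_ann, study.summary_stats,
            study.fixtures.pathogenic, cfg["enrichment"]["gwas_threshold"],
        )
        write_tsv(report.frame(), outdir / "enrichment.tsv")
        finish_stage("enrich")

        tw = cfg["twas"]
        qc = twas_mod.QcConfig(maf_min=tw["maf_min"], missing_max=tw["missing_max"],
                               hwe_p_min=tw["hwe_p_min"])
        prioritized = set(subsets.subset(cfg["subset_sizes"][-1]))
        results, kept_models, qc_log = twas_mod.run_twas(
            study.genotypes, study.expression, study.cohort.covariates,
            study.panel.frame(), study.gene_defs, study.summary_stats,
            prioritized_set=prioritized, qc=qc, window=tw["window"],
            r2_min=tw["r2_min"], seed=seed + 15,
        )
        write_tsv(results, outdir / "twas_results.tsv")
        write_tsv(qc_log, outdir / "twas_qc_log.tsv")
        write_tsv(
            pd.DataFrame({"gene": [m.gene for m in kept_models],
                          "n_predictors": [len(m.weights) for m in kept_models],
                          "cv_r2": [m.cv_r2 for m in kept_models]}),
            outdir / "twas_models.tsv",
        )
        finish_stage("twas")

        sig_genes = list(results.loc[results["significant"], "gene"]) or list(results["gene"])
        if sig_genes:
            gene_report = ganno.annotate_genes(
                sig_genes, study.fixtures.ceres, study.fixtures.drug_targets,
                study.fixtures.disease_genes,
            )
            write_tsv(gene_report, outdir / "gene_report.tsv")
        finish_stage("annotate")
    except Exception as exc:  # name the failing stage; keep partial outputs
        done = ", ".join(manifest["stages"]) or "none"
        raise RuntimeError(
            f"pipeline failed after stage(s) [{done}]: {type(exc).__name__}: {exc}"
        ) from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
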