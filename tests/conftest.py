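"""Shared fixtures.

Two tiers: ``mini_*`` fixtures are small fast inputs for unit tests, and the
session-scoped ``study`` / ``pretrained_trunk`` / ``finetuned_models``
fixtures carry the one expensive surrogate pretraining run that the
integration tests share.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcratl import synthetic_data as syn
from tcratl.data_prep import PrepConfig, build_dataset, tiling_regions
from tcratl.evaluation import per_track_pearson
from tcratl.model import (
    FineTuneConfig,
    build_baseline_cnn,
    fine_tune,
    pretrain_surrogate_trunk,
    replace_head,
)
from tcratl.pipeline import DEFAULT_CONFIG, simulate_study


@pytest.fixture(scope="session")
def study():
    """The default desk-scale synthetic study (3 Mb genome, 4+2 motif tracks)."""
    return simulate_study(dict(DEFAULT_CONFIG), seed=1)


@pytest.fixture(scope="session")
def pretrained_trunk(study):
    """Surrogate base model trained once on the 6-track pretraining task."""
    trunk, _ = pretrain_surrogate_trunk(
        study.pretrain_splits["train"], study.pretrain_splits["valid"], study.prep,
        steps=DEFAULT_CONFIG["pretrain"]["steps"], seed=11,
    )
    return trunk


@pytest.fixture(scope="session")
def finetuned_models(study, pretrained_trunk):
    """Per seed: head-replaced TL model and from-scratch CNN, both trained
    under the identical 300-step budget, with held-out per-track r."""
    ftr, fva, fte = (study.finetune_splits[s] for s in ("train", "valid", "test"))
    Xte, Yte = fte.inputs(), fte.targets()
    out = {}
    k = study.finetune_truth.k
    for seed in (1, 2, 3):
        tl = replace_head(pretrained_trunk, k, seed=100 + seed)
        tl, _ = fine_tune(tl, ftr, fva, FineTuneConfig.desk(level=1), seed=200 + seed)
        r_tl = per_track_pearson(tl.predict_batch(Xte), Yte)
        cnn = build_baseline_cnn(k, study.prep, channels=(32, 64, 64, 64), seed=100 + seed)
        cnn, _ = fine_tune(cnn, ftr, fva, FineTuneConfig.desk(level=1), seed=300 + seed)
        r_cnn = per_track_pearson(cnn.predict_batch(Xte), Yte)
        out[seed] = {"tl": tl, "cnn": cnn, "r_tl": r_tl, "r_cnn": r_cnn}
    return out


@pytest.fixture(scope="session")
def tl_model(finetuned_models):
    return finetuned_models[1]["tl"]


# ----------------------------------------------------------------- mini tier


@pytest.fixture(scope="session")
def mini_prep():
    """Tiny geometry: 2,048 bp, 256 bp crop, 128 bp bins -> 12 bins."""
    return PrepConfig(L=2048, crop=256, bin_size=128)


@pytest.fixture(scope="session")
def mini_genome():
    return syn.make_genome(1, 120_000, seed=5)


@pytest.fixture(scope="session")
def mini_truth():
    return syn.TrackTruthModel(k=2, motifs=["TGAC", "GGAT"], seed=6)


@pytest.fixture(scope="session")
def mini_splits(mini_genome, mini_truth, mini_prep):
    tracks = syn.simulate_tracks(mini_genome, mini_truth)
    regions = tiling_regions(mini_genome, mini_prep)
    return build_dataset(mini_genome, tracks, regions, mini_prep, (0.7, 0.15, 0.15), seed=7)


@pytest.fixture(scope="session")
def mini_panel(mini_genome, mini_truth, mini_prep):
    return syn.plant_variants(mini_genome, mini_truth, 40, 0.5, seed=8,
                              edge_margin=mini_prep.L // 2 + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
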