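"""Generator correctness: determinism, planted ground truth, and the
agreement of planted flags with independent brute-force re-scans."""

import numpy as np
import pandas as pd
import pytest

from tcratl import synthetic_data as syn


def brute_occurrence_count(seq: str, motifs) -> int:
    """Independent oracle: total exact-match occurrence count."""
    total = 0
    for motif in motifs:
        total += sum(1 for i in range(len(seq) - len(motif) + 1)
                     if seq[i : i + len(motif)] == motif)
    return total


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        a = syn.make_genome(1, 100, seed=7)
        b = syn.make_genome(1, 100, seed=7)
        assert a.sequences == b.sequences
        assert syn.make_genome(1, 100, seed=8).sequences != a.sequences

    def test_shapes(self):
        g = syn.make_genome(2, 4096, seed=1)
        assert g.chrom_names == ["chr1", "chr2"]
        assert all(len(s) == 4096 for s in g.sequences)

    def test_base_composition_uniform(self):
        g = syn.make_genome(1, 10**6, seed=3)
        seq = g.sequences[0]
        for base in "ACGT":
            # 0.25 +/- 0.01 is ~23 binomial standard errors at n = 1e6
            assert 0.24 <= seq.count(base) / len(seq) <= 0.26

    @pytest.mark.parametrize("args", [(0, 10), (1, 0)])
    def test_nonpositive_sizes_rejected(self, args):
        with pytest.raises(ValueError):
            syn.make_genome(*args, seed=0)


class TestSimulateTracks:
    def test_zero_peak_rate_gives_background_mean(self):
        g = syn.make_genome(1, 200_000, seed=1)
        truth = syn.TrackTruthModel(k=1, motifs=["TGAC"], background_rate=0.7,
                                    peak_rate=0.0, seed=2)
        sig = syn.simulate_tracks(g, truth)["chr1"]
        se = np.sqrt(0.7 / sig.size)
        assert abs(sig.mean() - 0.7) < 3 * se

    def test_no_background_no_motif_is_all_zero(self):
        g = syn.SyntheticGenome(["chr1"], ["A" * 5000], seed=0)
        truth = syn.TrackTruthModel(k=1, motifs=["TGAC"], background_rate=0.0,
                                    peak_rate=5.0, seed=3)
        assert (syn.simulate_tracks(g, truth)["chr1"] == 0).all()

    def test_planted_motif_raises_local_rate(self):
        base = "A" * 2000
        seq = base[:1000] + "TGAC" + base[1004:]
        g = syn.SyntheticGenome(["chr1"], [seq], seed=0)
        truth = syn.TrackTruthModel(k=1, motifs=["TGAC"], background_rate=0.1,
                                    peak_rate=5.0, seed=4)
        lam = syn.track_rates(g, truth)["chr1"][:, 0]
        # independent recomputation of the occurrence position
        occ = [i for i in range(len(seq) - 3) if seq[i : i + 4] == "TGAC"]
        assert occ == [1000]
        assert lam[995:1010].mean() > lam[100:500].mean()

    def test_deterministic(self):
        g = syn.make_genome(1, 50_000, seed=1)
        truth = syn.TrackTruthModel(k=2, motifs=["TGAC", "GGAT"], seed=9)
        a = syn.simulate_tracks(g, truth)["chr1"]
        b = syn.simulate_tracks(g, truth)["chr1"]
        np.testing.assert_array_equal(a, b)


class TestPlantVariants:
    def test_frac_zero_all_nonregulatory(self, mini_genome, mini_truth):
        panel = syn.plant_variants(mini_genome, mini_truth, 30, 0.0, seed=1)
        assert not panel.is_regulatory.any()

    def test_flags_match_brute_force_rescan(self, mini_genome, mini_truth):
        panel = syn.plant_variants(mini_genome, mini_truth, 30, 0.5, seed=2)
        seq = mini_genome.sequences[0]
        for v, flag in zip(panel.variants, panel.is_regulatory):
            p0 = v.pos - 1
            assert seq[p0] == v.ref
            alt_seq = seq[:p0] + v.alt + seq[p0 + 1 :]
            changed = brute_occurrence_count(seq, mini_truth.motifs) != \
                brute_occurrence_count(alt_seq, mini_truth.motifs)
            assert changed == bool(flag)

    def test_frac_one_every_variant_flips(self, mini_genome, mini_truth):
        panel = syn.plant_variants(mini_genome, mini_truth, 20, 1.0, seed=3)
        assert panel.is_regulatory.all()

    def test_deterministic_panel(self, mini_genome, mini_truth):
        a = syn.plant_variants(mini_genome, mini_truth, 100, 0.4, seed=5)
        b = syn.plant_variants(mini_genome, mini_truth, 100, 0.4, seed=5)
        assert [v.key for v in a.variants] == [v.key for v in b.variants]
        np.testing.assert_array_equal(a.is_regulatory, b.is_regulatory)

    def test_too_short_genome_rejected(self):
        g = syn.SyntheticGenome(["chr1"], ["ATGACGGATC"], seed=0)
        truth = syn.TrackTruthModel(k=1, motifs=["TGAC"], seed=0)
        with pytest.raises(ValueError):
            syn.plant_variants(g, truth, 50, 1.0, seed=0)


def _quick_panel(n=60, seed=8):
    g = syn.make_genome(1, 150_000, seed=seed)
    truth = syn.TrackTruthModel(k=2, motifs=["TGAC", "GGAT"], seed=seed)
    return syn.plant_variants(g, truth, n, 0.5, seed=seed, edge_margin=100)


class TestSimulateCohort:
    def test_h2_zero_expression_independent_of_genotype(self):
        panel = _quick_panel()
        genes = syn.define_genes(panel, 3, 2, 1.0, seed=1)
        truth, geno, expr = syn.simulate_cohort(panel, 400, (0.2, 0.5), genes, 0.0, seed=2)
        for gd in genes:
            for vid, _ in gd.causal:
                r = np.corrcoef(geno[vid], expr[gd.gene])[0, 1]
                assert abs(r) < 3 / np.sqrt(400)

    def test_maf_half_empirical_frequency(self):
        panel = _quick_panel(n=20)
        genes = syn.define_genes(panel, 2, 2, 1.0, seed=1)
        _, geno, _ = syn.simulate_cohort(panel, 10_000, (0.5, 0.5), genes, 0.3, seed=3)
        freqs = geno.mean(axis=0) / 2
        assert (np.abs(freqs - 0.5) < 0.015).all()

    def test_bit_identical_under_seed(self):
        panel = _quick_panel(n=20)
        genes = syn.define_genes(panel, 2, 2, 1.0, seed=1)
        t1, g1, e1 = syn.simulate_cohort(panel, 50, (0.1, 0.5), genes, 0.4, seed=9)
        t2, g2, e2 = syn.simulate_cohort(panel, 50, (0.1, 0.5), genes, 0.4, seed=9)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_cis_r2_approaches_h2(self):
        # residualize covariates, then R^2 of expression on the true causal
        # dosage combination should approach the nominal h2
        from tcratl.twas import residualize_expression

        panel = _quick_panel()
        genes = syn.define_genes(panel, 2, 2, 1.0, seed=4)
        h2 = 0.4
        truth, geno, expr = syn.simulate_cohort(panel, 2000, (0.2, 0.5), genes, h2, seed=5)
        gd = genes[0]
        genetic = sum(eff * geno[vid].to_numpy() for vid, eff in gd.causal)
        resid = residualize_expression(expr[gd.gene].to_numpy(), truth.covariates)
        r2 = np.corrcoef(genetic, resid)[0, 1] ** 2
        assert abs(r2 - h2) < 0.05

    def test_invalid_inputs(self):
        panel = _quick_panel(n=10)
        genes = syn.define_genes(panel, 1, 2, 1.0, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_cohort(panel, 5, (0.1, 0.5), genes, 0.5, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_cohort(panel, 50, (0.0, 0.5), genes, 0.5, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_cohort(panel, 50, (0.1, 0.5), [], 0.5, seed=0)


class TestGwasSummary:
    def test_null_type_one_error_rate(self):
        panel = _quick_panel(n=400, seed=11)
        ss = syn.simulate_gwas_summary(panel, {}, 5000, 5000, seed=1)
        frac = (ss["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(ss))
        assert abs(frac - 0.05) < 3 * se

    def test_large_effect_attains_minimum_p(self):
        panel = _quick_panel(n=50, seed=12)
        target = panel.variants[10].id
        ss = syn.simulate_gwas_summary(panel, {target: 1.0}, 100_000, 100_000, seed=2)
        assert ss.loc[ss["p"].idxmin(), "id"] == target

    def test_deterministic(self):
        panel = _quick_panel(n=30, seed=13)
        a = syn.simulate_gwas_summary(panel, {}, 1000, 1000, seed=3)
        b = syn.simulate_gwas_summary(panel, {}, 1000, 1000, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_individual_level_mode_recovers_effect(self):
        panel = _quick_panel(n=5, seed=14)
        target = panel.variants[0].id
        ss = syn.simulate_gwas_summary(
            panel, {target: 0.5}, 3000, 3000, seed=4,
            freqs={v.id: 0.3 for v in panel.variants}, method="individual",
        )
        row = ss.set_index("id").loc[target]
        assert abs(row["beta"] - 0.5) < 3 * row["se"]
        assert row["se"] > 0


class TestAnnotationFixtures:
    def test_enrichment_factor_one_is_null(self):
        panel = _quick_panel(n=300, seed=21)
        fx = syn.make_annotation_fixtures(panel, ["g1", "g2"], seed=1,
                                          enhancer_enrichment=1.0, p_base=0.3)
        from tcratl.enrichment import StateAnnotation, overlap_proportion

        reg = [v for v, f in zip(panel.variants, panel.is_regulatory) if f]
        nonreg = [v for v, f in zip(panel.variants, panel.is_regulatory) if not f]
        ann = StateAnnotation("t", fx.states[fx.tissue_cell_lines[0]])
        p_r, p_n = overlap_proportion(reg, ann), overlap_proportion(nonreg, ann)
        se = np.sqrt(0.3 * 0.7 * (1 / len(reg) + 1 / len(nonreg)))
        assert abs(p_r - p_n) < 3 * se

    def test_essential_gene_median_below_cutoff(self):
        panel = _quick_panel(n=20, seed=22)
        fx = syn.make_annotation_fixtures(panel, [f"g{i}" for i in range(10)], seed=2)
        med = fx.ceres.groupby("gene")["score"].median()
        for g in fx.truth["essential_genes"]:
            assert med[g] < -0.5

    def test_pathogenic_truth_rows_are_germline_pathogenic(self):
        panel = _quick_panel(n=60, seed=23)
        fx = syn.make_annotation_fixtures(panel, ["g1"], seed=3, n_pathogenic=14)
        keep = fx.pathogenic[
            (fx.pathogenic["clinical_significance"] == "pathogenic")
            & (fx.pathogenic["origin"] == "germline")
        ]
        assert len(keep) == 14
        assert set(fx.truth["pathogenic_germline_ids"]) <= {v.id for v in panel.variants}


def test_injected_n_runs_encode_to_zero_rows():
    g = syn.make_genome(1, 2000, seed=1)
    g2 = syn.inject_n_runs(g, n_runs=3, run_length=50, seed=2)
    from tcratl.data_prep import one_hot_encode

    oh = one_hot_encode(g2.sequences[0])
    n_count = g2.sequences[0].count("N")
    assert n_count >= 50
    assert oh.sum() == len(g2.sequences[0]) - n_count
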