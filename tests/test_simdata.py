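"""Tests for the synthetic-data generator and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from conftest import SEED
from tnpipe.enrichment import hypergeom_enrich
from tnpipe.simdata import (
    MECHANISM_PRESETS,
    ConfigError,
    SimConfig,
    gen_count_matrix,
    gen_exon_depth_and_probes,
    gen_gene_sets,
    gen_paired_counts,
    simulate_cohort,
    subgroup_signatures,
)
from tnpipe.cna_loh import windowed_z
from tnpipe import io


class TestConfig:
    def test_invalid_depth_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            SimConfig(depth_mean=0.0)

    def test_de_ratio_outside_model_range_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            SimConfig(de_up_frac=0.05, de_down_frac=0.05)  # ratio 1 < 1.5

    def test_n_somatic_bounded_by_sites(self):
        with pytest.raises((ConfigError, ValueError)):
            SimConfig(n_sites=10, n_somatic=11)


class TestPairedCounts:
    def test_depth_mean_recovered(self):
        """Empirical mean depth over 10k sites within 2% of the target."""
        cfg = SimConfig(n_sites=10_000, n_genes=600, n_somatic=0, seed=SEED)
        sites, _ = gen_paired_counts(cfg)
        depths = [s.tumor.depth for s in sites] + [s.normal.depth for s in sites]
        assert np.mean(depths) == pytest.approx(cfg.depth_mean, rel=0.02)

    def test_zero_error_rate_means_clean_normals(self):
        cfg = SimConfig(
            n_sites=500, n_genes=600, n_somatic=100, purity=1.0, somatic_vaf=0.5,
            error_rate=0.0, germline_het_rate=0.0, seed=SEED,
        )
        sites, truth = gen_paired_counts(cfg)
        by_id = {s.site_id: s for s in sites}
        assert all(by_id[sid].normal.alt_count == 0 for sid in truth.somatic_sites)

    def test_no_somatic_config_has_empty_truth(self):
        cfg = SimConfig(n_sites=200, n_genes=600, n_somatic=0, seed=SEED)
        _, truth = gen_paired_counts(cfg)
        assert truth.somatic_sites == {}

    def test_truth_labels_partition_sites(self):
        cfg = SimConfig(
            n_sites=1000, n_genes=600, n_somatic=100, germline_het_rate=0.5, seed=SEED
        )
        sites, truth = gen_paired_counts(cfg)
        som = set(truth.somatic_sites)
        germ = set(truth.germline_sites)
        assert not som & germ
        assert som | germ <= {s.site_id for s in sites}

    def test_loh_sites_lie_in_regions_and_push_tumor_vaf(self):
        cfg = SimConfig(n_sites=4000, n_genes=600, n_somatic=0, seed=SEED)
        sites, truth = gen_paired_counts(cfg)
        assert truth.loh_sites  # default region covers the driver tile
        by_id = {s.site_id: s for s in sites}
        vafs = [
            by_id[sid].tumor.alt_count / by_id[sid].tumor.depth
            for sid in truth.loh_sites
        ]
        assert all(v <= 0.2 or v >= 0.8 for v in vafs)

    def test_seeded_determinism(self):
        cfg = SimConfig(n_sites=300, n_genes=600, n_somatic=30, seed=SEED)
        a, _ = gen_paired_counts(cfg)
        b, _ = gen_paired_counts(cfg)
        assert a == b


class TestCountMatrix:
    def test_determinism_bitwise(self):
        cfg = SimConfig(n_genes=300, seed=SEED)
        a, _ = gen_count_matrix(cfg)
        b, _ = gen_count_matrix(cfg)
        assert a.counts.equals(b.counts)

    def test_zero_lfc_plants_nothing(self):
        cfg = SimConfig(n_genes=300, lfc_magnitude=0.0, seed=SEED)
        _, truth = gen_count_matrix(cfg)
        assert truth.de_genes == {}

    def test_planted_up_down_ratio_exact(self):
        # 1000 genes at 3.4% up / 2% down: ratio exactly 1.7 by construction
        cfg = SimConfig(
            n_genes=1000, de_up_frac=0.034, de_down_frac=0.02, seed=SEED
        )
        _, truth = gen_count_matrix(cfg)
        n_up = sum(d == "UP" for d, _ in truth.de_genes.values())
        n_down = sum(d == "DOWN" for d, _ in truth.de_genes.values())
        assert (n_up, n_down) == (34, 20)
        assert n_up / n_down == pytest.approx(1.7)

    def test_marginal_means_match_baselines(self):
        """Mean generated control count tracks the configured baseline within 2%."""
        from tnpipe.simdata import baseline_means

        cfg = SimConfig(n_genes=5000, n_controls=5, libsize_sd=0.0, seed=SEED)
        cm, _ = gen_count_matrix(cfg)
        base = baseline_means(cfg)
        controls = [c for c in cm.counts.columns if c.startswith("C")]
        ratio = cm.counts[controls].to_numpy().mean() / base.mean()
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises((ConfigError, ValueError)):
            gen_count_matrix(SimConfig(n_genes=300, n_tumors=1, seed=SEED))


class TestGeneSets:
    def test_single_fully_de_set_is_the_unique_enriched_entry(self):
        cfg = SimConfig(
            n_genes=600, n_gene_sets=1, n_enriched_sets=1, enriched_de_frac=1.0,
            set_size_min=10, set_size_max=12, seed=SEED,
        )
        coll, cancer, truth = gen_gene_sets(cfg)
        assert truth.enriched_sets == ["SET001"]
        de = set(truth.de_genes)
        assert coll.sets["SET001"] <= de

    def test_disjoint_sets_share_no_genes(self):
        cfg = SimConfig(n_genes=2000, n_gene_sets=10, disjoint_sets=True, seed=SEED)
        coll, _, _ = gen_gene_sets(cfg)
        seen = set()
        for members in coll.sets.values():
            assert not members & seen
            seen |= members

    def test_top_gene_in_first_enriched_set_and_cancer_list(self):
        cfg = SimConfig(n_genes=600, seed=SEED)
        coll, cancer, truth = gen_gene_sets(cfg)
        assert truth.top_gene in coll.sets[truth.enriched_sets[0]]
        assert truth.top_gene in cancer

    def test_random_sets_give_uniformish_pvalues(self):
        """With no planted structure, enrichment p-values are super-uniform."""
        cfg = SimConfig(
            n_genes=2000, n_gene_sets=200, n_enriched_sets=0, seed=SEED
        )
        coll, _, _ = gen_gene_sets(cfg)
        rng = np.random.default_rng(SEED)
        query = list(rng.choice(sorted(coll.universe), size=150, replace=False))
        recs = hypergeom_enrich(query, coll, q_max=0.05)
        ps = np.array([r.p for r in recs])
        for alpha in (0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps < alpha).mean() <= alpha + 3 * se
        assert not any(r.enriched for r in recs)


class TestExonsAndProbes:
    def test_noiseless_het_deletion_exact_ratio(self):
        cfg = SimConfig(n_genes=600, exon_noise_sd=0.0, probe_noise_sd=0.0, seed=SEED)
        exons, _, truth = gen_exon_depth_and_probes(cfg)
        driver_rows = exons[exons["gene"] == cfg.driver_gene]
        assert (driver_rows["log2_ratio"] == -1.0).all()

    def test_no_deletions_means_pure_noise(self):
        cfg = SimConfig(n_genes=600, exon_noise_sd=0.1, seed=SEED)
        exons, _, truth = gen_exon_depth_and_probes(cfg)
        neutral = exons[~exons["gene"].isin(truth.deleted_genes)]
        assert abs(neutral["log2_ratio"].mean()) < 0.01
        assert neutral["log2_ratio"].std() == pytest.approx(0.1, rel=0.1)

    def test_windowed_z_flags_exactly_the_planted_tiles(self):
        cfg = SimConfig(n_genes=600, exon_noise_sd=0.0, probe_noise_sd=0.0, seed=SEED)
        _, probes, truth = gen_exon_depth_and_probes(cfg)
        results = windowed_z(probes, window_bp=cfg.window_bp)
        flagged = {r.start for r in results if r.flagged}
        from tnpipe.simdata import gene_model

        model = gene_model(cfg)
        expected = {
            ((int(model.at[g, "start"]) - 1) // cfg.window_bp) * cfg.window_bp + 1
            for g in truth.deleted_genes
        }
        assert flagged == expected


class TestCohort:
    def test_mechanism_presets_cover_the_four_patients(self, small_config):
        cohort = simulate_cohort(small_config)
        assert len(cohort.tumor_samples) == 4
        assert sorted(set(cohort.truth.mechanisms.values())) == sorted(
            {l.expected_mechanism for l in MECHANISM_PRESETS}
        )

    def test_signatures_exclude_reference_and_de_genes(self, small_config):
        sig = subgroup_signatures(small_config)
        cohort = simulate_cohort(small_config)
        for genes in sig.signatures.values():
            assert small_config.reference_gene not in genes
            assert not set(genes) & set(cohort.truth.de_genes)

    def test_every_somatic_site_annotated(self, small_config):
        cohort = simulate_cohort(small_config)
        for sid in cohort.truth.somatic_sites:
            assert sid in cohort.annotations

    def test_truth_roundtrips_through_json(self, small_config, tmp_path):
        cohort = simulate_cohort(small_config)
        path = tmp_path / "truth.json"
        cohort.truth.to_json(path)
        from tnpipe.simdata import TruthSet

        back = TruthSet.from_json(path)
        assert back.somatic_sites == cohort.truth.somatic_sites
        assert back.de_genes == cohort.truth.de_genes
        assert back.mechanisms == cohort.truth.mechanisms


class TestIORoundtrips:
    def test_paired_counts_tsv(self, small_config, tmp_path):
        sites, _ = gen_paired_counts(
            SimConfig(n_sites=50, n_genes=600, n_somatic=5, seed=SEED)
        )
        path = tmp_path / "sites.tsv"
        io.write_paired_counts(sites, path)
        assert io.read_paired_counts(path) == sites

    def test_paired_counts_vcf(self, tmp_path):
        sites, _ = gen_paired_counts(
            SimConfig(n_sites=30, n_genes=600, n_somatic=5, seed=SEED)
        )
        path = tmp_path / "sites.vcf"
        io.write_paired_vcf(sites, path)
        back = io.read_paired_vcf(path)
        assert sorted(back, key=lambda s: s.pos) == sorted(sites, key=lambda s: s.pos)

    def test_count_matrix_roundtrip(self, tmp_path):
        cm, _ = gen_count_matrix(SimConfig(n_genes=50, seed=SEED))
        io.write_count_matrix(cm, tmp_path)
        back = io.read_count_matrix(
            tmp_path / "counts.tsv", tmp_path / "lengths.tsv", tmp_path / "samples.tsv"
        )
        assert back.counts.equals(cm.counts)
        assert (back.groups == cm.groups).all()

    def test_gmt_roundtrip(self, tmp_path):
        cfg = SimConfig(n_genes=600, seed=SEED)
        coll, _, _ = gen_gene_sets(cfg)
        path = tmp_path / "sets.gmt"
        coll.to_gmt(path)
        from tnpipe.enrichment import GeneSetCollection

        back = GeneSetCollection.from_gmt(path, universe=coll.universe)
        assert back.sets == coll.sets
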