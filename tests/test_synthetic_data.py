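import filecmp

import numpy as np
import pytest

from polycap.formats_io import (
    ValidationError,
    read_bedgraph,
    read_genome_index,
    read_targets_bed,
    read_vcf,
)
from polycap.synthetic_data import (
    SimulationConfig,
    add_replacement_event,
    homoeolog_partner,
    inject_hemi_snps,
    simulate_experiment,
)


def _region_mass(track, region):
    return track.region_mass(region.chrom, region.start, region.end)


class TestDeterminism:
    def test_identical_seeds_give_bitwise_identical_files(self, tmp_path):
        config = SimulationConfig(n_genes=2, seed=42)
        d1 = simulate_experiment(config).write(tmp_path / "run1")
        d2 = simulate_experiment(
            SimulationConfig(n_genes=2, seed=42)).write(tmp_path / "run2")
        for name in d1:
            assert filecmp.cmp(d1[name], d2[name], shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        t1 = simulate_experiment(SimulationConfig(n_genes=1, seed=1))
        t2 = simulate_experiment(SimulationConfig(n_genes=1, seed=2))
        assert t1.tracks["geno1"] != t2.tracks["geno1"]


class TestNullModel:
    def test_all_normal_zero_rates_gives_no_truth_entries_and_empty_vcfs(self):
        config = SimulationConfig(n_genes=2, snp_rate=0.0, hemi_site_rate=0.0,
                                  seed=3)
        experiment = simulate_experiment(config)
        assert experiment.truth.events.empty
        assert experiment.truth.snps.empty
        assert all(not v for v in experiment.variants.values())


class TestCopyNumberEvents:
    def test_absent_locus_has_zero_depth_in_its_genotype_only(self):
        config = SimulationConfig(
            n_genes=1, snp_rate=0, hemi_site_rate=0,
            events={"geno2": {"Bna.G01.A01_1": 0.0}}, seed=4)
        experiment = simulate_experiment(config)
        region = next(t for t in experiment.targets
                      if t.copy_id == "Bna.G01.A01_1")
        assert _region_mass(experiment.tracks["geno2"], region) == 0
        assert _region_mass(experiment.tracks["geno1"], region) > 0

    def test_multiplier_scales_expected_depth(self):
        config = SimulationConfig(
            n_genes=1, snp_rate=0, hemi_site_rate=0, background_mean=2.0,
            events={"geno2": {"Bna.G01.A01_1": 2.0}}, seed=4)
        experiment = simulate_experiment(config)
        region = next(t for t in experiment.targets
                      if t.copy_id == "Bna.G01.A01_1")
        m1 = _region_mass(experiment.tracks["geno1"], region)
        m2 = _region_mass(experiment.tracks["geno2"], region)
        assert m2 / m1 == pytest.approx(2.0, rel=0.2)


class TestEnrichmentGeometry:
    def test_on_off_target_depth_ratio_tracks_enrichment_factor(self):
        """Monte-Carlo check: mean on/off-target depth ratio within 5% of E
        at a deep background (mean >= 5), averaged over 10 replicates."""
        ratios = []
        for seed in range(10):
            config = SimulationConfig(
                n_genes=2, background_mean=5.0, genome_length=2_000_000,
                background_window=1000, snp_rate=0, hemi_site_rate=0,
                genotypes=("geno1",), seed=seed)
            exp = simulate_experiment(config)
            track = exp.tracks["geno1"]
            target_mass = sum(_region_mass(track, t) for t in exp.targets)
            target_len = sum(t.length for t in exp.targets)
            off_mass = track.total_aligned_bases - target_mass
            off_len = exp.genome_index.total_length - target_len
            ratios.append((target_mass / target_len) / (off_mass / off_len))
        assert np.mean(ratios) == pytest.approx(760, rel=0.05)


class TestHemiInjection:
    def test_zero_rate_injects_nothing(self):
        seq = "ACGT" * 100
        new_seq, sites = inject_hemi_snps(seq, seq, 0.0, 1)
        assert new_seq == seq and sites == []

    def test_sites_reproducible_and_forced_divergent(self):
        rng_seed = 77
        primary = "A" * 1000
        partner = "A" * 1000
        new1, sites1 = inject_hemi_snps(primary, partner, 0.01, rng_seed)
        new2, sites2 = inject_hemi_snps(primary, partner, 0.01, rng_seed)
        assert sites1 == sites2 and new1 == new2
        assert 2 <= len(sites1) <= 25  # ~10 expected at 1 kb x 0.01
        for offset, a, b in sites1:
            assert a != b and new1[offset] == b

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            inject_hemi_snps("AAAA", "AAA", 0.1, 1)

    def test_excessive_rate_warns(self, caplog):
        with caplog.at_level("WARNING"):
            inject_hemi_snps("A" * 100, "A" * 100, 0.7, 1)
        assert "unrealistic" in caplog.text


class TestReplacementEvents:
    def test_replacement_zeroes_one_copy_and_doubles_partner(self):
        config = SimulationConfig(n_genes=1)
        ids = ["Bna.G01.A01_1", "Bna.G01.C01_1"]
        add_replacement_event(config, "geno4", "Bna.G01.C01_1", ids)
        assert config.events["geno4"]["Bna.G01.C01_1"] == 0.0
        assert config.events["geno4"]["Bna.G01.A01_1"] == 2.0

    def test_replacement_without_partner_is_a_config_error(self):
        config = SimulationConfig(n_genes=1)
        with pytest.raises(ValidationError, match="no homoeolog partner"):
            add_replacement_event(config, "geno1", "Bna.G01.C01_1",
                                  ["Bna.G01.C01_1"])

    def test_partner_lookup(self):
        ids = ["Bna.FLC.A10_1", "Bna.FLC.C09_1"]
        assert homoeolog_partner("Bna.FLC.C09_1", ids) == "Bna.FLC.A10_1"
        assert homoeolog_partner("Bna.CDF1.unk_1", ids) is None


class TestEmittedFilesAreValid:
    def test_outputs_pass_format_validation(self, tmp_path, small_experiment):
        paths = small_experiment.write(tmp_path)
        gi = read_genome_index(paths["genome_index.tsv"])
        assert gi.lengths == small_experiment.genome_index.lengths
        targets = read_targets_bed(paths["targets.bed"])
        assert targets == small_experiment.targets
        for genotype in small_experiment.config.genotypes:
            track = read_bedgraph(paths[f"{genotype}.bedgraph"])
            assert track == small_experiment.tracks[genotype]
            records = read_vcf(paths[f"{genotype}.vcf"])
            assert records == small_experiment.variants[genotype]

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimulationConfig(inter_homoeolog_identity=0.0)
        with pytest.raises(ValidationError):
            SimulationConfig(cds_length=100)
        with pytest.raises(ValidationError):
            SimulationConfig(events={"geno1": {"x": -1.0}})
        with pytest.raises(ValidationError, match="genome_length"):
            simulate_experiment(SimulationConfig(n_genes=50,
                                                 genome_length=100_000))
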