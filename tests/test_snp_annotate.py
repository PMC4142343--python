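import itertools

import pytest
from Bio.Seq import Seq

from polycap.formats_io import TargetRegion, ValidationError, VariantRecord
from polycap.snp_annotate import (
    CdsModel,
    classify_effect,
    classify_zygosity,
    het_loci_by_genotype,
    substitution_effect,
    summarize_snps,
    zygosity_percentages,
)
from polycap.synthetic_data import SimulationConfig, simulate_experiment


def _rec(call, pos=100, ref="A", alt="G", sample="s1", depth=50):
    return VariantRecord("chr1", pos, ref, alt, {sample: call}, depth)


class TestZygosity:
    def test_hom_alt_is_a_homozygous_snp(self):
        assert classify_zygosity(_rec("hom_alt")) == "homozygous"

    def test_het_in_inbred_line_is_hemi(self):
        assert classify_zygosity(_rec("het"), inbred=True) == "hemi"

    def test_het_in_non_inbred_sample_is_withheld(self):
        assert classify_zygosity(_rec("het"), inbred=False) == \
            "heterozygous_unresolved"

    def test_hom_ref_and_missing_are_not_snps(self):
        assert classify_zygosity(_rec("hom_ref")) is None
        assert classify_zygosity(_rec("missing")) is None


class TestSubstitutionEffect:
    def test_wobble_position_is_synonymous(self):
        aa_ref, aa_alt, consequence, codon_pos = substitution_effect("GGA", 2, "G")
        assert (aa_ref, aa_alt) == ("G", "G")
        assert consequence == "synonymous" and codon_pos == 3

    def test_first_position_change_is_nonsynonymous(self):
        _, aa_alt, consequence, _ = substitution_effect("GGA", 0, "A")
        assert consequence == "non_synonymous" and aa_alt == "R"

    def test_frame_violation_rejected(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            substitution_effect("GGAA", 0, "C")

    def test_exhaustive_codon_space_matches_translation_oracle(self):
        """All 576 single-base substitutions over the 64 codons, checked
        against independent whole-sequence translation."""
        bases = "ACGT"
        checked = 0
        for codon in map("".join, itertools.product(bases, repeat=3)):
            for i, alt in itertools.product(range(3), bases):
                if alt == codon[i]:
                    continue
                _, _, consequence, _ = substitution_effect(codon, i, alt)
                mutated = codon[:i] + alt + codon[i + 1:]
                oracle = ("synonymous"
                          if str(Seq(codon).translate()) == str(Seq(mutated).translate())
                          else "non_synonymous")
                assert consequence == oracle, (codon, i, alt)
                checked += 1
        assert checked == 576


class TestClassifyEffect:
    def _model(self, strand="+", cds="ATGGGATAA"):
        # gene body at chr1:100-130, CDS in the middle, promoter up/downstream
        exons = ((110, 110 + len(cds)),)
        promoter = (100, 110) if strand == "+" else (110 + len(cds), 130)
        return CdsModel("g.A01_1", "chr1", strand, exons,
                        cds if strand == "+" else cds,
                        promoter=promoter, gene_span=(100, 130))

    def test_plus_strand_exon_variant(self):
        model = self._model("+")
        # CDS base 5 (0-based) is codon 2 position 3: GGA -> GGG, synonymous
        effect = classify_effect(model, _rec("hom_alt", pos=116, ref="A", alt="G"))
        assert effect.location == "exon"
        assert effect.consequence == "synonymous"
        assert effect.codon_position == 3

    def test_minus_strand_variant_is_complemented_onto_coding_strand(self):
        # coding strand ATGGGATAA on the minus strand: genomic plus strand is
        # its reverse complement, so genomic position maps backwards
        model = self._model("-")
        # coding index 5 ('A' of GGA) sits at genomic pos0 110 + (9-1-5) = 113
        # genomic ref = complement('A') = 'T'; genomic alt 'C' -> coding 'G'
        effect = classify_effect(model, _rec("hom_alt", pos=114, ref="T", alt="C"))
        assert effect.location == "exon"
        assert effect.consequence == "synonymous"  # GGA -> GGG on coding strand
        assert (effect.aa_ref, effect.aa_alt) == ("G", "G")

    def test_promoter_and_intergenic_locations(self):
        model = self._model("+")
        assert classify_effect(model, _rec("hom_alt", pos=105)).location == \
            "promoter"
        assert classify_effect(model, _rec("hom_alt", pos=500)).location == \
            "intergenic"

    def test_frame_violation_yields_not_applicable_with_reason(self):
        model = CdsModel("g.A01_1", "chr1", "+", ((110, 114),), "ATGG")
        effect = classify_effect(model, _rec("hom_alt", pos=111, ref="T", alt="C"))
        assert effect.consequence == "not_applicable"
        assert "divisible by 3" in effect.reason

    def test_reference_mismatch_reported_not_classified(self):
        model = self._model("+")
        effect = classify_effect(model, _rec("hom_alt", pos=116, ref="C", alt="G"))
        assert effect.consequence == "not_applicable"
        assert "reference mismatch" in effect.reason


class TestSummaries:
    TARGETS = [TargetRegion("chr1", 0, 1000, "g.A01_1")]

    def test_counts_and_percentages(self):
        records = {
            "s1": [_rec("hom_alt", pos=10), _rec("het", pos=20),
                   _rec("hom_alt", pos=5000)],
            "s2": [_rec("hom_alt", pos=10)],
        }
        summary = summarize_snps(records, self.TARGETS, target_length=1000)
        t = summary.table
        assert t.loc["s1", "total"] == 3 and t.loc["s1", "target"] == 2
        assert t.loc["s1", "target_hom"] == 1 and t.loc["s1", "target_het"] == 1
        # panel-wide distinct variants: 3 total, 2 on target
        assert summary.panel_total == 3 and summary.panel_target_total == 2
        assert t.loc["s1", "target_hom_pct"] == pytest.approx(50.0)
        assert summary.density_bp_per_snp == 500

    def test_empty_record_set_gives_all_zero_summary(self):
        summary = summarize_snps({"s1": []}, self.TARGETS, target_length=1000)
        assert (summary.table.loc["s1", ["total", "target"]] == 0).all()
        assert summary.density_bp_per_snp is None

    def test_published_panel_percentage_convention(self):
        import pandas as pd
        counts = pd.DataFrame({"total_hom": [2772], "total_het": [5259],
                               "target_hom": [546], "target_het": [1145]},
                              index=["25629-3"])
        pct = zygosity_percentages(counts, panel_total=17316,
                                   panel_target_total=4269)
        assert pct.loc["25629-3", "target_hom_pct"] == 12.79
        assert pct.loc["25629-3", "total_hom_pct"] == 16.01
        assert pct.loc["25629-3", "target_het_pct"] == 26.82

    def test_het_loci_exclusion_set(self):
        records = {"s1": [_rec("het", pos=10), _rec("hom_alt", pos=20)],
                   "s2": [_rec("hom_alt", pos=10)]}
        loci = het_loci_by_genotype(records, self.TARGETS)
        assert loci == {"s1": {"g.A01_1"}, "s2": set()}


class TestSimulatorTruthAgreement:
    @pytest.fixture(scope="class")
    @staticmethod
    def absence_experiment():
        """One gene pair with hemi sites; geno2 lacks the primary (A) copy."""
        config = SimulationConfig(
            n_genes=1, copies_per_subgenome=1, hemi_site_rate=0.02,
            snp_rate=0.001, genome_length=1_000_000,
            events={"geno2": {"Bna.G01.A01_1": 0.0}}, seed=23)
        return simulate_experiment(config)

    def test_shared_divergent_sites_are_hemi_where_both_copies_present(
            self, absence_experiment):
        truth = absence_experiment.truth.snps
        hemi_pos = set(truth[(truth.genotype == "geno1")
                             & (truth.zygosity == "hemi")].pos)
        assert hemi_pos, "expected some cross-locus divergent sites"
        for rec in absence_experiment.variants["geno1"]:
            expected = "hemi" if rec.pos in hemi_pos else "homozygous"
            assert classify_zygosity(rec) == expected

    def test_divergent_sites_turn_homozygous_when_one_homoeolog_is_lost(
            self, absence_experiment):
        truth = absence_experiment.truth.snps
        hemi_pos = set(truth[(truth.genotype == "geno1")
                             & (truth.zygosity == "hemi")].pos)
        geno2 = {r.pos: classify_zygosity(r)
                 for r in absence_experiment.variants["geno2"]}
        for pos in hemi_pos:
            assert geno2[pos] == "homozygous"
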