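import numpy as np
import pytest

from polycap.formats_io import (
    CoverageTrack,
    FormatError,
    GenomeIndex,
    TargetRegion,
    ValidationError,
    VariantRecord,
    parse_copy_id,
    read_bedgraph,
    read_genome_index,
    read_targets_bed,
    read_vcf,
    write_bedgraph,
    write_genome_index,
    write_targets_bed,
    write_vcf,
)

from conftest import random_track_segments


class TestGenomeIndex:
    def test_total_length_sums_chromosomes(self):
        gi = GenomeIndex({"chr1": 100, "chr2": 250})
        assert gi.total_length == 350
        assert gi.contains_interval("chr1", 0, 100)
        assert not gi.contains_interval("chr1", 50, 101)
        assert not gi.contains_interval("chrX", 0, 1)

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValidationError):
            GenomeIndex({"chr1": 0})

    def test_tsv_round_trip(self, tmp_path):
        gi = GenomeIndex({"chrA01": 12345, "chrC01": 999})
        path = tmp_path / "genome.tsv"
        write_genome_index(gi, path)
        assert read_genome_index(path).lengths == gi.lengths


class TestBedgraph:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.bedgraph"
        path.write_text("chr1 0 100 5\n")
        track = read_bedgraph(path)
        assert list(track.iter_segments()) == [("chr1", 0, 100, 5)]
        assert track.total_aligned_bases == 500

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        track = read_bedgraph(path)
        assert len(track) == 0 and track.covered_length == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t100\t5\nchr1\t100\tnotanumber\t3\n")
        with pytest.raises(FormatError, match="line 2"):
            read_bedgraph(path)

    def test_contradictory_overlap_rejected(self):
        with pytest.raises(ValidationError, match="contradictory overlap"):
            CoverageTrack([("chr1", 0, 100, 5), ("chr1", 50, 150, 7)])

    def test_equal_depth_overlap_and_adjacency_merge(self):
        track = CoverageTrack([("chr1", 50, 150, 5), ("chr1", 0, 100, 5),
                               ("chr1", 150, 200, 5)])
        assert list(track.iter_segments()) == [("chr1", 0, 200, 5)]

    def test_round_trip_byte_identity_on_random_tracks(self, tmp_path, rng):
        """write(read(f)) reproduces a canonically formatted f byte for byte."""
        for i in range(50):
            track = CoverageTrack(random_track_segments(rng))
            f1 = tmp_path / f"a{i}.bedgraph"
            f2 = tmp_path / f"b{i}.bedgraph"
            write_bedgraph(track, f1)
            reread = read_bedgraph(f1)
            write_bedgraph(reread, f2)
            assert f1.read_bytes() == f2.read_bytes()
            assert reread.total_aligned_bases == track.total_aligned_bases
            assert reread == track

    def test_region_queries_match_per_base_scan(self, rng):
        segments = random_track_segments(rng, n_segments=60)
        track = CoverageTrack(segments)
        arr = np.zeros(10_000, dtype=int)
        for chrom, s, e, d in segments:
            if chrom == "chr1":
                arr[s:e] = d
        for _ in range(25):
            qs = int(rng.integers(0, 9000))
            qe = qs + int(rng.integers(1, 1000))
            assert track.region_mass("chr1", qs, qe) == arr[qs:qe].sum()
            assert (track.region_bases_ge("chr1", qs, qe, 10)
                    == int((arr[qs:qe] >= 10).sum()))


class TestTargetsBed:
    def test_copy_id_parsing(self):
        assert parse_copy_id("Bna.TEM1.C02_1") == ("Bna.TEM1", "C")
        assert parse_copy_id("Bna.CDF1.unk_1") == ("Bna.CDF1", "unk")
        assert parse_copy_id("weird-name") == ("weird-name", "unk")

    def test_round_trip_with_metadata(self, tmp_path):
        regions = [
            TargetRegion("chrA02", 100, 1300, "Bna.TEM1.A02_1"),
            TargetRegion("chrC02", 0, 900, "Bna.TEM1.C02_1", strand="-",
                         functional=False),
        ]
        path = tmp_path / "targets.bed"
        write_targets_bed(regions, path)
        back = read_targets_bed(path)
        assert back == regions
        assert back[0].subgenome == "A" and back[1].subgenome == "C"
        assert not back[1].functional

    def test_overlap_within_copy_rejected(self, tmp_path):
        path = tmp_path / "targets.bed"
        path.write_text("chr1\t0\t100\tg.A01_1\t0\t+\n"
                        "chr1\t50\t150\tg.A01_1\t0\t+\n")
        with pytest.raises(ValidationError, match="overlapping"):
            read_targets_bed(path)


class TestVcf:
    GI = GenomeIndex({"chr1": 100_000})

    def _records(self, depths):
        return [VariantRecord("chr1", 10 * (i + 1), "A", "G",
                              {"s1": "hom_alt"}, depth)
                for i, depth in enumerate(depths)]

    def test_depth_filter_excludes_below_threshold(self, tmp_path):
        """100 records, 37 with depth < 10, filter keeps the other 63."""
        rng = np.random.default_rng(7)
        depths = np.concatenate([rng.integers(0, 10, size=37),
                                 rng.integers(10, 500, size=63)])
        rng.shuffle(depths)
        path = tmp_path / "panel.vcf"
        write_vcf(self._records(depths), "s1", self.GI, path)
        # independent line scan of the written file
        kept_by_scan = sum(
            1 for line in path.read_text().splitlines()
            if not line.startswith("#") and int(line.split("DP=")[1].split("\t")[0]) >= 10)
        records = read_vcf(path, min_depth=10)
        assert len(records) == kept_by_scan == 63
        assert all(r.depth >= 10 for r in records)

    def test_min_depth_zero_keeps_everything(self, tmp_path):
        path = tmp_path / "panel.vcf"
        write_vcf(self._records([0, 5, 9, 10, 100]), "s1", self.GI, path)
        assert len(read_vcf(path, min_depth=0)) == 5

    def test_boundary_depth_9_is_excluded_at_min_10(self, tmp_path):
        path = tmp_path / "panel.vcf"
        write_vcf(self._records([9]), "s1", self.GI, path)
        assert read_vcf(path, min_depth=10) == []

    def test_multiallelic_split_retains_depth(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t42\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t1/2:55\n")
        records = read_vcf(path)
        assert [(r.alt, r.depth) for r in records] == [("G", 55), ("T", 55)]
        assert [r.call("s1") for r in records] == ["het", "het"]

    def test_missing_gt_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t42\t.\tA\tG\t.\tPASS\t.\tGT:DP\t./.:55\n"
            "chr1\t43\t.\tA\tC\t.\tPASS\t.\tGT:DP\t1/1:30\n")
        with caplog.at_level("WARNING"):
            records = read_vcf(path)
        assert len(records) == 1 and records[0].pos == 43
        assert "skipped 1" in caplog.text

    def test_write_read_round_trip(self, tmp_path):
        records = [
            VariantRecord("chr1", 5, "A", "T", {"s1": "het"}, 42),
            VariantRecord("chr1", 99, "G", "C", {"s1": "hom_alt"}, 17),
        ]
        path = tmp_path / "rt.vcf"
        write_vcf(records, "s1", self.GI, path)
        assert read_vcf(path) == records

    def test_record_invariants(self):
        with pytest.raises(ValidationError):
            VariantRecord("chr1", 5, "A", "A", {"s1": "het"}, 10)
        with pytest.raises(ValidationError):
            VariantRecord("chr1", 0, "A", "T", {"s1": "het"}, 10)
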