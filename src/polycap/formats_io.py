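"""Readers and writers for the standard formats the capture pipeline touches.

Coordinate conventions: BED and bedGraph intervals are 0-based half-open;
VCF positions are 1-based.  Every conversion between the two happens inside
this module and nowhere else, so off-by-one risk is confined to one place.

The genome index (a two-column name/length TSV, as produced by ``samtools
faidx`` after dropping the extra columns) supplies the total genome length
G used by the coverage normalisation; it is read from its own file rather
than inferred from a depth track so that uncovered chromosomes still count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GT_CLASSES = ("hom_ref", "het", "hom_alt", "missing")


class FormatError(ValueError):
    """A file could not be parsed (malformed line, wrong column count...)."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Genome index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered mapping of sequence name -> length in bp."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValidationError("genome index is empty")
        for name, length in self.lengths.items():
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has length {length} <= 0")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def total_length(self) -> int:
        """Total genome length G = sum over chromosomes."""
        return int(sum(self.lengths.values()))

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return int(self.lengths[name])

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        return chrom in self.lengths and 0 <= start < end <= self.lengths[chrom]


def read_genome_index(path: str | Path) -> GenomeIndex:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["name", "length"])
    return GenomeIndex(dict(zip(df["name"].astype(str), df["length"].astype(int))))


def write_genome_index(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in index.lengths.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Sorted, non-overlapping constant-depth segments per chromosome.

    Uncovered bases are implicit depth 0.  Construction normalises the input
    to canonical form: segments sorted by (chrom, start), touching or
    overlapping segments of equal depth merged, depth-0 segments dropped.
    Overlapping segments with *different* depths are contradictory and
    rejected.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, int]] = ()) -> None:
        per_chrom: dict[str, list[list[int]]] = {}
        for chrom, start, end, depth in segments:
            start, end, depth = int(start), int(end), int(depth)
            if start < 0 or start >= end:
                raise ValidationError(
                    f"bad segment {chrom}:{start}-{end} (need 0 <= start < end)")
            if depth < 0:
                raise ValidationError(f"negative depth {depth} at {chrom}:{start}-{end}")
            per_chrom.setdefault(str(chrom), []).append([start, end, depth])

        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(per_chrom):
            rows = sorted(per_chrom[chrom])
            merged: list[list[int]] = []
            for start, end, depth in rows:
                if merged and start < merged[-1][1]:
                    if depth != merged[-1][2]:
                        raise ValidationError(
                            f"contradictory overlap at {chrom}:{start} "
                            f"(depth {depth} vs {merged[-1][2]})")
                    merged[-1][1] = max(merged[-1][1], end)
                elif merged and start == merged[-1][1] and depth == merged[-1][2]:
                    merged[-1][1] = end
                else:
                    merged.append([start, end, depth])
            merged = [row for row in merged if row[2] > 0]
            if merged:
                arr = np.asarray(merged, dtype=np.int64)
                self._data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])

    # -- basic accessors ----------------------------------------------------

    def chroms(self) -> list[str]:
        return list(self._data)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, depths) arrays for one chromosome (may be empty)."""
        empty = np.empty(0, dtype=np.int64)
        return self._data.get(chrom, (empty, empty, empty))

    def iter_segments(self) -> Iterator[tuple[str, int, int, int]]:
        for chrom, (s, e, d) in self._data.items():
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), int(d[i])

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return list(self.iter_segments()) == list(other.iter_segments())

    # -- aggregate queries --------------------------------------------------

    @property
    def total_aligned_bases(self) -> int:
        """Sum over segments of (end - start) * depth."""
        return int(sum(((e - s) * d).sum() for s, e, d in self._data.values()))

    @property
    def covered_length(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self._data.values()))

    def bases_with_depth_ge(self, k: int) -> int:
        """Total bases (anywhere) with depth >= k; k must be >= 1."""
        if k < 1:
            raise ValueError("k must be >= 1 (depth-0 bases are implicit)")
        total = 0
        for s, e, d in self._data.values():
            sel = d >= k
            total += int((e[sel] - s[sel]).sum())
        return total

    def region_mass(self, chrom: str, start: int, end: int) -> int:
        """Sum of depth * overlap length over [start, end)."""
        s, e, d = self.segments(chrom)
        if len(s) == 0:
            return 0
        i0 = int(np.searchsorted(e, start, side="right"))
        i1 = int(np.searchsorted(s, end, side="left"))
        if i0 >= i1:
            return 0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        return int((ov * d[i0:i1]).sum())

    def region_bases_ge(self, chrom: str, start: int, end: int, k: int) -> int:
        """Bases in [start, end) with depth >= k; k must be >= 1."""
        if k < 1:
            raise ValueError("k must be >= 1")
        s, e, d = self.segments(chrom)
        if len(s) == 0:
            return 0
        i0 = int(np.searchsorted(e, start, side="right"))
        i1 = int(np.searchsorted(s, end, side="left"))
        if i0 >= i1:
            return 0
        ov = np.minimum(e[i0:i1], end) - np.maximum(s[i0:i1], start)
        sel = d[i0:i1] >= k
        return int(ov[sel].sum())

    def scaled(self, factor: int) -> "CoverageTrack":
        """New track with every depth multiplied by an integer factor."""
        if int(factor) != factor or factor < 0:
            raise ValueError("factor must be a nonnegative integer")
        return CoverageTrack(
            (chrom, s, e, d * int(factor)) for chrom, s, e, d in self.iter_segments())


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Parse a whitespace-delimited chrom/start/end/depth file (0-based half-open)."""
    segments: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}")
            chrom, start, end, depth = fields
            try:
                segments.append((chrom, int(start), int(end), int(depth)))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return CoverageTrack(segments)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write canonical form: sorted, merged, depth-0 omitted, tab-separated."""
    with open(path, "w") as fh:
        for chrom, start, end, depth in track.iter_segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


# ---------------------------------------------------------------------------
# Target regions (BED6 + optional metadata columns)
# ---------------------------------------------------------------------------

_COPY_ID_RE = re.compile(r"^(?P<gene>.+)\.(?P<loc>[A-Za-z]+\w*?)_(?P<idx>\d+)$")


def parse_copy_id(copy_id: str) -> tuple[str, str]:
    """Split a copy id like ``Bna.TEM1.C02_1`` into (gene_id, subgenome).

    The subgenome is the leading letter of the chromosome token when it is
    A or C, otherwise ``unk``.
    """
    m = _COPY_ID_RE.match(copy_id)
    if not m:
        return copy_id, "unk"
    gene = m.group("gene")
    sub = m.group("loc")[0].upper()
    return gene, sub if sub in ("A", "C") else "unk"


@dataclass(frozen=True)
class TargetRegion:
    """One captured gene-copy interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    copy_id: str
    gene_id: str = ""
    subgenome: str = "unk"
    strand: str = "+"
    functional: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"bad target {self.copy_id}: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r} for {self.copy_id}")
        if self.subgenome not in ("A", "C", "unk"):
            raise ValidationError(f"bad subgenome {self.subgenome!r} for {self.copy_id}")
        if not self.gene_id:
            gene, sub = parse_copy_id(self.copy_id)
            object.__setattr__(self, "gene_id", gene)
            if self.subgenome == "unk":
                object.__setattr__(self, "subgenome", sub)

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_copy_overlaps(regions: Sequence[TargetRegion]) -> None:
    by_copy: dict[str, list[TargetRegion]] = {}
    for r in regions:
        by_copy.setdefault(r.copy_id, []).append(r)
    for copy_id, rows in by_copy.items():
        rows = sorted(rows, key=lambda r: (r.chrom, r.start))
        for a, b in zip(rows, rows[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValidationError(f"overlapping regions within copy {copy_id}")


def read_targets_bed(path: str | Path) -> list[TargetRegion]:
    """Read BED6 (+3 optional columns: gene_id, subgenome, functional)."""
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >= 6 BED columns")
            try:
                kwargs = dict(chrom=f[0], start=int(f[1]), end=int(f[2]),
                              copy_id=f[3], strand=f[5])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if len(f) >= 9:
                kwargs.update(gene_id=f[6], subgenome=f[7],
                              functional=f[8].lower() in ("1", "true", "yes"))
            regions.append(TargetRegion(**kwargs))
    _check_copy_overlaps(regions)
    return regions


def write_targets_bed(regions: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), r.copy_id, "0", r.strand,
                r.gene_id, r.subgenome, "1" if r.functional else "0"]) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A single-alt variant with per-sample genotype class and read depth."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    calls: Mapping[str, str]
    depth: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"VCF position {self.pos} < 1")
        if self.depth < 0:
            raise ValidationError(f"negative depth at {self.chrom}:{self.pos}")
        for sample, call in self.calls.items():
            if call not in GT_CLASSES:
                raise ValidationError(f"bad genotype class {call!r} for {sample}")
        object.__setattr__(self, "calls", dict(self.calls))

    def call(self, sample: str | None = None) -> str:
        if sample is None:
            if len(self.calls) != 1:
                raise ValueError("sample must be named for multi-sample records")
            return next(iter(self.calls.values()))
        return self.calls[sample]


def _classify_gt(alleles: tuple, alt_index: int) -> str:
    if alleles is None or all(a is None for a in alleles):
        return "missing"
    hits = sum(1 for a in alleles if a == alt_index)
    if hits == 0:
        return "hom_ref"
    if hits == len(alleles):
        return "hom_alt"
    return "het"


def read_vcf(path: str | Path, min_depth: int = 0) -> list[VariantRecord]:
    """Read a VCF 4.x file, split multi-allelics, and depth-filter records.

    Records with depth below ``min_depth`` are excluded; multi-allelic
    records yield one :class:`VariantRecord` per alt allele with the depth
    retained.  Records with a missing GT field are skipped (a warning with
    the skip count is logged).  Missing DP with ``min_depth > 0`` is a
    validation error because the filter cannot be applied.
    """
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            fmt_gt = [rec.samples[s].get("GT") for s in samples] if samples else []
            if samples and all(gt is None or all(a is None for a in gt) for gt in fmt_gt):
                skipped += 1
                continue
            depth = None
            if samples and len(samples) == 1:
                depth = rec.samples[samples[0]].get("DP")
            if depth is None:
                depth = rec.info.get("DP")
            if depth is None:
                if min_depth > 0:
                    raise ValidationError(
                        f"{path}: {rec.chrom}:{rec.pos} has no DP field but a "
                        f"depth filter of {min_depth} was requested")
                depth = 0
            if depth < min_depth:
                continue
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                calls = {s: _classify_gt(rec.samples[s].get("GT"), alt_index)
                         for s in samples}
                records.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    calls=calls, depth=int(depth)))
    if skipped:
        log.warning("%s: skipped %d records with missing GT", path, skipped)
    return records


def write_vcf(records: Sequence[VariantRecord], sample: str,
              genome_index: GenomeIndex, path: str | Path) -> None:
    """Write single-sample VCF 4.2 with GT:DP per record."""
    gt_strings = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=polycap",
    ]
    for name, length in genome_index.lengths.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        gt = gt_strings[rec.call(sample) if sample in rec.calls else rec.call()]
        lines.append("\t".join([
            rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS",
            f"DP={rec.depth}", "GT:DP", f"{gt}:{rec.depth}"]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene models emitted by the simulator / consumed by snp_annotate)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModelFeature:
    """One GFF3 feature row (0-based start internally, 1-based on disk)."""

    chrom: str
    source: str
    ftype: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str
    attributes: Mapping[str, str] = field(default_factory=dict)
    phase: str = "."


def write_gff3(features: Sequence[GeneModelFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write("\t".join([
                f.chrom, f.source, f.ftype, str(f.start + 1), str(f.end), ".",
                f.strand, f.phase, attrs]) + "\n")


def read_gff3(path: str | Path) -> list[GeneModelFeature]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    features = []
    for f in db.all_features(order_by=("seqid", "start")):
        features.append(GeneModelFeature(
            chrom=f.seqid, source=f.source, ftype=f.featuretype,
            start=f.start - 1, end=f.end, strand=f.strand,
            attributes={k: v[0] for k, v in f.attributes.items()},
            phase=str(f.frame) if f.frame is not None else "."))
    return features
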