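"""Capture-performance metrics for a targeted enrichment experiment.

All depth arithmetic is done on bedGraph-style constant-depth segments.
The key quantity is the *normalized coverage* of a depth value d:

    c = d * G / (N * rl)

where G is the total genome length, N the number of aligned reads and rl
the read length.  N * rl / G is the expected genome-wide mean depth, so c
expresses depth in units of that mean; c = 1 for a region covered exactly
at the genome-wide average, and the value is invariant under rescaling the
library size.  Each constant-depth segment contributes its depth weighted
by its length, and per-region values are length-weighted means.

The summary metrics mirror the standard capture QC panel: mean genome-wide
and on-target coverage, enrichment factor (their ratio), fraction of the
target covered at >= 1 and at a configurable depth k (default 10), and
specificity, the percentage of sequenced bases that fall on target.
Specificity is computed over bases, not reads, because read assignment is
not recoverable from a depth track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .formats_io import CoverageTrack, GenomeIndex, TargetRegion, ValidationError


@dataclass(frozen=True)
class AlignmentStats:
    """Aligned read count and read length of one sequencing library."""

    aligned_reads: int
    read_length: int

    def __post_init__(self) -> None:
        if self.aligned_reads < 0:
            raise ValidationError("aligned_reads must be >= 0")
        if self.read_length <= 0:
            raise ValidationError("read_length must be > 0")


@dataclass(frozen=True)
class CaptureMetrics:
    mean_genome_coverage: float
    mean_target_coverage: float
    enrichment_factor: float
    normalized_mean_target_coverage: float
    fraction_target_covered: float         # % of target bases with depth >= 1
    fraction_target_ge_k: float            # % of target bases with depth >= k
    specificity: float                     # % of sequenced bases on target
    genome_fraction_ge_k: float            # % of genome bases with depth >= k
    k: int

    def to_series(self) -> pd.Series:
        return pd.Series({
            "mean_genome_coverage": self.mean_genome_coverage,
            "mean_target_coverage": self.mean_target_coverage,
            "enrichment_factor": self.enrichment_factor,
            "normalized_mean_target_coverage": self.normalized_mean_target_coverage,
            "fraction_target_covered_pct": self.fraction_target_covered,
            f"fraction_target_ge_{self.k}_pct": self.fraction_target_ge_k,
            "specificity_pct": self.specificity,
            f"genome_fraction_ge_{self.k}_pct": self.genome_fraction_ge_k,
        })


def merged_intervals(regions: Sequence[TargetRegion],
                     genome_index: GenomeIndex | None = None,
                     ) -> dict[str, list[tuple[int, int]]]:
    """Union of target intervals per chromosome (for base-level metrics)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        if genome_index is not None and not genome_index.contains_interval(
                r.chrom, r.start, r.end):
            raise ValidationError(
                f"target {r.copy_id} ({r.chrom}:{r.start}-{r.end}) lies outside "
                f"the genome index")
        per_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort()
        out = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def mean_depth(track: CoverageTrack, genome_index: GenomeIndex,
               regions: Sequence[TargetRegion] | None = None) -> float:
    """Length-weighted mean depth over a region set or the whole genome.

    Uncovered bases count as depth 0.  Overlaps between regions are merged
    so no base is counted twice.
    """
    if regions is None:
        return track.total_aligned_bases / genome_index.total_length
    merged = merged_intervals(regions, genome_index)
    mass = 0
    length = 0
    for chrom, ivals in merged.items():
        for s, e in ivals:
            mass += track.region_mass(chrom, s, e)
            length += e - s
    if length == 0:
        raise ValidationError("empty region set")
    return mass / length


def normalized_coverage(depth: float, stats: AlignmentStats,
                        genome_index: GenomeIndex) -> float:
    """depth * G / (N * rl): depth in units of the expected genome-wide mean."""
    denominator = stats.aligned_reads * stats.read_length
    if denominator == 0:
        raise ValidationError(
            "normalized coverage undefined: zero aligned reads")
    return depth * genome_index.total_length / denominator


def capture_metrics(track: CoverageTrack, targets: Sequence[TargetRegion],
                    stats: AlignmentStats, genome_index: GenomeIndex,
                    k: int = 10, strict_gt: bool = False) -> CaptureMetrics:
    """Compute the full capture QC panel for one genotype.

    ``fraction_target_covered`` counts target bases with depth >= 1;
    ``fraction_target_ge_k`` uses depth >= k, or depth > k when
    ``strict_gt`` is set.
    """
    if not targets:
        raise ValidationError("empty target set")
    merged = merged_intervals(targets, genome_index)
    kk = k + 1 if strict_gt else k

    target_len = 0
    target_mass = 0
    covered_ge1 = 0
    covered_gek = 0
    for chrom, ivals in merged.items():
        for s, e in ivals:
            target_len += e - s
            target_mass += track.region_mass(chrom, s, e)
            covered_ge1 += track.region_bases_ge(chrom, s, e, 1)
            covered_gek += track.region_bases_ge(chrom, s, e, kk)

    G = genome_index.total_length
    genome_mass = track.total_aligned_bases
    mean_genome = genome_mass / G
    mean_target = target_mass / target_len
    enrichment = mean_target / mean_genome if mean_genome > 0 else float("nan")
    specificity = 100.0 * target_mass / genome_mass if genome_mass > 0 else 0.0

    return CaptureMetrics(
        mean_genome_coverage=mean_genome,
        mean_target_coverage=mean_target,
        enrichment_factor=enrichment,
        normalized_mean_target_coverage=normalized_coverage(
            mean_target, stats, genome_index),
        fraction_target_covered=100.0 * covered_ge1 / target_len,
        fraction_target_ge_k=100.0 * covered_gek / target_len,
        specificity=specificity,
        genome_fraction_ge_k=100.0 * track.bases_with_depth_ge(kk) / G,
        k=k,
    )


def metrics_table(metrics_by_genotype: Mapping[str, CaptureMetrics]) -> pd.DataFrame:
    """One QC column per genotype, rows are metric names."""
    return pd.DataFrame({g: m.to_series() for g, m in metrics_by_genotype.items()})
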