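"""Copy-number and presence/absence variation calling from coverage ratios.

For every target gene copy (locus) and genotype, the locus's normalized
coverage c_g (length-weighted over the copy's full span, in units of the
genotype's expected genome-wide mean depth; see :mod:`polycap.capture_qc`)
is compared to a panel reference c_bar, the arithmetic mean of the locus's
normalized coverage across genotypes.  The ratio r = c_g / c_bar is
classified with fixed thresholds:

    r <  0.05        -> absent  (presence/absence variation)
    0.05 <= r < 0.5  -> loss
    r >  1.5         -> gain
    otherwise        -> normal

Thresholds are strict inequalities ("smaller than 0.5", "higher than
1.5"); a ratio exactly at a threshold is normal.  Absence is treated as
the extreme of the same ratio and checked first.

The panel reference comes in two flavours.  ``loo=False`` averages over
all genotypes including the focal one; in a small panel a genuine event
then dilutes its own reference (a half-dose locus in a 4-genotype panel
has ratio 0.5/0.875 ~ 0.57 and is missed).  ``loo=True`` (leave-one-out)
averages over the other genotypes only.  The default enables LOO for
panels of up to 6 genotypes.

Loci at which a genotype shows heterozygous SNPs are excluded from calling
for that genotype: in a fully inbred line a heterozygous call means reads
from multiple homoeologous loci are collapsing onto one position, so the
depth there does not measure the dosage of a single locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .capture_qc import AlignmentStats, normalized_coverage
from .formats_io import CoverageTrack, GenomeIndex, TargetRegion, ValidationError

STATES = ("normal", "gain", "loss", "absent")


@dataclass(frozen=True)
class CnvThresholds:
    """Ratio thresholds for gain / loss / absence calls."""

    gain: float = 1.5
    loss: float = 0.5
    absent: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.absent < self.loss < 1 < self.gain):
            raise ValidationError(
                f"need 0 < absent < loss < 1 < gain, got "
                f"({self.absent}, {self.loss}, {self.gain})")

    def classify(self, ratio: float) -> str:
        if ratio < self.absent:
            return "absent"
        if ratio < self.loss:
            return "loss"
        if ratio > self.gain:
            return "gain"
        return "normal"


def locus_normalized_matrix(tracks: Mapping[str, CoverageTrack],
                            targets: Sequence[TargetRegion],
                            stats: Mapping[str, AlignmentStats],
                            genome_index: GenomeIndex) -> pd.DataFrame:
    """Matrix of length-weighted mean normalized coverage, copy_id x genotype.

    Each entry is the mean normalized coverage over the copy's full span
    (all of its regions, uncovered bases counting as depth 0), which removes
    library-size differences between genotypes.
    """
    if len(tracks) < 2:
        raise ValidationError("need at least 2 genotypes for a panel matrix")
    missing = [g for g in tracks if g not in stats]
    if missing:
        raise ValidationError(f"missing alignment stats for genotype(s): {missing}")

    by_copy: dict[str, list[TargetRegion]] = {}
    for r in targets:
        if not genome_index.contains_interval(r.chrom, r.start, r.end):
            raise ValidationError(
                f"target {r.copy_id} ({r.chrom}:{r.start}-{r.end}) outside genome")
        by_copy.setdefault(r.copy_id, []).append(r)

    rows = {}
    for copy_id, regions in by_copy.items():
        length = sum(r.length for r in regions)
        row = {}
        for genotype, track in tracks.items():
            mass = sum(track.region_mass(r.chrom, r.start, r.end) for r in regions)
            row[genotype] = normalized_coverage(
                mass / length, stats[genotype], genome_index)
        rows[copy_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=list(tracks))
    matrix.index.name = "copy_id"
    return matrix


def call_cnv(matrix: pd.DataFrame,
             thresholds: CnvThresholds | None = None,
             het_snp_loci: Mapping[str, set] | None = None,
             loo: bool | None = None) -> pd.DataFrame:
    """Classify every locus x genotype cell of a normalized coverage matrix.

    Parameters
    ----------
    matrix
        copy_id x genotype normalized coverage (from
        :func:`locus_normalized_matrix`).
    thresholds
        Ratio thresholds; defaults to 1.5 / 0.5 / 0.05.
    het_snp_loci
        Optional per-genotype sets of copy_ids at which heterozygous SNPs
        were observed; those cells are excluded from calling.
    loo
        Use the leave-one-out panel mean as reference.  Default: True for
        panels of <= 6 genotypes.

    Returns
    -------
    DataFrame with columns copy_id, genotype, coverage, reference, ratio,
    state, excluded, reason.  Excluded cells carry no state (NA).
    """
    thresholds = thresholds or CnvThresholds()
    het_snp_loci = het_snp_loci or {}
    genotypes = list(matrix.columns)
    n = len(genotypes)
    if n < 2:
        raise ValidationError(
            "CNV calling needs a panel of >= 2 genotypes: the ratio against a "
            "self-only mean is undefined")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValidationError("coverage matrix must be finite and nonnegative")
    if loo is None:
        loo = n <= 6

    out = []
    row_sums = values.sum(axis=1)
    for i, copy_id in enumerate(matrix.index):
        for j, genotype in enumerate(genotypes):
            c = values[i, j]
            if loo:
                ref = (row_sums[i] - c) / (n - 1)
            else:
                ref = row_sums[i] / n
            excluded = False
            reason = ""
            state: str | None = None
            ratio: float = float("nan")
            if copy_id in het_snp_loci.get(genotype, ()):
                excluded = True
                reason = "heterozygous SNPs at locus"
            elif ref == 0:
                excluded = True
                reason = "no panel coverage"
            else:
                ratio = c / ref
                state = thresholds.classify(ratio)
            out.append({
                "copy_id": copy_id, "genotype": genotype, "coverage": c,
                "reference": ref, "ratio": ratio, "state": state,
                "excluded": excluded, "reason": reason})
    return pd.DataFrame(out)


def event_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Convenience view: only non-normal, non-excluded calls."""
    return calls[(~calls["excluded"]) & (calls["state"] != "normal")].reset_index(
        drop=True)
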