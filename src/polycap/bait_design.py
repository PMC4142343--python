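"""Tiling of 120-mer hybridization-capture baits over target sequences.

Baits are placed at 1x tiling frequency: end-to-end, non-overlapping,
within each contiguous run of unmasked sequence (repeats are marked by
lowercase letters or N; both soft and hard masking are honoured).  A run
shorter than the bait length yields no bait.  When a run leaves an
uncovered tail, a final bait anchored at the run's end is added only if
its overlap with the previously placed bait does not exceed the
overlap-avoidance limit (default 20 bp); otherwise the tail stays
uncovered.  The exact terminal-window behaviour of commercial design
tools is proprietary; this rule is declared, not claimed identical.

Strand rule: baits for plus-strand genes are synthesized antisense, baits
for minus-strand genes in sense — in both cases the emitted oligo is the
reverse complement of the plus-strand genomic window; only the recorded
synthesis strand differs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .formats_io import ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_UNMASKED_RUN = re.compile(r"[ACGT]+")


@dataclass(frozen=True)
class BaitParams:
    bait_length: int = 120
    tiling_frequency: int = 1
    avoid_overlap: int = 20   # max bp a terminal rescue bait may overlap
    avoid_masked: bool = True

    def __post_init__(self) -> None:
        if self.bait_length <= 0:
            raise ValidationError("bait_length must be > 0")
        if self.avoid_overlap < 0:
            raise ValidationError("avoid_overlap must be >= 0")
        if self.tiling_frequency != 1:
            raise ValidationError("only 1x tiling is supported")


@dataclass(frozen=True)
class Bait:
    copy_id: str
    start: int          # 0-based offset on the source sequence
    sequence: str       # the synthesized oligo (see strand rule)
    strand: str         # "sense" or "antisense" relative to the gene

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValidationError(f"bad bait strand {self.strand!r}")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _runs(seq: str, avoid_masked: bool) -> Iterator[tuple[int, int]]:
    if avoid_masked:
        for m in _UNMASKED_RUN.finditer(seq):
            yield m.span()
    else:
        # masking ignored: any non-N base is usable
        for m in re.finditer(r"[ACGTacgt]+", seq):
            yield m.span()


def tile_baits(sequence: str, gene_strand: str,
               params: BaitParams | None = None, copy_id: str = "") -> list[Bait]:
    """Tile baits over one target sequence.

    ``sequence`` is the plus-strand genomic sequence with repeats soft-
    (lowercase) or hard- (N) masked; ``gene_strand`` is the strand the gene
    is annotated on.  Short or fully masked input yields an empty list.
    """
    params = params or BaitParams()
    if gene_strand not in ("+", "-"):
        raise ValidationError(f"bad gene strand {gene_strand!r}")
    L = params.bait_length
    label = "antisense" if gene_strand == "+" else "sense"

    baits: list[Bait] = []
    for run_start, run_end in _runs(sequence, params.avoid_masked):
        run_len = run_end - run_start
        n_full = run_len // L
        starts = [run_start + i * L for i in range(n_full)]
        remainder = run_len - n_full * L
        if n_full >= 1 and remainder > 0 and (L - remainder) <= params.avoid_overlap:
            starts.append(run_end - L)  # terminal bait anchored to the run end
        for s in starts:
            window = sequence[s:s + L].upper()
            baits.append(Bait(copy_id=copy_id, start=s,
                              sequence=reverse_complement(window), strand=label))
    return baits


def tile_bait_library(sequences: Mapping[str, str], strands: Mapping[str, str],
                      params: BaitParams | None = None) -> list[Bait]:
    """Tile a whole FASTA's worth of targets; strands keyed like sequences."""
    baits = []
    for name, seq in sequences.items():
        if name not in strands:
            raise ValidationError(f"no strand given for target {name!r}")
        baits.extend(tile_baits(seq, strands[name], params=params, copy_id=name))
    return baits


def baits_table(baits: Sequence[Bait]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"copy_id": b.copy_id, "start": b.start, "length": len(b.sequence),
          "strand": b.strand, "sequence": b.sequence} for b in baits])
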