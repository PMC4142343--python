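"""Book-keeping of detected vs expected gene copies in an allopolyploid panel.

A copy inventory lists every detected homolog/paralog of the target genes
with its detection status (full_length / partial / not_detected), a
functionality flag (supplied as input; deciding functionality is an
upstream annotation task), and whether the copy was expected from the
progenitor genomes.  From the inventory we derive the panel statistics:
copies lost and duplicated relative to the progenitor expectation, the
non-functional fraction, and the mean functional copy number per gene.

Gene dosage ratios (e.g. activator:repressor copy counts in one genotype)
are obtained by adjusting the reference copy counts with that genotype's
CNV/PAV calls: loss -1, gain +1, absence removes the locus entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .formats_io import ValidationError

DETECTED_STATES = ("full_length", "partial", "not_detected")


@dataclass(frozen=True)
class InventoryCounts:
    """Aggregate copy counts for a gene panel."""

    n_genes: int
    n_detected: int
    n_full_length: int
    n_partial: int
    n_nonfunctional: int
    n_lost: int
    n_duplicated: int
    n_nonfunctional_duplicated: int

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_nonfunctional_duplicated > self.n_duplicated:
            raise ValidationError(
                "non-functional duplicated copies exceed duplicated copies")


@dataclass(frozen=True)
class InventorySummary:
    n_detected: int
    n_nonfunctional: int
    pct_nonfunctional: int            # nearest-integer percent
    n_lost: int
    n_duplicated: int
    n_functional_duplications: int
    mean_copies_per_gene: float       # one decimal

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_inventory(counts: InventoryCounts, n_genes: int | None = None
                        ) -> InventorySummary:
    """Panel statistics from aggregate copy counts.

    The mean copy number counts full-length plus partially captured
    functional copies per gene, to one decimal.  The non-functional
    percentage is rounded to the nearest integer.
    """
    n_genes = counts.n_genes if n_genes is None else n_genes
    if n_genes <= 0:
        raise ValidationError("n_genes must be > 0")
    if counts.n_detected <= 0:
        raise ValidationError("no detected copies")
    return InventorySummary(
        n_detected=counts.n_detected,
        n_nonfunctional=counts.n_nonfunctional,
        pct_nonfunctional=round(100 * counts.n_nonfunctional / counts.n_detected),
        n_lost=counts.n_lost,
        n_duplicated=counts.n_duplicated,
        n_functional_duplications=(counts.n_duplicated
                                   - counts.n_nonfunctional_duplicated),
        mean_copies_per_gene=round(
            (counts.n_full_length + counts.n_partial) / n_genes, 1),
    )


def tabulate_inventory(inventory: pd.DataFrame) -> InventoryCounts:
    """Aggregate a per-copy inventory table into :class:`InventoryCounts`.

    Expected columns: copy_id, gene_id, detected (one of full_length /
    partial / not_detected), functional (bool), expected_in_progenitor
    (bool).
    """
    required = {"copy_id", "gene_id", "detected", "functional",
                "expected_in_progenitor"}
    missing = required - set(inventory.columns)
    if missing:
        raise ValidationError(f"inventory missing columns: {sorted(missing)}")
    bad = set(inventory["detected"]) - set(DETECTED_STATES)
    if bad:
        raise ValidationError(f"bad detection states: {sorted(bad)}")
    if inventory["copy_id"].duplicated().any():
        raise ValidationError("duplicate copy_id in inventory")

    detected = inventory[inventory["detected"] != "not_detected"]
    # a copy that was not detected has no meaningful functionality flag
    nonfunctional = detected[~detected["functional"].astype(bool)]
    duplicated = detected[~detected["expected_in_progenitor"].astype(bool)]
    lost = inventory[(inventory["detected"] == "not_detected")
                     & inventory["expected_in_progenitor"].astype(bool)]
    functional = detected[detected["functional"].astype(bool)]
    return InventoryCounts(
        n_genes=inventory["gene_id"].nunique(),
        n_detected=len(detected),
        n_full_length=len(functional[functional["detected"] == "full_length"]),
        n_partial=len(functional[functional["detected"] == "partial"]),
        n_nonfunctional=len(nonfunctional),
        n_lost=len(lost),
        n_duplicated=len(duplicated),
        n_nonfunctional_duplicated=len(
            duplicated[~duplicated["functional"].astype(bool)]),
    )


def dosage_ratio(inventory: pd.DataFrame, genotype: str, gene_a: str,
                 gene_b: str, calls: pd.DataFrame | None = None
                 ) -> tuple[int, int]:
    """Copy-count ratio (gene_a : gene_b) in one genotype after CNV/PAV calls.

    Reference copy number is one per detected copy in the inventory (or an
    explicit ``ref_copies`` column).  Calls adjust it: loss -1, gain +1,
    absent removes all reference copies at the locus.  An adjustment below
    zero means the calls contradict the inventory and is an error.
    """
    counts = []
    for gene in (gene_a, gene_b):
        rows = inventory[(inventory["gene_id"] == gene)
                         & (inventory["detected"] != "not_detected")]
        if rows.empty:
            raise ValidationError(f"gene {gene!r} not present in inventory")
        ref_copies = (rows["ref_copies"].astype(int)
                      if "ref_copies" in rows.columns
                      else pd.Series(1, index=rows.index))
        by_copy = dict(zip(rows["copy_id"], ref_copies))
        total = int(sum(by_copy.values()))
        if calls is not None and len(calls):
            excl = (calls["excluded"].astype(bool) if "excluded" in calls.columns
                    else pd.Series(False, index=calls.index))
            sel = calls[(calls["genotype"] == genotype)
                        & calls["copy_id"].isin(by_copy) & ~excl]
            for _, call in sel.iterrows():
                if call["state"] == "loss":
                    total -= 1
                elif call["state"] == "gain":
                    total += 1
                elif call["state"] == "absent":
                    total -= by_copy[call["copy_id"]]
        if total < 0:
            raise ValidationError(
                f"copy count for {gene!r} in {genotype!r} adjusted below zero: "
                f"calls are inconsistent with the inventory")
        counts.append(total)
    return counts[0], counts[1]


def read_inventory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("functional", "expected_in_progenitor"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(["1", "true", "yes"])
    return df
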