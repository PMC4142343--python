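"""Zygosity and coding-consequence classification of filtered SNPs.

Zygosity in a fully inbred line
-------------------------------
The genotype panel consists of lines selfed to at least S5, so residual
heterozygosity is negligible and an apparently heterozygous call is
interpreted as a *hemi-SNP*: reads from two divergent homoeologous or
paralogous loci collapsing onto one mapped position.  Homozygous-alt calls
are genuine locus-specific SNPs.  For samples not declared inbred the hemi
interpretation is withheld and heterozygous calls are reported as
``heterozygous_unresolved``.  Only homozygous SNPs feed downstream
functional (amino-acid) analysis.

Coding consequence
------------------
A variant inside a CDS exon is mapped to its codon, the codon is
translated with the standard nuclear genetic code before and after the
substitution (minus-strand genes are handled on the coding strand), and
the SNP is classified synonymous or non-synonymous.  CDS sequences whose
length is not a multiple of three yield ``not_applicable`` with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .formats_io import (
    TargetRegion,
    ValidationError,
    VariantRecord,
    read_fasta,
    read_gff3,
)

LOCATIONS = ("exon", "intron", "promoter", "intergenic")
CONSEQUENCES = ("synonymous", "non_synonymous", "not_applicable")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def classify_zygosity(record: VariantRecord, sample: str | None = None,
                      inbred: bool = True) -> str | None:
    """Classify one genotype call as homozygous SNP, hemi-SNP, or no SNP.

    Returns ``"homozygous"`` for hom-alt calls, ``"hemi"`` for heterozygous
    calls in inbred material (``"heterozygous_unresolved"`` otherwise), and
    ``None`` for hom-ref / missing calls, which are not SNPs in this sample.
    """
    call = record.call(sample)
    if call == "hom_alt":
        return "homozygous"
    if call == "het":
        return "hemi" if inbred else "heterozygous_unresolved"
    return None


@dataclass(frozen=True)
class SnpEffect:
    copy_id: str
    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str
    location: str
    consequence: str = "not_applicable"
    aa_ref: str = ""
    aa_alt: str = ""
    codon_position: int = 0  # 1..3 within the codon, 0 if not coding
    reason: str = ""

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValidationError(f"bad location {self.location!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(f"bad consequence {self.consequence!r}")
        if self.consequence != "not_applicable" and self.location != "exon":
            raise ValidationError("coding consequence outside an exon")


@dataclass(frozen=True)
class CdsModel:
    """A gene copy's CDS: genomic exons plus the coding-strand sequence."""

    copy_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, sorted
    cds: str                            # coding strand, 5'->3'
    promoter: tuple[int, int] | None = None  # genomic interval, optional
    gene_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand for {self.copy_id}")
        exon_len = sum(e - s for s, e in self.exons)
        if exon_len != len(self.cds):
            raise ValidationError(
                f"{self.copy_id}: CDS length {len(self.cds)} != exon span {exon_len}")
        bad = set(self.cds.upper()) - set("ACGT")
        if bad:
            raise ValidationError(
                f"{self.copy_id}: ambiguity codes in CDS: {sorted(bad)}")

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a 1-based genomic position to a 0-based coding index, or None."""
        pos0 = pos - 1
        offset = 0
        for s, e in self.exons:
            if s <= pos0 < e:
                within = pos0 - s
                if self.strand == "+":
                    return offset + within
                # minus strand: coding order runs from the last exon backwards
                preceding = sum(ee - ss for ss, ee in self.exons if ss > s)
                return preceding + (e - 1 - pos0)
            offset += e - s
        return None


def substitution_effect(cds: str, cds_index: int, alt_base: str) -> tuple[str, str, str, int]:
    """Effect of a single-base substitution at a 0-based coding index.

    Returns (aa_ref, aa_alt, consequence, codon_position 1..3).
    """
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    if not 0 <= cds_index < len(cds):
        raise ValidationError("coding index out of range")
    alt_base = alt_base.upper()
    if alt_base not in "ACGT":
        raise ValidationError(f"bad alt base {alt_base!r}")
    codon_start = (cds_index // 3) * 3
    codon = cds[codon_start:codon_start + 3].upper()
    within = cds_index - codon_start
    alt_codon = codon[:within] + alt_base + codon[within + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    consequence = "synonymous" if aa_ref == aa_alt else "non_synonymous"
    return aa_ref, aa_alt, consequence, within + 1


def classify_effect(model: CdsModel, variant: VariantRecord) -> SnpEffect:
    """Classify a variant's location and coding consequence for one gene copy.

    The variant's ref/alt are on the genomic plus strand; for minus-strand
    genes they are complemented onto the coding strand before translation.
    """
    base = dict(copy_id=model.copy_id, chrom=variant.chrom, pos=variant.pos,
                ref=variant.ref, alt=variant.alt)
    pos0 = variant.pos - 1
    if model.promoter and model.promoter[0] <= pos0 < model.promoter[1]:
        return SnpEffect(location="promoter", **base)

    cds_index = model.genomic_to_cds(variant.pos)
    if cds_index is None:
        span = model.gene_span
        if span and span[0] <= pos0 < span[1]:
            return SnpEffect(location="intron", **base)
        return SnpEffect(location="intergenic", **base)

    if len(model.cds) % 3 != 0:
        return SnpEffect(location="exon",
                         reason=f"CDS length {len(model.cds)} not divisible by 3",
                         **base)
    alt = variant.alt if model.strand == "+" else variant.alt.translate(_COMPLEMENT)
    ref = variant.ref if model.strand == "+" else variant.ref.translate(_COMPLEMENT)
    if model.cds[cds_index].upper() != ref.upper():
        return SnpEffect(location="exon",
                         reason=(f"reference mismatch: CDS has "
                                 f"{model.cds[cds_index]!r}, VCF ref maps to {ref!r}"),
                         **base)
    aa_ref, aa_alt, consequence, codon_pos = substitution_effect(
        model.cds, cds_index, alt)
    return SnpEffect(location="exon", consequence=consequence, aa_ref=aa_ref,
                     aa_alt=aa_alt, codon_position=codon_pos, **base)


def cds_models_from_gff(gff_path: str | Path, cds_fasta: str | Path) -> list[CdsModel]:
    """Build CDS models from a GFF3 with gene/CDS (and optional promoter) rows.

    CDS feature IDs (or Parents) must match the FASTA record names, which
    carry the coding-strand sequences.
    """
    seqs = read_fasta(cds_fasta)
    features = read_gff3(gff_path)
    genes: dict[str, dict] = {}
    for f in features:
        copy_id = f.attributes.get("ID") or f.attributes.get("Parent") or ""
        copy_id = copy_id.split(":")[0]
        entry = genes.setdefault(copy_id, {"exons": [], "promoter": None,
                                           "span": None, "chrom": f.chrom,
                                           "strand": f.strand})
        if f.ftype == "CDS":
            entry["exons"].append((f.start, f.end))
            entry["strand"] = f.strand
        elif f.ftype == "promoter":
            entry["promoter"] = (f.start, f.end)
        elif f.ftype == "gene":
            entry["span"] = (f.start, f.end)
    models = []
    for copy_id, entry in genes.items():
        if not entry["exons"] or copy_id not in seqs:
            continue
        models.append(CdsModel(
            copy_id=copy_id, chrom=entry["chrom"], strand=entry["strand"],
            exons=tuple(sorted(entry["exons"])), cds=seqs[copy_id],
            promoter=entry["promoter"], gene_span=entry["span"]))
    return models


# ---------------------------------------------------------------------------
# Per-genotype summaries (counts, percentages, SNP density)
# ---------------------------------------------------------------------------


def _target_lookup(targets: Sequence[TargetRegion]):
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for r in targets:
        per_chrom.setdefault(r.chrom, []).append((r.start, r.end, r.copy_id))
    for rows in per_chrom.values():
        rows.sort()

    def lookup(chrom: str, pos: int) -> str | None:
        pos0 = pos - 1
        for s, e, copy_id in per_chrom.get(chrom, ()):
            if s <= pos0 < e:
                return copy_id
            if s > pos0:
                break
        return None

    return lookup


def assign_to_targets(records: Iterable[VariantRecord],
                      targets: Sequence[TargetRegion]) -> list[str | None]:
    """copy_id containing each record's position, or None if off target."""
    lookup = _target_lookup(targets)
    return [lookup(rec.chrom, rec.pos) for rec in records]


def het_loci_by_genotype(records_by_genotype: Mapping[str, Sequence[VariantRecord]],
                         targets: Sequence[TargetRegion],
                         inbred: Mapping[str, bool] | None = None,
                         ) -> dict[str, set[str]]:
    """Copy ids with >= 1 heterozygous SNP, per genotype (CNV exclusion set)."""
    lookup = _target_lookup(targets)
    out: dict[str, set[str]] = {}
    for genotype, records in records_by_genotype.items():
        loci = set()
        for rec in records:
            if rec.call() == "het":
                copy_id = lookup(rec.chrom, rec.pos)
                if copy_id is not None:
                    loci.add(copy_id)
        out[genotype] = loci
    return out


@dataclass
class SnpSummary:
    """Panel SNP summary: per-genotype counts plus panel-wide totals."""

    table: pd.DataFrame
    panel_total: int
    panel_target_total: int
    target_length: int
    density_bp_per_snp: float | None  # bp of target per target SNP (rounded)

    def __post_init__(self) -> None:
        t = self.table
        if ((t["total_hom"] + t["total_het"]) > t["total"]).any():
            raise ValidationError("hom + het exceeds total SNP count")


def summarize_snps(records_by_genotype: Mapping[str, Sequence[VariantRecord]],
                   targets: Sequence[TargetRegion],
                   target_length: int,
                   inbred: Mapping[str, bool] | None = None,
                   panel_total: int | None = None,
                   panel_target_total: int | None = None,
                   per_genotype_denominator: bool = False) -> SnpSummary:
    """Count SNPs per genotype and express them against panel-wide totals.

    Percentages use the panel-wide SNP totals as denominator (the survey
    convention for this kind of table); set ``per_genotype_denominator`` to
    divide by each genotype's own total instead.  Panel totals default to
    the number of distinct variants (chrom, pos, ref, alt) observed across
    the panel but can be given explicitly.  SNP density is reported as bp
    of target per target SNP, rounded to the nearest integer, or None when
    there are no target SNPs.
    """
    inbred = inbred or {}
    lookup = _target_lookup(targets)
    rows = {}
    panel_keys: set[tuple] = set()
    panel_target_keys: set[tuple] = set()
    for genotype, records in records_by_genotype.items():
        counts = dict(total=0, total_hom=0, total_het=0,
                      target=0, target_hom=0, target_het=0)
        for rec in records:
            zyg = classify_zygosity(rec, inbred=inbred.get(genotype, True))
            if zyg is None:
                continue
            key = (rec.chrom, rec.pos, rec.ref, rec.alt)
            panel_keys.add(key)
            on_target = lookup(rec.chrom, rec.pos) is not None
            counts["total"] += 1
            if on_target:
                panel_target_keys.add(key)
                counts["target"] += 1
            if zyg == "homozygous":
                counts["total_hom"] += 1
                counts["target_hom"] += on_target
            else:
                counts["total_het"] += 1
                counts["target_het"] += on_target
        rows[genotype] = counts

    count_cols = ["total", "total_hom", "total_het",
                  "target", "target_hom", "target_het"]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=count_cols)
    if table.empty:
        table = pd.DataFrame(columns=count_cols, dtype=int)
    table.index.name = "genotype"
    if panel_total is None:
        panel_total = len(panel_keys)
    if panel_target_total is None:
        panel_target_total = len(panel_target_keys)

    def pct(count_col: str, denom_col: str, panel_denom: int) -> pd.Series:
        if per_genotype_denominator:
            denom = table[denom_col].replace(0, pd.NA)
            return (100.0 * table[count_col] / denom).astype(float)
        if panel_denom == 0:
            return pd.Series(0.0, index=table.index)
        return 100.0 * table[count_col] / panel_denom

    table["total_hom_pct"] = pct("total_hom", "total", panel_total).round(2)
    table["total_het_pct"] = pct("total_het", "total", panel_total).round(2)
    table["target_hom_pct"] = pct("target_hom", "target", panel_target_total).round(2)
    table["target_het_pct"] = pct("target_het", "target", panel_target_total).round(2)

    density = (round(target_length / panel_target_total)
               if panel_target_total > 0 else None)
    return SnpSummary(table=table, panel_total=int(panel_total),
                      panel_target_total=int(panel_target_total),
                      target_length=int(target_length),
                      density_bp_per_snp=density)


def zygosity_percentages(counts: pd.DataFrame, panel_total: int,
                         panel_target_total: int) -> pd.DataFrame:
    """Percentage view of a per-genotype zygosity count table.

    Each count is expressed against the *panel-wide* SNP total (total or
    on-target), the convention under which the same SNP class can be
    compared across genotypes of one survey.  Expects the count columns of
    :class:`SnpSummary` tables; returns percentages rounded to 2 decimals.
    """
    if panel_total <= 0 or panel_target_total <= 0:
        raise ValidationError("panel totals must be positive")
    out = pd.DataFrame(index=counts.index)
    for col in ("total_hom", "total_het"):
        out[f"{col}_pct"] = (100.0 * counts[col] / panel_total).round(2)
    for col in ("target_hom", "target_het"):
        out[f"{col}_pct"] = (100.0 * counts[col] / panel_target_total).round(2)
    return out


def annotate_panel(records_by_genotype: Mapping[str, Sequence[VariantRecord]],
                   targets: Sequence[TargetRegion],
                   models: Sequence[CdsModel],
                   inbred: Mapping[str, bool] | None = None) -> pd.DataFrame:
    """Full per-SNP annotation table across a genotype panel.

    One row per (genotype, variant): target copy, zygosity class, location
    and coding consequence (computed for homozygous exonic SNPs; hemi-SNPs
    are collapsed multi-locus signals and get no amino-acid call).
    """
    inbred = inbred or {}
    lookup = _target_lookup(targets)
    by_copy = {m.copy_id: m for m in models}
    rows = []
    for genotype, records in records_by_genotype.items():
        for rec in records:
            zyg = classify_zygosity(rec, inbred=inbred.get(genotype, True))
            if zyg is None:
                continue
            copy_id = lookup(rec.chrom, rec.pos)
            location = "intergenic"
            consequence = "not_applicable"
            aa_ref = aa_alt = ""
            reason = ""
            if copy_id is not None and copy_id in by_copy:
                effect = classify_effect(by_copy[copy_id], rec)
                location = effect.location
                if zyg == "homozygous":
                    consequence = effect.consequence
                    aa_ref, aa_alt = effect.aa_ref, effect.aa_alt
                    reason = effect.reason
                else:
                    reason = "multi-locus signal: no single-copy amino-acid call"
            rows.append({
                "genotype": genotype, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alt, "depth": rec.depth,
                "copy_id": copy_id or "", "zygosity": zyg, "location": location,
                "consequence": consequence, "aa_ref": aa_ref, "aa_alt": aa_alt,
                "reason": reason})
    return pd.DataFrame(rows)
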