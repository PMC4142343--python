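"""Simulation of an allopolyploid targeted-capture experiment.

The generator emulates the statistical structure a ratio-based CNV/PAV and
hemi-SNP analysis assumes, without simulating reads or mapping:

* a multi-gene target set with homoeologous copies on an A and a C
  subgenome, each copy a promoter plus a single-exon CDS;
* per-genotype depth tracks in which a locus with copy-number multiplier m
  has expected depth m * E * mu (E the capture enrichment factor, mu the
  genotype's background mean depth), with negative-binomial noise per
  constant-depth segment to mimic capture variability, and off-target
  depth at mu;
* locus-specific homozygous SNPs, and cross-locus divergent sites between
  homoeolog pairs that surface as heterozygous "hemi-SNPs" wherever both
  partners are captured.

Hemi-SNP convention: each divergent site is anchored at the A-subgenome
("primary") copy, where the collapsed read pile accumulates.  A genotype
carrying both partners gets a heterozygous call there; a genotype lacking
the primary but carrying the partner gets a homozygous-alt call (the pile
consists of partner reads only); a genotype lacking the partner gets no
call.  Depth tracks represent uniquely-mapped coverage (an absent locus
has depth 0) while the variant DP reflects the collapsed pile.

Everything is driven by one :class:`numpy.random.Generator`; identical
seeds give identical in-memory objects and bitwise-identical output files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .capture_qc import AlignmentStats
from .formats_io import (
    CoverageTrack,
    GeneModelFeature,
    GenomeIndex,
    TargetRegion,
    ValidationError,
    VariantRecord,
    write_bedgraph,
    write_fasta,
    write_genome_index,
    write_gff3,
    write_targets_bed,
    write_vcf,
)
from .snp_annotate import CdsModel

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in _STOPS]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Study design of one simulated capture experiment.

    Defaults describe a scaled-down version of a four-genotype capture
    panel: 100 bp single reads, an enrichment factor of 760x, a
    negative-binomial background depth with mean 0.5 and dispersion 0.1,
    and ~97% inter-homoeolog identity.  ``events`` maps genotype ->
    copy_id -> copy-number multiplier (0 absent, 0.5 loss, 1 normal,
    1.5/2 gain).
    """

    n_genes: int = 8
    copies_per_subgenome: int = 2
    cds_length: int = 900
    promoter_length: int = 300
    inter_homoeolog_identity: float = 0.97
    genome_length: int = 8_000_000
    read_length: int = 100
    enrichment_factor: float = 760.0
    background_mean: float = 0.5
    background_dispersion: float = 0.1
    genotypes: tuple[str, ...] = ("geno1", "geno2", "geno3", "geno4")
    library_scale: dict = field(default_factory=dict)   # genotype -> factor
    inbred: dict = field(default_factory=dict)          # genotype -> bool
    events: dict = field(default_factory=dict)          # genotype -> {copy: m}
    snp_rate: float = 0.002          # locus-specific hom SNPs per bp per genotype
    hemi_site_rate: float = 0.005    # cross-locus divergent sites per bp per pair
    cross_mapping_bleed: float = 0.0  # fraction of partner depth bleeding into
    segment_length: int = 60          # an absent locus (0 = unique mapping only)
    background_window: int = 0        # bp; 0 = no explicit off-target segments
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.inter_homoeolog_identity <= 1):
            raise ValidationError("inter_homoeolog_identity must be in (0, 1]")
        if self.cds_length % 3:
            raise ValidationError("cds_length must be a multiple of 3")
        for rate in (self.snp_rate, self.hemi_site_rate, self.cross_mapping_bleed):
            if rate < 0:
                raise ValidationError("rates must be >= 0")
        for per_copy in self.events.values():
            for copy_id, m in per_copy.items():
                if m < 0:
                    raise ValidationError(f"multiplier < 0 for {copy_id}")
        if len(self.genotypes) < 1:
            raise ValidationError("need at least one genotype")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "genotypes" in raw:
            raw["genotypes"] = tuple(raw["genotypes"])
        return cls(**raw)

    def multiplier(self, genotype: str, copy_id: str) -> float:
        return float(self.events.get(genotype, {}).get(copy_id, 1.0))


@dataclass
class TruthTable:
    """Ground truth emitted alongside the simulated files."""

    multipliers: pd.DataFrame          # copy_id x genotype
    snps: pd.DataFrame                 # one row per emitted genotype call

    @property
    def events(self) -> pd.DataFrame:
        stacked = self.multipliers.stack()
        ev = stacked[stacked != 1.0].reset_index()
        ev.columns = ["copy_id", "genotype", "multiplier"]
        return ev


@dataclass
class _Copy:
    copy_id: str
    gene_id: str
    subgenome: str
    chrom: str
    start: int          # 0-based genomic start of the full region
    strand: str
    seq: str            # promoter + CDS, coding orientation

    def genomic_pos(self, offset: int) -> int:
        """0-based genomic position of coding-orientation offset."""
        span = len(self.seq)
        if self.strand == "+":
            return self.start + offset
        return self.start + (span - 1 - offset)

    def genomic_base(self, offset: int) -> str:
        base = self.seq[offset]
        return base if self.strand == "+" else base.translate(_COMPLEMENT)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    genome_index: GenomeIndex
    targets: list[TargetRegion]
    cds_models: list[CdsModel]
    gff_features: list[GeneModelFeature]
    cds_seqs: dict[str, str]
    promoter_seqs: dict[str, str]
    tracks: dict[str, CoverageTrack]
    stats: dict[str, AlignmentStats]
    variants: dict[str, list[VariantRecord]]
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def _p(name: str) -> Path:
            paths[name] = outdir / name
            return paths[name]

        write_genome_index(self.genome_index, _p("genome_index.tsv"))
        write_targets_bed(self.targets, _p("targets.bed"))
        write_gff3(self.gff_features, _p("genes.gff3"))
        write_fasta(self.cds_seqs, _p("cds.fasta"))
        write_fasta(self.promoter_seqs, _p("promoters.fasta"))
        for genotype in self.config.genotypes:
            write_bedgraph(self.tracks[genotype], _p(f"{genotype}.bedgraph"))
            write_vcf(self.variants[genotype], genotype, self.genome_index,
                      _p(f"{genotype}.vcf"))
        stats = pd.DataFrame(
            [{"genotype": g, "aligned_reads": s.aligned_reads,
              "read_length": s.read_length} for g, s in self.stats.items()])
        stats.to_csv(_p("alignment_stats.tsv"), sep="\t", index=False)
        self.truth.multipliers.to_csv(_p("truth_multipliers.tsv"), sep="\t")
        self.truth.snps.to_csv(_p("truth_snps.tsv"), sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _nbinom(rng: np.random.Generator, mean: float, dispersion: float,
            size: int) -> np.ndarray:
    """NB draws with var = mean + dispersion * mean^2 (Poisson at dispersion 0)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size).astype(np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size).astype(np.int64)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=length // 3)
    return "".join(_CODONS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


_PARTNER_RE = re.compile(r"^(?P<gene>.+)\.(?P<sub>[AC])(?P<chrom>\w*)_(?P<idx>\d+)$")


def homoeolog_partner(copy_id: str, known_ids: Sequence[str]) -> str | None:
    """The copy on the other subgenome with the same gene and copy index."""
    m = _PARTNER_RE.match(copy_id)
    if not m:
        return None
    other = "C" if m.group("sub") == "A" else "A"
    prefix = f"{m.group('gene')}.{other}"
    suffix = f"_{m.group('idx')}"
    for cand in known_ids:
        if cand.startswith(prefix) and cand.endswith(suffix):
            return cand
    return None


def add_replacement_event(config: SimulationConfig, genotype: str,
                          lost_copy_id: str, known_ids: Sequence[str]) -> None:
    """Model a homoeologous replacement: one copy lost, its partner doubled."""
    partner = homoeolog_partner(lost_copy_id, known_ids)
    if partner is None:
        raise ValidationError(
            f"replacement event requested for {lost_copy_id!r}, which has no "
            f"homoeolog partner in the target set")
    per = config.events.setdefault(genotype, {})
    per[lost_copy_id] = 0.0
    per[partner] = per.get(partner, 1.0) + 1.0


def inject_hemi_snps(primary_seq: str, partner_seq: str, rate: float,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[str, list[tuple[int, str, str]]]:
    """Plant cross-locus divergent sites between two aligned homoeologs.

    Positions are drawn at ``rate`` per bp; at each chosen position the
    partner sequence is forced to differ from the primary.  Returns the
    modified partner sequence and the site list (offset, primary base,
    partner base).  A rate above 0.5 is allowed but flagged as an
    unrealistically low inter-homoeolog identity.
    """
    if len(primary_seq) != len(partner_seq):
        raise ValidationError("homoeolog pair must have aligned, equal lengths")
    if rate > 0.5:
        log.warning("hemi-site rate %.2f implies <50%% identity between "
                    "homoeologs; this is unrealistic", rate)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rate <= 0:
        return partner_seq, []
    arr = np.array(list(partner_seq))
    sites: list[tuple[int, str, str]] = []
    for offset in np.flatnonzero(rng.random(len(arr)) < rate):
        primary_base = primary_seq[offset]
        if arr[offset] == primary_base:
            choices = [b for b in "ACGT" if b != primary_base]
            arr[offset] = choices[rng.integers(0, 3)]
        sites.append((int(offset), primary_base, str(arr[offset])))
    return "".join(arr), sites


def _consequence(cds: str, cds_index: int, alt_base: str) -> str:
    codon_start = (cds_index // 3) * 3
    codon = cds[codon_start:codon_start + 3]
    alt_codon = (codon[:cds_index - codon_start] + alt_base
                 + codon[cds_index - codon_start + 1:])
    return ("synonymous" if Seq(codon).translate() == Seq(alt_codon).translate()
            else "non_synonymous")


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a full simulated capture experiment from a config."""
    rng = np.random.default_rng(config.seed)
    P, L = config.promoter_length, config.cds_length
    span = P + L
    gap = 2000

    # --- target copies with sequences -------------------------------------
    copies: list[_Copy] = []
    cursors = {"chrA01": gap, "chrC01": gap}
    chrom_for = {"A": "chrA01", "C": "chrC01"}
    per_copy_rate = (1 - config.inter_homoeolog_identity) / 2
    gene_ids = [f"Bna.G{i + 1:02d}" for i in range(config.n_genes)]

    for gene_id in gene_ids:
        ancestral = _random_seq(rng, P) + _random_cds(rng, L)
        for ci in range(1, config.copies_per_subgenome + 1):
            for sub in ("A", "C"):
                chrom = chrom_for[sub]
                seq = _mutate(rng, ancestral, per_copy_rate)
                copies.append(_Copy(
                    copy_id=f"{gene_id}.{sub}01_{ci}", gene_id=gene_id,
                    subgenome=sub, chrom=chrom, start=cursors[chrom],
                    strand="+" if ci % 2 == 1 else "-", seq=seq))
                cursors[chrom] += span + gap

    by_id = {c.copy_id: c for c in copies}

    # --- cross-locus divergent (hemi) sites per homoeolog pair -------------
    hemi_sites: dict[str, list[tuple[int, str, str]]] = {}  # primary copy id
    occupied: dict[str, set[int]] = {c.copy_id: set() for c in copies}
    for c in copies:
        if c.subgenome != "A":
            continue
        partner_id = homoeolog_partner(c.copy_id, list(by_id))
        if partner_id is None:
            continue
        partner = by_id[partner_id]
        new_seq, sites = inject_hemi_snps(c.seq, partner.seq,
                                          config.hemi_site_rate, rng)
        partner.seq = new_seq
        hemi_sites[c.copy_id] = sites
        for offset, _, _ in sites:
            occupied[c.copy_id].add(offset)
            occupied[partner_id].add(offset)

    # --- genome index, targets, gene models --------------------------------
    placed = {chrom: cursor for chrom, cursor in cursors.items()}
    background_len = config.genome_length - sum(placed.values())
    if background_len <= 0:
        raise ValidationError(
            f"genome_length {config.genome_length} does not exceed the "
            f"placed target layout ({sum(placed.values())} bp)")
    lengths = dict(placed)
    lengths["chrBg01"] = background_len
    genome_index = GenomeIndex(lengths)

    targets: list[TargetRegion] = []
    gff: list[GeneModelFeature] = []
    cds_models: list[CdsModel] = []
    cds_seqs: dict[str, str] = {}
    promoter_seqs: dict[str, str] = {}
    for c in copies:
        end = c.start + span
        targets.append(TargetRegion(
            chrom=c.chrom, start=c.start, end=end, copy_id=c.copy_id,
            gene_id=c.gene_id, subgenome=c.subgenome, strand=c.strand))
        if c.strand == "+":
            promoter_iv = (c.start, c.start + P)
            cds_iv = (c.start + P, end)
        else:
            cds_iv = (c.start, c.start + L)
            promoter_iv = (c.start + L, end)
        gff.append(GeneModelFeature(c.chrom, "polycap_sim", "gene", c.start, end,
                                    c.strand, {"ID": c.copy_id}))
        gff.append(GeneModelFeature(c.chrom, "polycap_sim", "promoter",
                                    promoter_iv[0], promoter_iv[1], c.strand,
                                    {"Parent": c.copy_id}))
        gff.append(GeneModelFeature(c.chrom, "polycap_sim", "CDS", cds_iv[0],
                                    cds_iv[1], c.strand, {"Parent": c.copy_id},
                                    phase="0"))
        cds_seqs[c.copy_id] = c.seq[P:]
        promoter_seqs[c.copy_id] = c.seq[:P]
        cds_models.append(CdsModel(
            copy_id=c.copy_id, chrom=c.chrom, strand=c.strand,
            exons=(cds_iv,), cds=c.seq[P:], promoter=promoter_iv,
            gene_span=(c.start, end)))

    # --- per-genotype depth tracks -----------------------------------------
    G = genome_index.total_length
    E = config.enrichment_factor
    tracks: dict[str, CoverageTrack] = {}
    stats: dict[str, AlignmentStats] = {}
    for genotype in config.genotypes:
        mu = config.background_mean * float(config.library_scale.get(genotype, 1.0))
        stats[genotype] = AlignmentStats(
            aligned_reads=int(round(mu * G / config.read_length)),
            read_length=config.read_length)
        segments: list[tuple[str, int, int, int]] = []
        for c in copies:
            m = config.multiplier(genotype, c.copy_id)
            partner_id = homoeolog_partner(c.copy_id, list(by_id))
            lam = m * E * mu
            if m == 0 and config.cross_mapping_bleed > 0 and partner_id:
                pm = config.multiplier(genotype, partner_id)
                lam = config.cross_mapping_bleed * pm * E * mu
            if lam <= 0:
                continue
            edges = list(range(c.start, c.start + span, config.segment_length))
            edges.append(c.start + span)
            depths = _nbinom(rng, lam, config.background_dispersion,
                             len(edges) - 1)
            segments.extend((c.chrom, edges[i], edges[i + 1], int(depths[i]))
                            for i in range(len(edges) - 1))
        if config.background_window > 0:
            w = config.background_window
            target_ivals: dict[str, list[tuple[int, int]]] = {}
            for c in copies:
                target_ivals.setdefault(c.chrom, []).append(
                    (c.start, c.start + span))
            for chrom, length in genome_index.lengths.items():
                # off-target intervals: the complement of the target layout
                free: list[tuple[int, int]] = []
                cursor = 0
                for s, e in sorted(target_ivals.get(chrom, [])):
                    if s > cursor:
                        free.append((cursor, s))
                    cursor = e
                if cursor < length:
                    free.append((cursor, length))
                for fs, fe in free:
                    edges = np.arange(fs, fe, w, dtype=np.int64)
                    edges = np.append(edges, fe)
                    depths = _nbinom(rng, mu, config.background_dispersion,
                                     len(edges) - 1)
                    nz = np.flatnonzero(depths)
                    segments.extend((chrom, int(edges[i]), int(edges[i + 1]),
                                     int(depths[i])) for i in nz)
        tracks[genotype] = CoverageTrack(segments)

    # --- variants ----------------------------------------------------------
    variants: dict[str, list[VariantRecord]] = {}
    truth_rows: list[dict] = []
    for genotype in config.genotypes:
        mu = config.background_mean * float(config.library_scale.get(genotype, 1.0))
        records: list[VariantRecord] = []

        # locus-specific homozygous SNPs
        if config.snp_rate > 0:
            for c in copies:
                m = config.multiplier(genotype, c.copy_id)
                if m == 0:
                    continue
                for offset in np.flatnonzero(rng.random(span) < config.snp_rate):
                    offset = int(offset)
                    if offset in occupied[c.copy_id]:
                        continue
                    ref_c = c.seq[offset]
                    alt_c = [b for b in "ACGT" if b != ref_c][rng.integers(0, 3)]
                    depth = int(_nbinom(rng, m * E * mu,
                                        config.background_dispersion, 1)[0])
                    pos = c.genomic_pos(offset) + 1
                    ref_g = ref_c if c.strand == "+" else ref_c.translate(_COMPLEMENT)
                    alt_g = alt_c if c.strand == "+" else alt_c.translate(_COMPLEMENT)
                    records.append(VariantRecord(
                        chrom=c.chrom, pos=pos, ref=ref_g, alt=alt_g,
                        calls={genotype: "hom_alt"}, depth=depth))
                    location = "promoter" if offset < P else "exon"
                    consequence = (_consequence(c.seq[P:], offset - P, alt_c)
                                   if location == "exon" else "not_applicable")
                    truth_rows.append(dict(
                        genotype=genotype, chrom=c.chrom, pos=pos,
                        copy_id=c.copy_id, ref=ref_g, alt=alt_g,
                        zygosity="homozygous", location=location,
                        consequence=consequence))

        # cross-locus divergent sites anchored at the primary (A) copy
        for primary_id, sites in hemi_sites.items():
            primary = by_id[primary_id]
            partner_id = homoeolog_partner(primary_id, list(by_id))
            m_primary = config.multiplier(genotype, primary_id)
            m_partner = config.multiplier(genotype, partner_id)
            for offset, a_base, c_base in sites:
                if m_partner == 0:
                    continue  # only primary-locus reads: matches its own ref
                pos = primary.genomic_pos(offset) + 1
                if primary.strand == "+":
                    ref_g, alt_g = a_base, c_base
                else:
                    ref_g = a_base.translate(_COMPLEMENT)
                    alt_g = c_base.translate(_COMPLEMENT)
                if m_primary > 0:
                    zygosity, call = "hemi", "het"
                    lam = (m_primary + m_partner) * E * mu
                else:
                    zygosity, call = "homozygous", "hom_alt"
                    lam = m_partner * E * mu
                depth = int(_nbinom(rng, lam, config.background_dispersion, 1)[0])
                records.append(VariantRecord(
                    chrom=primary.chrom, pos=pos, ref=ref_g, alt=alt_g,
                    calls={genotype: call}, depth=depth))
                location = "promoter" if offset < P else "exon"
                consequence = "not_applicable"
                if zygosity == "homozygous" and location == "exon":
                    consequence = _consequence(primary.seq[P:], offset - P, c_base)
                truth_rows.append(dict(
                    genotype=genotype, chrom=primary.chrom, pos=pos,
                    copy_id=primary_id, ref=ref_g, alt=alt_g,
                    zygosity=zygosity, location=location,
                    consequence=consequence))
        variants[genotype] = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))

    multipliers = pd.DataFrame(
        {g: [config.multiplier(g, c.copy_id) for c in copies]
         for g in config.genotypes},
        index=pd.Index([c.copy_id for c in copies], name="copy_id"))
    snps = pd.DataFrame(
        truth_rows, columns=["genotype", "chrom", "pos", "copy_id", "ref",
                             "alt", "zygosity", "location", "consequence"])

    return SimulatedExperiment(
        config=config, genome_index=genome_index, targets=targets,
        cds_models=cds_models, gff_features=gff, cds_seqs=cds_seqs,
        promoter_seqs=promoter_seqs, tracks=tracks, stats=stats,
        variants=variants, truth=TruthTable(multipliers=multipliers, snps=snps))
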