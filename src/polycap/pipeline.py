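"""End-to-end orchestration: QC -> CNV/PAV -> SNP annotation -> copies -> tree.

A run is driven by a YAML panel config naming the genotypes, their depth
tracks and VCFs, the genome index and target BED, and the analysis
parameters (depth filter, ratio thresholds, bootstrap replicates, seed).
Alternatively the config may carry a ``simulate`` section, in which case
the inputs are generated first and the pipeline runs on them.

Every run writes a ``manifest.json`` recording the package version, seed,
thresholds, SHA-256 checksums of all inputs and outputs, and per-stage
timings; deterministic stages reproduce byte-identical outputs (and hence
checksums) when rerun with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .capture_qc import AlignmentStats, capture_metrics, metrics_table
from .cnv_pav import CnvThresholds, call_cnv, locus_normalized_matrix
from .copy_accounting import read_inventory, summarize_inventory, tabulate_inventory
from .formats_io import (
    ValidationError,
    read_bedgraph,
    read_fasta,
    read_genome_index,
    read_targets_bed,
    read_vcf,
)
from .promoter_phylo import bootstrap, write_newick
from .snp_annotate import (
    annotate_panel,
    cds_models_from_gff,
    het_loci_by_genotype,
    summarize_snps,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PanelConfig:
    genotypes: list[str]
    genome_index: str = ""
    targets: str = ""
    bedgraphs: dict = field(default_factory=dict)      # genotype -> path
    vcfs: dict = field(default_factory=dict)           # genotype -> path
    aligned_reads: dict = field(default_factory=dict)  # genotype -> N
    inbred: dict = field(default_factory=dict)         # genotype -> bool
    gff: str = ""
    cds_fasta: str = ""
    inventory: str = ""
    promoter_alignment: str = ""
    read_length: int = 100
    min_depth: int = 10
    gain_threshold: float = 1.5
    loss_threshold: float = 0.5
    absent_threshold: float = 0.05
    loo: bool | None = None
    bootstrap_reps: int = 100
    seed: int = 0
    simulate: dict | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if len(self.genotypes) < 2:
            raise ValidationError("a CNV panel needs at least 2 genotypes")
        if self.simulate is not None:
            return  # inputs are generated, not read
        for genotype in self.genotypes:
            if genotype not in self.bedgraphs:
                raise ValidationError(f"no depth track for genotype {genotype!r}")
            if genotype not in self.vcfs:
                raise ValidationError(f"no VCF for genotype {genotype!r}")
            if genotype not in self.aligned_reads:
                raise ValidationError(
                    f"no aligned-read count for genotype {genotype!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PanelConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "polycap_version": __version__,
        "seed": config.seed,
        "thresholds": {"gain": config.gain_threshold,
                       "loss": config.loss_threshold,
                       "absent": config.absent_threshold,
                       "min_depth": config.min_depth},
        "stages": {}, "inputs": {}, "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)}
                log.info("stage %s: done", name)
        return _Ctx()

    # --- optional simulation ----------------------------------------------
    if config.simulate is not None:
        from .synthetic_data import SimulationConfig, simulate_experiment

        with stage("simulate"):
            sim_cfg = SimulationConfig(**{**config.simulate,
                                          "genotypes": tuple(config.genotypes),
                                          "seed": config.seed})
            experiment = simulate_experiment(sim_cfg)
            paths = experiment.write(outdir / "sim")
            config.genome_index = str(paths["genome_index.tsv"])
            config.targets = str(paths["targets.bed"])
            config.gff = str(paths["genes.gff3"])
            config.cds_fasta = str(paths["cds.fasta"])
            config.bedgraphs = {g: str(paths[f"{g}.bedgraph"])
                                for g in config.genotypes}
            config.vcfs = {g: str(paths[f"{g}.vcf"]) for g in config.genotypes}
            config.aligned_reads = {g: experiment.stats[g].aligned_reads
                                    for g in config.genotypes}

    # --- load inputs --------------------------------------------------------
    with stage("load"):
        genome_index = read_genome_index(config.genome_index)
        targets = read_targets_bed(config.targets)
        tracks = {g: read_bedgraph(config.bedgraphs[g]) for g in config.genotypes}
        stats = {g: AlignmentStats(int(config.aligned_reads[g]),
                                   config.read_length)
                 for g in config.genotypes}
        for name in ("genome_index", "targets"):
            manifest["inputs"][name] = _sha256(Path(getattr(config, name)))
        for g in config.genotypes:
            manifest["inputs"][f"bedgraph:{g}"] = _sha256(Path(config.bedgraphs[g]))
            manifest["inputs"][f"vcf:{g}"] = _sha256(Path(config.vcfs[g]))

    with stage("qc"):
        table = metrics_table({
            g: capture_metrics(tracks[g], targets, stats[g], genome_index)
            for g in config.genotypes})
        outputs["qc_metrics.tsv"] = outdir / "qc_metrics.tsv"
        table.to_csv(outputs["qc_metrics.tsv"], sep="\t")

    with stage("snps"):
        records = {g: read_vcf(config.vcfs[g], min_depth=config.min_depth)
                   for g in config.genotypes}
        inbred = {g: bool(config.inbred.get(g, True)) for g in config.genotypes}
        models = (cds_models_from_gff(config.gff, config.cds_fasta)
                  if config.gff and config.cds_fasta else [])
        snp_table = annotate_panel(records, targets, models, inbred=inbred)
        target_length = sum(r.length for r in targets)
        summary = summarize_snps(records, targets, target_length, inbred=inbred)
        outputs["snps.tsv"] = outdir / "snps.tsv"
        snp_table.to_csv(outputs["snps.tsv"], sep="\t", index=False)
        outputs["snp_summary.tsv"] = outdir / "snp_summary.tsv"
        with_density = summary.table.copy()
        with_density.attrs = {}
        with_density.to_csv(outputs["snp_summary.tsv"], sep="\t")
        het_loci = het_loci_by_genotype(records, targets, inbred)

    with stage("cnv"):
        matrix = locus_normalized_matrix(tracks, targets, stats, genome_index)
        thresholds = CnvThresholds(gain=config.gain_threshold,
                                   loss=config.loss_threshold,
                                   absent=config.absent_threshold)
        calls = call_cnv(matrix, thresholds, het_snp_loci=het_loci,
                         loo=config.loo)
        outputs["coverage_matrix.tsv"] = outdir / "coverage_matrix.tsv"
        matrix.to_csv(outputs["coverage_matrix.tsv"], sep="\t")
        outputs["cnv_calls.tsv"] = outdir / "cnv_calls.tsv"
        calls.to_csv(outputs["cnv_calls.tsv"], sep="\t", index=False)

    if config.inventory:
        with stage("copies"):
            inventory = read_inventory(config.inventory)
            counts = tabulate_inventory(inventory)
            summary = summarize_inventory(counts)
            outputs["inventory_summary.tsv"] = outdir / "inventory_summary.tsv"
            pd.Series(summary.as_dict()).to_csv(
                outputs["inventory_summary.tsv"], sep="\t", header=False)

    if config.promoter_alignment:
        with stage("tree"):
            alignment = read_fasta(config.promoter_alignment)
            tree = bootstrap(alignment, n_reps=config.bootstrap_reps,
                             seed=config.seed)
            outputs["tree.nwk"] = outdir / "tree.nwk"
            write_newick(tree, outputs["tree.nwk"])

    with stage("manifest"):
        for name, path in outputs.items():
            manifest["outputs"][name] = _sha256(path)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
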