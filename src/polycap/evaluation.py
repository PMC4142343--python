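"""Truth-recovery benchmarking of the CNV/PAV caller and capture QC.

These helpers run the synthetic-data generator under defined study
conditions and measure how well the analysis recovers the planted truth:

* :func:`cnv_recovery` plants copy-number events (half-dose loss, double
  gain, full absence) at random loci/genotypes of a 4-genotype panel and
  reports per-class sensitivity and the false-call rate on event-free
  cells.  The event mix per 100 loci (4 loss, 2 gain, 1 absent) mirrors
  the variant load observed in real capture panels of this size.
* :func:`enrichment_estimate` simulates a small target set embedded in a
  large genome (so the on-target mass is a negligible fraction of the
  total, as in a real capture experiment) and returns the measured
  enrichment factor, which should converge to the configured value.

Note on half-dose losses: with an otherwise-normal panel the expected
coverage ratio of a multiplier-0.5 event sits exactly on the loss
threshold (0.5), so under the strict "smaller than" rule roughly half of
such events are called; the measured loss sensitivity quantifies this
boundary behaviour rather than noise.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .capture_qc import capture_metrics
from .cnv_pav import CnvThresholds, call_cnv, locus_normalized_matrix
from .synthetic_data import SimulationConfig, simulate_experiment


def copy_ids_for(config: SimulationConfig) -> list[str]:
    """Copy ids the simulator will generate for a config, in layout order."""
    ids = []
    for i in range(config.n_genes):
        for ci in range(1, config.copies_per_subgenome + 1):
            for sub in ("A", "C"):
                ids.append(f"Bna.G{i + 1:02d}.{sub}01_{ci}")
    return ids


def plant_events(config: SimulationConfig, seed: int, n_loss: int = 4,
                 n_gain: int = 2, n_absent: int = 1) -> SimulationConfig:
    """Assign loss/gain/absence events to random (locus, genotype) cells.

    At most one event per locus; the event genotype is drawn uniformly.
    Returns the config with its ``events`` filled in.
    """
    rng = np.random.default_rng([seed, 1])
    ids = copy_ids_for(config)
    n_events = n_loss + n_gain + n_absent
    if n_events > len(ids):
        raise ValueError("more events than loci")
    loci = rng.choice(len(ids), size=n_events, replace=False)
    genotype_idx = rng.integers(0, len(config.genotypes), size=n_events)
    multipliers = [0.5] * n_loss + [2.0] * n_gain + [0.0] * n_absent
    events: dict[str, dict[str, float]] = {}
    for locus, g_idx, m in zip(loci, genotype_idx, multipliers):
        genotype = config.genotypes[g_idx]
        events.setdefault(genotype, {})[ids[locus]] = m
    config.events = events
    return config


def recovery_config(seed: int, n_loci: int = 100) -> SimulationConfig:
    """Default recovery panel: 4 genotypes, E=760, NB(0.5, 0.1), n_loci loci."""
    if n_loci % 4:
        raise ValueError("n_loci must be a multiple of 4 (2 copies x 2 subgenomes)")
    return SimulationConfig(
        n_genes=n_loci // 4, copies_per_subgenome=2,
        enrichment_factor=760.0, background_mean=0.5,
        background_dispersion=0.1,
        genome_length=200_000 + n_loci * 3200,
        snp_rate=0.0, hemi_site_rate=0.0, seed=seed)


def cnv_recovery(seeds: Sequence[int], n_loci: int = 100, loo: bool = True,
                 thresholds: CnvThresholds | None = None) -> dict:
    """Plant events, call CNV, and tally recovery across seeds.

    Returns per-class sensitivities (fraction of planted events called with
    the matching state), the false-call rate (non-normal calls on
    event-free cells), and the trial counts.
    """
    tallies = {"loss": [0, 0], "gain": [0, 0], "absent": [0, 0]}  # hit, total
    false_calls = 0
    clean_cells = 0
    state_of = {0.5: "loss", 2.0: "gain", 0.0: "absent"}
    for seed in seeds:
        config = plant_events(recovery_config(seed, n_loci=n_loci), seed)
        experiment = simulate_experiment(config)
        matrix = locus_normalized_matrix(
            experiment.tracks, experiment.targets, experiment.stats,
            experiment.genome_index)
        calls = call_cnv(matrix, thresholds=thresholds, loo=loo)
        calls = calls.set_index(["copy_id", "genotype"])
        truth = experiment.truth.multipliers
        for copy_id in truth.index:
            for genotype in truth.columns:
                m = truth.loc[copy_id, genotype]
                called = calls.loc[(copy_id, genotype)]
                if called["excluded"]:
                    continue
                if m == 1.0:
                    clean_cells += 1
                    false_calls += called["state"] != "normal"
                else:
                    expected = state_of[m]
                    tallies[expected][1] += 1
                    tallies[expected][0] += called["state"] == expected
    out = {f"{cls}_sensitivity": (hit / total if total else float("nan"))
           for cls, (hit, total) in tallies.items()}
    out.update({f"n_{cls}_events": total for cls, (_, total) in tallies.items()})
    out["false_call_rate"] = false_calls / clean_cells if clean_cells else 0.0
    out["n_clean_cells"] = clean_cells
    return out


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with positive branch lengths and its leaf matrix.

    Path distances on such a tree form an additive matrix, on which
    neighbor joining provably recovers the generating topology exactly.
    """
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i + 1}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.uniform(0.05, 1.0))
        right.length = float(rng.uniform(0.05, 1.0))
        nodes.append(TreeNode(children=[left, right]))
    tree = nodes[0]
    return tree, tree.tip_tip_distances()


def nj_additive_recovery(seed: int, n_trials: int = 20,
                         taxa_range: tuple[int, int] = (4, 8)) -> float:
    """Fraction of random additive matrices whose topology NJ recovers exactly."""
    from .promoter_phylo import _bipartitions, nj_tree

    rng = np.random.default_rng([seed, 2])
    hits = 0
    for _ in range(n_trials):
        n_taxa = int(rng.integers(taxa_range[0], taxa_range[1] + 1))
        true_tree, dm = random_additive_tree(rng, n_taxa)
        inferred = nj_tree(dm)
        taxa = frozenset(t.name for t in true_tree.tips())
        hits += _bipartitions(inferred, taxa) == _bipartitions(true_tree, taxa)
    return hits / n_trials


def enrichment_config(seed: int) -> SimulationConfig:
    """A capture-like geometry: ~19 kbp of targets in a 1.5 Gbp genome."""
    return SimulationConfig(
        n_genes=4, copies_per_subgenome=2, genome_length=1_500_000_000,
        background_window=8000, snp_rate=0.0, hemi_site_rate=0.0,
        genotypes=("geno1",), seed=seed)


def enrichment_estimate(seed: int) -> float:
    """Measured enrichment factor of one simulated capture library."""
    experiment = simulate_experiment(enrichment_config(seed))
    genotype = experiment.config.genotypes[0]
    metrics = capture_metrics(
        experiment.tracks[genotype], experiment.targets,
        experiment.stats[genotype], experiment.genome_index)
    return metrics.enrichment_factor
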