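# Methods

## Coverage normalization and capture QC

All depth arithmetic operates on bedGraph-style constant-depth segments
(0-based half-open); uncovered bases are implicit depth 0.  The
normalized coverage of a depth value `d` is `c = d·G/(N·rl)`, where `G`
is the total genome length (from a two-column name/length index, so
uncovered chromosomes count), `N` the aligned reads and `rl` the read
length.  `N·rl/G` is the expected genome-wide mean depth, so `c` is depth
in units of that mean: `c = 1` for an average region, and `c` is
invariant under multiplying both the depths and `N` by any constant.
Each constant-depth segment contributes `depth × length`; per-region
values are length-weighted means.  This segment-wise reading is the only
one under which the normalization is dimensionless and scale-invariant; a
literal read-count reading would not be.

QC metrics follow the standard capture panel: mean genome-wide and mean
on-target coverage, their ratio (the enrichment factor), the fraction of
target covered at depth ≥ 1 ("capture sensitivity") and at a configurable
depth k (default 10, with a `strict_gt` switch for > k), and specificity.
Specificity is computed over *bases* (on-target base mass / total base
mass), because read-level assignment is not recoverable from a depth
track; this is recorded in the output metadata.  Note that the enrichment
factor's denominator includes the on-target mass itself, so the estimate
converges to the true enrichment `E` only when `E·T/G ≪ 1` (`T` = target
size) — true for a real capture experiment (hundreds of kbp of target in
a gigabase genome) and respected by the sizing of the simulated QC
geometry below.

## CNV / PAV calling

For each locus (target gene copy) and genotype, the length-weighted mean
normalized coverage over the locus's full span is compared with the panel
reference, and the ratio is classified with fixed thresholds: absent
below 0.05, loss below 0.5, gain above 1.5, otherwise normal.  The
inequalities are strict; absence is checked first as the extreme of the
same ratio.  Two reference conventions are implemented:

* **panel mean** (`loo=False`): the mean over all genotypes including the
  focal one.  In a 4-genotype panel a genuine half-dose event then has
  ratio 0.5/0.875 ≈ 0.57 and can never cross the 0.5 threshold — the
  event dilutes its own reference.
* **leave-one-out** (`loo=True`, the default for panels of ≤ 6): the mean
  over the other genotypes only.

Neither convention removes a structural boundary problem of small panels:
with leave-one-out, a half-dose locus in an otherwise-normal panel has
expected ratio exactly 0.5, and the genotypes *around* an absent locus
have expected ratio exactly 1.5.  The ratio distribution is then centred
on the decision boundary and the call is a coin flip regardless of depth
— no threshold or noise level fixes this without changing the published
rule, so the package reports it rather than papering over it (the
truth-recovery benchmark in `polycap.evaluation` quantifies it: half-dose
sensitivity ≈ 0.45, while double-dose and absence are recovered at ≈ 1.0
with a false-call rate < 0.01).  Full absences themselves are always
called: with unique-mapping depth their ratio is exactly 0.

Loci at which a genotype shows any heterozygous SNP are excluded from
calling for that genotype, because in fully inbred material heterozygosity
marks collapsed homoeologous read piles whose depth does not measure
single-locus dosage.  A locus with zero panel coverage is excluded with
reason "no panel coverage".

## SNP classification

Variants are read from VCF 4.x (via pysam), multi-allelic records split
one alt at a time with the depth retained, and records below the minimum
depth (default 10 reads) dropped.  In lines declared inbred (S5 or
beyond), heterozygous calls are classified as hemi-SNPs — signals of two
or more divergent homoeologous/paralogous loci mapping to one position —
and homozygous-alt calls as true locus-specific SNPs; for non-inbred
samples the hemi interpretation is withheld
(`heterozygous_unresolved`).  Only homozygous SNPs receive an amino-acid
call: the variant is mapped through the gene model (GFF3) to its coding
index, complemented onto the coding strand for minus-strand genes, and
the affected codon translated with the standard nuclear genetic code
before and after substitution.  CDS sequences with ambiguity codes are
rejected on read; a CDS whose length is not a multiple of three yields
`not_applicable` with a reason, as does a reference mismatch between VCF
and CDS.  Indels are out of scope throughout.

Summary percentages divide each genotype's class count by the
*panel-wide* SNP total (total or on-target), so classes are comparable
across genotypes of one survey; a per-genotype denominator is available
by flag.  SNP density is reported as bp of target per target SNP, rounded
to the nearest integer.

## Copy accounting

The copy inventory records, per detected homolog/paralog: detection
status (full length / partial / not detected), a functionality flag
(an *input* — deciding functionality is an upstream annotation task), and
whether the copy was expected from the progenitor genomes.  Derived
statistics: lost = expected but not detected; duplicated = detected
beyond expectation; functional duplications = duplicated minus
non-functional duplicated; mean copies per gene = functional (full +
partial) copies / number of genes, to one decimal; percent non-functional
to the nearest integer.  The packaged reference table for the *B. napus*
flowering-time panel uses 30 genes (the 29 targeted genes plus the
co-captured *CO-like 2*), which is the divisor consistent with its
reported 4.7 mean; its full-length count (124) follows the survey's
copy-level accounting, whose section totals disagree by four copies with
an earlier rounding of the same numbers.  Dosage ratios apply a
genotype's calls to the reference counts: loss −1, gain +1, absence
removes the locus's reference copies; a negative total is an error.

## Bait tiling

120-mer baits at 1× tiling: end-to-end placement within each contiguous
unmasked run (lowercase or N marks repeats; both honoured).  Runs shorter
than the bait yield nothing.  A terminal bait anchored at the run end
rescues an uncovered tail only if it would overlap the previous bait by
at most the avoidance limit (default 20 bp) — a declared interpretation
of the vendor's undocumented "avoid overlap" semantics, configurable and
not claimed identical to any proprietary tool.  Both strand rules (sense
for minus-strand genes, antisense for plus-strand genes) emit the reverse
complement of the plus-strand genomic window; only the recorded synthesis
strand differs, which is the unique reading under which both rules are
mutually consistent.

## Promoter clustering

p-distances are computed over a fixed alignment with pairwise gap
deletion (Jukes–Cantor correction by flag; the distance model of the
original commercial tool is unknown, so the uncorrected p-distance is the
default).  Neighbor joining is the canonical Saitou–Nei algorithm with
the standard Q-criterion and branch-length formulas; ties in the Q
minimisation are broken on the lexicographically smallest cluster-label
pair (a cluster is labelled by its smallest leaf), making the
construction deterministic, and negative branch lengths are clamped to
zero with a flag.  On any additive matrix the implementation recovers the
generating topology exactly (property-tested against random trees and
cross-checked against an independent NJ implementation).  Bootstrap
support resamples columns with replacement (default 100 replicates,
seeded) and reports, per internal edge, the percentage of replicates
containing the same leaf bipartition.

## The synthetic-data generator

`polycap.synthetic_data` emulates the *statistical* structure of an
allopolyploid capture experiment, not the reads: a multi-gene target set
with A/C homoeolog pairs (each copy a 300 bp promoter plus a 900 bp
single-exon CDS, alternating strands), per-genotype depth tracks, VCFs
and truth tables.  Key choices:

* **Depth.**  A locus with copy-number multiplier `m` has expected depth
  `m·E·μ` (`E` enrichment factor, default 760×, as in a real capture
  experiment; `μ` the genotype's background mean, default 0.5); off-target
  depth is `μ`.  Noise is negative-binomial per 60 bp segment with
  variance `μ + α·μ²` (dispersion `α`, default 0.1) — overdispersed
  relative to Poisson, mimicking capture variability; the original
  experiment reports no noise model, so this is the package's choice.
* **Sequences** are i.i.d. uniform with mutations imposed (inter-homoeolog
  identity default 97%); no indels, matching the survey's observation
  that none were detected in the target space.
* **Hemi-SNPs.**  Cross-locus divergent sites (default 0.005/bp) are
  anchored at the A-subgenome copy, where the collapsed read pile
  accumulates: both partners present → heterozygous call; primary absent
  but partner present → homozygous-alt call; partner absent → no call.
  Depth tracks represent uniquely-mapped coverage (an absent locus has
  depth 0) while variant DP reflects the collapsed pile — the one place
  the two views intentionally differ.  A `cross_mapping_bleed` parameter
  (default 0) lets ambiguous-mapping depth leak into an absent locus;
  how often this occurs in real data is unquantified, so it is exposed
  rather than guessed.
* **Homoeologous replacement** is modelled as multiplier 0 on one copy
  and +1 on its partner in the same genotype
  (`add_replacement_event`), and is a config error for a copy without a
  partner.
* **Determinism.**  One `numpy` generator seeded from the config drives
  everything; identical seeds give bitwise-identical output files.

What the generator does *not* emulate — mapping-quality structure, GC
bias, duplicate reads, indels, residual heterozygosity — bounds what
passing tests show: they validate the arithmetic and the decision rules
under the stated generative model, not robustness to artefacts of real
mapping.

## Problem sizes used in tests and benchmarks

The truth-recovery benchmark uses a 100-locus (25 genes × 4 copies),
4-genotype panel at E = 760, NB(0.5, 0.1), with an event mix scaled from
a real panel's variant load (per 100 loci: 4 half-dose losses, 2
double-dose gains, 1 absence, at most one event per locus, placed by a
seeded draw) over 20 seeds.  The enrichment-convergence check simulates
~19 kbp of targets in a 1.5 Gbp genome with 8 kbp background windows, so
`E·T/G < 1%` and the estimator's bias is negligible.  The whole suite
runs in a few seconds on one CPU.
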