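import numpy as np
import pytest

from polycap.synthetic_data import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 2-gene, 4-genotype simulated capture panel with SNPs and hemi sites."""
    return simulate_experiment(SimulationConfig(n_genes=2, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def random_track_segments(rng, n_chroms=2, n_segments=30, chrom_len=10_000,
                          max_depth=40):
    """Random non-overlapping bedGraph segments (possibly touching, some 0)."""
    segments = []
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        cursor = 0
        for _ in range(n_segments):
            cursor += int(rng.integers(0, 50))
            length = int(rng.integers(1, 80))
            if cursor + length > chrom_len:
                break
            depth = int(rng.integers(0, max_depth))
            segments.append((chrom, cursor, cursor + length, depth))
            cursor += length
    return segments


def per_base_arrays(track, genome_index):
    """Expand a coverage track to per-base numpy arrays (brute-force oracle)."""
    arrays = {chrom: np.zeros(length, dtype=np.int64)
              for chrom, length in genome_index.lengths.items()}
    for chrom, start, end, depth in track.iter_segments():
        arrays[chrom][start:end] = depth
    return arrays
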