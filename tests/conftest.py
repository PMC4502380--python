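import numpy as np
import pytest

from bingbs import binning
from bingbs.simulate import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def medium_cross():
    """120 F2s, 6 scaffolds of 1.5 Mb on 3 chromosomes, 1.5x coverage."""
    cfg = SimConfig(
        n_f2=120,
        n_chromosomes=3,
        scaffold_lengths=(1_500_000,) * 6,
        snp_density=80,
        mean_coverage=1.5,
        seed=2,
    )
    counts, truth = simulate_cross(cfg)
    return counts, truth


@pytest.fixture(scope="session")
def medium_binned(medium_cross):
    """Binned markers + genotype calls for the medium cross."""
    counts, truth = medium_cross
    lengths = dict(
        zip(truth.placement["scaffold"], truth.placement["length"].astype(int))
    )
    markers, snp_to_marker = binning.assign_bins(counts.snps, lengths)
    M, F = binning.pool_counts(counts, snp_to_marker, len(markers))
    codes, post = binning.call_genotypes(M, F)
    markers = markers.assign(midpoint_bp=(markers["start"] + markers["end"]) // 2)
    return markers, M, F, codes, post


@pytest.fixture(scope="session")
def sex_cross():
    """200 F2s at 0.5x with a 8-Mb sex scaffold ('2') among three."""
    cfg = SimConfig(
        n_f2=200,
        n_chromosomes=3,
        scaffold_lengths=(8_000_000,) * 3,
        snp_density=250,
        mean_coverage=0.5,
        sex_chromosome="2",
        male_fraction=0.5,
        seed=7,
    )
    counts, truth = simulate_cross(cfg)
    return counts, truth


def truth_bin_genotype(truth, snp_to_marker, n_markers):
    """Majority SNP dosage per (marker, F2) as the bin-level truth.

    Bins containing a breakpoint have mixed dosage; the majority state is
    the natural single-state summary the binned caller is asked to match.
    """
    n_f2 = truth.genotype.shape[1]
    out = np.full((n_markers, n_f2), -1, dtype=np.int8)
    for mk in range(n_markers):
        rows = np.flatnonzero(snp_to_marker == mk)
        if len(rows) == 0:
            continue
        sub = truth.genotype[rows]  # dosages 0/1/2 = codes A/H/B
        for j in range(n_f2):
            out[mk, j] = np.bincount(sub[:, j], minlength=3).argmax()
    return out
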