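"""Shared fixtures: a seeded planted dataset and its k-mer deviations.

The planted dataset is generated once per session; tests that need the
deviation engine's output on it share one computation.
"""

import numpy as np
import pytest

from tecis import accessibility as acc
from tecis import motifs as mot
from tecis.simulate import (
    PopulationSpec,
    SubfamilySpec,
    SyntheticConfig,
    generate_dataset,
)

PLANTED_SEED = 7


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted study at seed 7."""
    return generate_dataset(SyntheticConfig(seed=PLANTED_SEED))


@pytest.fixture(scope="session")
def planted_background(planted_dataset):
    ds = planted_dataset
    return acc.sample_background_peaks(
        acc.gc_fraction(ds.peak_seqs), ds.matrix.values.mean(axis=1),
        seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def planted_kmer_deviations(planted_dataset, planted_background):
    ds = planted_dataset
    A = mot.kmer_annotation(ds.peak_seqs, k=7).filter_min_support(5)
    return acc.compute_deviations(ds.matrix, A, planted_background)


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for fast end-to-end tests."""
    return SyntheticConfig(
        seed=3,
        chrom_len=150_000,
        subfamilies=[
            SubfamilySpec("MER130", "DNA", 400, 20, "CAGATGG", 216, "Amniota"),
            SubfamilySpec("B2_Mm1", "SINE", 200, 20, None, None, "Muridae"),
        ],
        populations=[
            PopulationSpec("progenitor", n_cells=60, n_specific_peaks=30,
                           motif_frac=0.8, planted_motif_of="MER130",
                           branch_id="S2_S1"),
            PopulationSpec("neuron", n_cells=60, n_specific_peaks=30,
                           branch_id="S0_S1"),
        ],
        n_common_peaks=40,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def brute_force_deviations(values, membership, bg_index):
    """Independent dense oracle for the deviation engine: explicit loops over
    features, cells and background iterations."""
    X = np.asarray(values, dtype=float)
    A = np.asarray(membership, dtype=float)
    n_peaks, n_cells = X.shape
    n_features = A.shape[1]
    n_iter = bg_index.shape[1]
    row = X.sum(axis=1)
    col = X.sum(axis=0)
    total = X.sum()
    E = np.empty_like(X)
    for i in range(n_peaks):
        for j in range(n_cells):
            E[i, j] = row[i] * col[j] / total

    def raw_for(idx):
        out = np.empty((n_features, n_cells))
        for k in range(n_features):
            for j in range(n_cells):
                obs = sum(A[i, k] * X[idx[i], j] for i in range(n_peaks))
                exp = sum(A[i, k] * E[idx[i], j] for i in range(n_peaks))
                out[k, j] = (obs - exp) / exp
        return out

    ident = np.arange(n_peaks)
    raw = raw_for(ident)
    bg_raws = np.stack([raw_for(bg_index[:, t]) for t in range(n_iter)])
    mean_bg = bg_raws.mean(axis=0)
    sd_bg = bg_raws.std(axis=0, ddof=1)
    dev = raw - mean_bg
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd_bg > 0, dev / sd_bg,
                     np.where(dev == 0, 0.0, np.nan))
    return dev, z
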