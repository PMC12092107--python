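"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pavpan import PAVMatrix, SampleSheet
from pavpan.synthetic_data import (
    SimConfig,
    make_sample_sheet,
    simulate_annotation,
    simulate_depth,
    simulate_pav_truth,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=200, n_wild=20, n_selection=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(truth, annotations, tracks, sheet) for a 50-sample, 200-gene cohort."""
    truth = simulate_pav_truth(small_config)
    anns = simulate_annotation(small_config)
    tracks = simulate_depth(truth, anns, small_config)
    sheet = make_sample_sheet(small_config)
    return truth, anns, tracks, sheet


def random_matrix(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    missing_rate: float = 0.0,
) -> PAVMatrix:
    """A random PAV matrix with placed + novel genes."""
    calls = rng.integers(0, 2, size=(n_genes, n_samples)).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n_genes, n_samples)) < missing_rate] = -1
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    n_novel = max(n_genes // 10, 1) if n_genes > 1 else 0
    chroms = [f"chr{(i % 3) + 1}" for i in range(n_genes - n_novel)] + ["novel_x"] * n_novel
    starts = rng.integers(1, 10_000_000, size=n_genes)
    meta = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + rng.integers(100, 5000, size=n_genes),
            "source": ["reference"] * (n_genes - n_novel) + ["novel"] * n_novel,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return PAVMatrix(gene_ids, [f"s{j:03d}" for j in range(n_samples)], calls, meta)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture()
def two_pop_sheet():
    def make(n_wild: int, n_sel: int, sample_ids=None) -> SampleSheet:
        if sample_ids is None:
            sample_ids = [f"s{j:03d}" for j in range(n_wild + n_sel)]
        return SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "population": ["wild"] * n_wild + ["selection"] * n_sel,
                }
            )
        )

    return make
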