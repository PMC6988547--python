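"""Shared fixtures and random-data helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deltapop import GenotypeMatrix, PopulationFrame


def random_dataset(
    rng: np.random.Generator,
    pop_sizes: list[int],
    n_loci: int = 2,
    n_alleles: int = 3,
) -> tuple[GenotypeMatrix, PopulationFrame]:
    """Complete random genotypes with per-population skewed allele frequencies."""
    n = sum(pop_sizes)
    calls = np.empty((n, n_loci, 2), dtype=np.int32)
    ids, pops = [], []
    row = 0
    for j, size in enumerate(pop_sizes):
        freqs = [rng.dirichlet(np.ones(n_alleles) * 0.8) for _ in range(n_loci)]
        for i in range(size):
            ids.append(f"p{j}_{i}")
            pops.append(f"P{j}")
            for l in range(n_loci):
                calls[row, l] = np.sort(rng.choice(n_alleles, 2, p=freqs[l]) + 1)
            row += 1
    gm = GenotypeMatrix(ids, [f"L{l + 1}" for l in range(n_loci)], calls)
    pf = PopulationFrame(pd.Series(pops, index=ids))
    return gm, pf


def matrix_from_pairs(
    pairs_by_pop: dict[str, list[list[tuple[int, int]]]], locus_ids: list[str]
) -> tuple[GenotypeMatrix, PopulationFrame]:
    """Build a tiny dataset from explicit per-population genotype rows."""
    ids, pops, calls = [], [], []
    for pop, rows in pairs_by_pop.items():
        for i, row in enumerate(rows):
            ids.append(f"{pop}_{i}")
            pops.append(pop)
            calls.append(row)
    gm = GenotypeMatrix(ids, locus_ids, np.array(calls, dtype=np.int32))
    pf = PopulationFrame(pd.Series(pops, index=ids))
    return gm, pf


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_three_pops() -> tuple[GenotypeMatrix, PopulationFrame]:
    """Three equal populations, one locus: fixed allele 1 / 50:50 / fixed allele 2."""
    return matrix_from_pairs(
        {
            "A": [[(1, 1)]] * 4,
            "B": [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]],
            "C": [[(2, 2)]] * 4,
        },
        ["L1"],
    )
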