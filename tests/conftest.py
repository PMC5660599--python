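"""Shared fixtures: small hand-built objects and session-scoped benchmark runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cocomplex.discovery import DiscoveryConfig, discover_complexes
from cocomplex.simulate import (
    SimulationConfig,
    generate,
    perturb_reference,
)
from cocomplex.types import ExpressionMatrix, InteractionNetwork


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    df = pd.DataFrame(
        {
            "s1": [1.0, 2.0, np.nan],
            "s2": [2.0, 4.0, 5.0],
            "s3": [3.0, 6.0, 7.0],
        },
        index=["gA", "gB", "gC"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def triangle_network() -> InteractionNetwork:
    return InteractionNetwork([("A", "B"), ("B", "C"), ("A", "C")])


def _benchmark_config(seed: int) -> SimulationConfig:
    """Planted-structure study conditions: 1,000 genes, 60 samples, 25
    complexes of 3-12 subunits at within-complex r = 0.7, dense within-complex
    connectivity (0.9) over 2,000 background edges, missing rates U(0, 0.3),
    plus 10 correlated-only and 10 clique-only decoy sets."""
    return SimulationConfig(
        n_genes=1000,
        n_samples=60,
        n_complexes=25,
        complex_size_range=(3, 12),
        within_complex_r=0.7,
        p_edge_within=0.9,
        n_background_edges=2000,
        missing_rate_range=(0.0, 0.3),
        n_correlated_decoys=10,
        n_clique_decoys=10,
        seed=seed,
    )


def _run_benchmark(seed: int, n_random: int = 25):
    data = generate(_benchmark_config(seed))
    reference = perturb_reference(
        data.truth.planted, data.protein.gene_ids, seed=seed
    )
    result = discover_complexes(
        data.protein,
        data.network,
        reference,
        DiscoveryConfig(seed=seed, n_random=n_random),
    )
    return data, result


@pytest.fixture(scope="session")
def benchmark_run():
    """The primary planted-recovery run (seed 1, 25 FDR randomizations)."""
    return _run_benchmark(1)


@pytest.fixture(scope="session")
def decoy_runs(benchmark_run):
    """Five independent planted+decoy runs for decoy-rejection statistics."""
    runs = [benchmark_run]
    for seed in (2, 3, 4, 5):
        runs.append(_run_benchmark(seed, n_random=10))
    return runs
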