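"""Shared fixtures: one modest synthetic dataset reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from salixevol.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_ortholog_set,
    simulate_site_table,
)


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig(seed=42, n_genes_per_category=30, gene_length_codons=150)


@pytest.fixture(scope="session")
def ortholog_set(config):
    return simulate_ortholog_set(config)


@pytest.fixture(scope="session")
def alignments(ortholog_set):
    return ortholog_set[0]


@pytest.fixture(scope="session")
def truth(ortholog_set):
    return ortholog_set[1]


@pytest.fixture(scope="session")
def categories(truth) -> pd.Series:
    return pd.Series(truth.categories, name="category")


@pytest.fixture(scope="session")
def expression_table(config):
    return simulate_expression(config)


@pytest.fixture(scope="session")
def site_table(ortholog_set, config):
    alignments, truth = ortholog_set
    return simulate_site_table(alignments, truth, config)
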