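"""Shared fixtures: small synthetic cohorts sized for fast tests."""

import numpy as np
import pytest

from metaprog import (AnalysisConfig, CountMatrix, GeneratorConfig,
                      generate_cohort)


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """A 3-sample desk cohort with 2 shared + 1 private program per sample."""
    return GeneratorConfig(
        n_samples=3, cells_per_sample=150, n_genes=400,
        n_shared_programs=2, n_private_programs_per_sample=1,
        genes_per_program=20, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_analysis_config() -> AnalysisConfig:
    return AnalysisConfig(k=5, n_top=20, min_programs=2, min_samples=2)


@pytest.fixture()
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(5)
    counts = rng.poisson(3.0, size=(30, 12)).astype(np.int64)
    counts[0, :] = 0  # an undetected gene
    return CountMatrix(
        sample_id="T01",
        gene_ids=[f"g{i:02d}" for i in range(30)],
        cell_ids=[f"c{j}" for j in range(12)],
        counts=counts)
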