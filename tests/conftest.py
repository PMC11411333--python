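"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from stempatterns import (ExpressionStudy, SampleMeta, SimulationConfig,
                          consensus_decompose, simulate_study)
from stempatterns.simulate import truth_decomposition


@pytest.fixture(scope="session")
def default_study():
    """Default-condition study: 2000 genes, 6 lines / 4 donors, 54 samples."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """Smaller study for fast stage-level tests (600 genes, K_true=5)."""
    cfg = SimulationConfig(
        seed=3, n_genes=600, k_dynamic=3, baseline=0.0,
        dynamic_shapes=("NSB-early", "NSB-late", "BMP4-rising"), k_line=2)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_decomp(small_study):
    study, _ = small_study
    return consensus_decompose(study, 5, n_restarts=8, seed=0,
                               max_iter=1000, tol=1e-7)


@pytest.fixture(scope="session")
def truth_decomp(default_study):
    """Planted factors wrapped as a decomposition (ideal factorization)."""
    study, truth = default_study
    return truth_decomposition(truth, study)


@pytest.fixture()
def tiny_study():
    """Hand-sized 3-gene x 4-sample study."""
    samples = [
        SampleMeta("s1", "L1", "D1", "SR", 2),
        SampleMeta("s2", "L1", "D1", "NSB", 2),
        SampleMeta("s3", "L2", "D2", "SR", 4),
        SampleMeta("s4", "L2", "D2", "NSB", 4),
    ]
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [0.5, 0.25, 8.0, 1.0],
                       [2.0, 2.0, 2.0, 5.0]])
    return ExpressionStudy(values, ["g1", "g2", "g3"], samples, scale="rpkm")
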