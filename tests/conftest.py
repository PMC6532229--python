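"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gliotalk.data_model import SingleCellMatrix
from gliotalk.pipeline import default_demo_sim
from gliotalk.synthetic import SimConfig, simulate_bulk_cohort, simulate_sc_cohort


@pytest.fixture(scope="session")
def demo_sim():
    """Demo-scale study configuration with planted LR pairs and hazard genes."""
    return default_demo_sim(seed=1)


@pytest.fixture(scope="session")
def sc_cohort(demo_sim):
    """(matrix, truth, catalog) for the demo single-cell cohort."""
    return simulate_sc_cohort(demo_sim)


@pytest.fixture(scope="session")
def bulk_cohort(demo_sim):
    """(cohort, gene_truth) for the demo bulk cohort."""
    return simulate_bulk_cohort(demo_sim)


@pytest.fixture()
def tiny_matrix():
    """Hand-built 5-gene x 6-cell matrix with two obvious groups."""
    genes = ["G1", "G2", "G3", "G4", "G5"]
    cells = [f"c{i}" for i in range(6)]
    values = pd.DataFrame(
        [
            [5.0, 5.2, 4.8, 0.0, 0.1, 0.0],   # up in first three cells
            [0.0, 0.2, 0.0, 6.0, 5.9, 6.1],   # up in last three cells
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],   # constant
            [2.0, 0.0, 3.0, 2.5, 0.0, 3.5],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # never detected
        ],
        index=genes,
        columns=cells,
    )
    meta = pd.DataFrame({"patient": ["p1", "p1", "p1", "p2", "p2", "p2"]}, index=cells)
    return SingleCellMatrix(values, meta)


@pytest.fixture()
def null_zinb_matrix():
    """Zero-inflated NB matrix with no group structure (200 genes x 120 cells)."""
    sim = SimConfig(
        n_patients=2,
        cells_per_patient=60,
        n_genes=1000,
        marker_effect=0.0,
        program_effect=0.0,
        healthy_fraction={},
        csc_fraction=0.0,
        seed=11,
    )
    matrix, truth, _ = simulate_sc_cohort(sim)
    return matrix, truth
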