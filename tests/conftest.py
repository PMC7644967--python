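import numpy as np
import pandas as pd
import pytest

from sclipid import QCThresholds, SimulationConfig, match_all, simulate_experiment
from sclipid.panel import build_panel


@pytest.fixture(scope="session")
def small_panel():
    """Six-lipid panel with both markers, two PE and one SM (for ratios)."""
    return build_panel(["PC 34:1", "PC 36:2", "PC 34:2", "PE 34:1", "PE 36:2", "SM 34:1"])


@pytest.fixture(scope="session")
def small_config(small_panel):
    """Two small plates; fast enough for per-test simulation variants."""
    return SimulationConfig(
        n_plates=2,
        wells_per_plate=30,
        qc_per_plate=3,
        lipid_panel=tuple(small_panel),
        seed=123,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulated experiment at generator defaults (7 x 96 wells)."""
    cfg = SimulationConfig(seed=20240917)
    spectra, samples, truth = simulate_experiment(cfg)
    return cfg, spectra, samples, truth


@pytest.fixture(scope="session")
def matched(default_sim):
    cfg, spectra, samples, truth = default_sim
    matches, raw = match_all(spectra, list(cfg.lipid_panel), QCThresholds())
    return matches, raw


def make_matrix(values, sample_ids=None, lipids=None, normalized=False):
    """Small AbundanceMatrix helper for hand-built examples."""
    from sclipid import AbundanceMatrix

    arr = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    lipids = lipids or [f"PC 3{i}:0" for i in range(arr.shape[1])]
    return AbundanceMatrix(pd.DataFrame(arr, index=sample_ids, columns=lipids), normalized)


def cell_table(sample_ids, genotypes=None, plates=None, replicates=None):
    """Minimal single-cell sample table for hand-built examples."""
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sample_type": ["single_cell"] * n,
            "plate": plates if plates is not None else [1] * n,
            "well": [f"W{i:02d}" for i in range(n)],
            "injection_order": range(1, n + 1),
            "genotype": genotypes if genotypes is not None else ["WT"] * n,
            "replicate": ["r1"] * n,
            "experiment_id": ["exp1"] * n,
            "n_cells": [np.nan] * n,
        }
    )
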