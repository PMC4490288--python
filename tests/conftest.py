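import numpy as np
import pandas as pd
import pytest

from twinprot import ProteinMatrix, SimulationTruth, simulate_twin_cohort
from twinprot.preprocess import log_standardize


def simulate_standardized(truth: SimulationTruth):
    """Simulate a cohort and return it with a log-standardized panel."""
    roster, proteins, phenotypes = simulate_twin_cohort(truth)
    return roster, log_standardize(proteins), phenotypes


@pytest.fixture
def small_twin_cohort():
    """50 MZ + 43 DZ pairs + 9 singletons, one moderately heritable analyte."""
    truth = SimulationTruth.uniform(
        a2=0.4, c2=0.1, e2=0.5, n_analytes=3, beta=0.0,
        n_mz_pairs=50, n_dz_pairs=43, n_singletons=9,
        missing_rate=0.0, seed=101,
    )
    return simulate_standardized(truth)


@pytest.fixture
def tiny_roster():
    """Hand-built 6-subject roster: 2 intact pairs, one flagged pair member."""
    return pd.DataFrame(
        {
            "subject_id": ["P0001-1", "P0001-2", "P0002-1", "P0002-2", "P0003-1", "P0003-2"],
            "pair_id": ["P0001", "P0001", "P0002", "P0002", "P0003", "P0003"],
            "zygosity": ["MZ", "MZ", "DZ", "DZ", "MZ", "MZ"],
            "age": [64.0, 64.0, 70.0, 70.0, 58.0, 58.0],
            "sex": ["F"] * 6,
            "centre": ["London"] * 6,
            "apoe_e4_count": [0.0, 1.0, 0.0, 0.0, 2.0, 0.0],
            "haemolysed": [False] * 6,
            "qc_fail": [False] * 6,
            "diagnosis": ["control"] * 6,
        }
    )


def matrix_from_columns(columns: dict, transform_state="raw", subjects=None) -> ProteinMatrix:
    df = pd.DataFrame(columns, dtype=float)
    if subjects is None:
        subjects = [f"S{i:03d}" for i in range(len(df))]
    df.index = pd.Index(subjects, name="subject_id")
    return ProteinMatrix(df, transform_state=transform_state)
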