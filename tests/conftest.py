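import numpy as np
import pandas as pd
import pytest

from surrogene.io_formats import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection
from surrogene.simulate import SimulationConfig, simulate


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 2 samples, linear space."""
    return ExpressionMatrix(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        value_space="linear",
    )


@pytest.fixture
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("top", "top gene", frozenset({"C"})),
            GeneSet("pair", "two genes", frozenset({"A", "B"})),
        ]
    )


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    return ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ["p1", "p2", "p3", "p4"],
                "cohort_id": ["c1", "c1", "c2", "c2"],
                "tumor_type": ["mel", "mel", "lung", "lung"],
                "os_months": [12.0, 30.0, 5.0, 40.0],
                "event": [1, 0, 1, 0],
                "recist": ["PR", "SD", "PD", "CR"],
                "response_duration_months": [np.nan, 8.0, np.nan, np.nan],
            }
        )
    )


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the reference configuration (seed 0)."""
    return simulate(SimulationConfig(seed=0))
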