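import numpy as np
import pytest

from sigrank import AnalysisConfig
from sigrank.consensus import build_consensus_table
from sigrank.data_model import InteractionMatrix
from sigrank.synthetic import SyntheticSpec, generate_cohort, planted_truth


@pytest.fixture
def tiny_matrix() -> InteractionMatrix:
    """Three compounds, two proteins: A=(0,0), B=(3,4), C=(1,0)."""
    return InteractionMatrix(
        ("a", "b", "c"), ("p1", "p2"), np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 0.0]])
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    spec = SyntheticSpec(seed=11)
    matrix, compounds, indications = generate_cohort(spec)
    return spec, matrix, compounds, indications, planted_truth(spec)


@pytest.fixture(scope="session")
def default_consensus(default_cohort):
    """Top10/Top25 consensus table for the shared cohort."""
    _, matrix, _, indications, _ = default_cohort
    config = AnalysisConfig(
        topx_values=(10, 25), association_thresholds={10: 2, 25: 3}, seed=11
    )
    return build_consensus_table(indications, matrix, config)
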