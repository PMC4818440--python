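import numpy as np
import pandas as pd
import pytest

from pairedconcord.core_model import ExpressionMatrix, SampleSheet
from pairedconcord.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix.from_values(values)


@pytest.fixture
def paired_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "tumour_id": ["t1", "t1"],
                "timepoint": ["first", "second"],
                "study_id": ["S1", "S1"],
                "batch_id": ["b1", "b1"],
                "elapsed_minutes": [None, 30.0],
            }
        )
    )


def make_sheet(n_pairs: int, elapsed=None, study="S1") -> SampleSheet:
    rows = []
    for i in range(n_pairs):
        for tp in ("first", "second"):
            rows.append(
                {
                    "sample_id": f"t{i}_{tp}",
                    "tumour_id": f"t{i}",
                    "timepoint": tp,
                    "study_id": study,
                    "batch_id": "b0",
                    "elapsed_minutes": None if elapsed is None else elapsed[i],
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def make_paired_matrix(first: np.ndarray, second: np.ndarray, prefix="g") -> tuple[ExpressionMatrix, SampleSheet]:
    """Build a matrix + sheet from genes x pairs arrays of both timepoints."""
    g, n = first.shape
    sheet = make_sheet(n)
    cols = {}
    for i in range(n):
        cols[f"t{i}_first"] = first[:, i]
        cols[f"t{i}_second"] = second[:, i]
    values = pd.DataFrame(cols, index=[f"{prefix}{j}" for j in range(g)])
    return ExpressionMatrix.from_values(values), sheet


@pytest.fixture(scope="session")
def default_cohort():
    cfg = SimulationConfig(seed=42, n_tumours=16, n_genes=200)
    return generate_cohort(cfg)
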