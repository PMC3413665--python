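import numpy as np
import pandas as pd
import pytest

from p53risk import simulate
from p53risk.types import AnnotationTable, ExpressionMatrix


@pytest.fixture(scope="session")
def scenario():
    """Small but realistic scenario reused by most integration tests."""
    return simulate.SimulationScenario(
        n_probesets=300,
        n_signature=20,
        n_normal=15,
        n_tumour=15,
        n_patients=150,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def mouse_data(scenario):
    return simulate.simulate_mouse_two_class(scenario)


@pytest.fixture(scope="session")
def probemap(scenario, mouse_data):
    expr, _, _ = mouse_data
    return simulate.simulate_platform_map(
        expr.probeset_ids, probes_per_gene=(1, 2), dropout=0.05, rng_seed=11
    )


@pytest.fixture(scope="session")
def human_data(scenario, probemap):
    return simulate.simulate_human_cohort(scenario, probemap)


@pytest.fixture
def tiny_expr():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [0.0, 0.5, 1.0], [2.0, 2.5, 1.5]],
        index=["p1", "p2", "p3", "p4"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(df, "tiny")


@pytest.fixture
def six_patient_cohort():
    """Toy cohort for partial-likelihood oracle checks."""
    return pd.DataFrame(
        {
            "survival_time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
        },
        index=[f"s{i}" for i in range(6)],
    )


def make_annotation(times, events, sample_ids=None, **clinical):
    n = len(times)
    ids = sample_ids or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(
        {"survival_time": times, "event": events, **clinical},
        index=pd.Index(ids, name="sample_id"),
    )
    return AnnotationTable(df, "test")
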