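import numpy as np
import pandas as pd
import pytest

from panelconcord.io_formats import ExpressionMatrix
from panelconcord.synthetic import (
    PANEL_A,
    PANEL_B,
    SimulationConfig,
    generate_panel_matrix,
    generate_truth,
)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return generate_truth(default_config)


@pytest.fixture(scope="session")
def default_panels(default_config, default_truth):
    """Both simulated panels at the study's default dimensions."""
    mat_a, man_a, meta = generate_panel_matrix(default_truth, default_config, PANEL_A)
    mat_b, man_b, _ = generate_panel_matrix(default_truth, default_config, PANEL_B)
    return {"A": (mat_a, man_a), "B": (mat_b, man_b), "meta": meta}


@pytest.fixture
def small_metadata() -> pd.DataFrame:
    """Four subjects (2 HER2+, 2 HER2-), one with technical+extract replicates."""
    rows = [
        ("S1.e1m1", "S1", "3+", "HER2+", "primary", 1, 1),
        ("S1.e1m2", "S1", "3+", "HER2+", "technical", 1, 2),
        ("S1.e2m1", "S1", "3+", "HER2+", "extract", 2, 3),
        ("S2.e1m1", "S2", "0", "HER2-", "primary", 1, 1),
        ("S3.e1m1", "S3", "2+", "HER2+", "primary", 1, 1),
        ("S4.e1m1", "S4", "1+", "HER2-", "primary", 1, 1),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "subject_id",
            "her2_ihc",
            "group",
            "replicate_kind",
            "extract",
            "order_index",
        ],
    )


def make_matrix(values: np.ndarray, scale="log2", panel="1.5K", prefix="p") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(panel, df, scale)
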