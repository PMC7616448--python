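import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import iegactivity as ia

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_matrix() -> ia.CountMatrix:
    """5 genes x 3 cells with easily hand-checked counts."""
    counts = np.array(
        [
            [5, 0, 1],
            [0, 2, 1],
            [3, 3, 0],
            [0, 0, 4],
            [2, 1, 1],
        ]
    )
    return ia.CountMatrix(
        gene_symbols=["Arc", "Gapdh", "Meg3", "Rbfox3", "Snap25"],
        cell_ids=["c1", "c2", "c3"],
        counts=counts,
    )


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3"],
            "cluster": ["A", "A", "B"],
            "sample": ["s1", "s1", "s2"],
            "condition": ["control", "control", "treated"],
        }
    )


@pytest.fixture(scope="session")
def small_synthetic() -> ia.SyntheticDataset:
    """Small but structured dataset: 2 conditions x 2 samples, 3 clusters."""
    spec = ia.SyntheticSpec(
        n_genes=1200,
        n_ieg=60,
        clusters=(("A", 60), ("B", 60), ("C", 60)),
        samples=(
            ("ctl_1", "control"),
            ("ctl_2", "control"),
            ("trt_1", "treated"),
            ("trt_2", "treated"),
        ),
        marker_genes_per_cluster=30,
        active_fraction={
            ("A", "control"): 0.05,
            ("B", "control"): 0.05,
            ("C", "control"): 0.05,
            ("A", "treated"): 0.05,
            ("B", "treated"): 0.5,
            ("C", "treated"): 0.05,
        },
        seed=11,
    )
    return ia.generate(spec)
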