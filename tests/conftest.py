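"""Shared fixtures: small programmatically generated datasets."""

import numpy as np
import pytest

from netsig.signature import ClassifierParams, ExpressionDataset
from netsig.synthetic import ExprSimConfig, simulate_expression


@pytest.fixture(scope="session")
def small_dataset() -> ExpressionDataset:
    """Separable 60-probe, 10v10 dataset for fast classifier tests."""
    cfg = ExprSimConfig(
        n_probes=60, n_samples_per_group=(10, 10), n_informative=12,
        effect_size=3.0, seed=42,
    )
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def null_dataset() -> ExpressionDataset:
    """No planted signal: 40 probes, 6v6."""
    cfg = ExprSimConfig(
        n_probes=40, n_samples_per_group=(6, 6), n_informative=10,
        effect_size=0.0, seed=7,
    )
    return simulate_expression(cfg)


@pytest.fixture(scope="session")
def default_params() -> ClassifierParams:
    return ClassifierParams(n1=5, n2=5, alpha_filter=0.05)


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """Hand-built 5-probe, 4-sample dataset with known rankings."""
    x = np.array(
        [
            [5.0, 1.0, 5.0, 1.0],
            [4.0, 2.0, 4.0, 2.0],
            [3.0, 3.0, 3.0, 3.0],
            [2.0, 4.0, 2.0, 4.0],
            [1.0, 5.0, 1.0, 5.0],
        ]
    )
    return ExpressionDataset(
        abundance=x,
        probe_ids=[f"p{i}" for i in range(5)],
        sample_ids=["a", "b", "c", "d"],
        group_labels=["G1", "G2", "G1", "G2"],
        probe_to_gene={f"p{i}": f"g{i // 2}" for i in range(5)},
    )
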