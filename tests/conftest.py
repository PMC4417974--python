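"""Shared fixtures: one default-design simulation reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from phytosig import preprocess, simulate as sim
from phytosig import signature as sg
from phytosig.io import ExpressionMatrix


@pytest.fixture(scope="session")
def default_sim():
    """Default study design: 3 vehicle + 4/4/3 treated + 5 comparators, 5000 probes."""
    config = sim.SimulationConfig(seed=0)
    matrix, truth = sim.generate_expression(config)
    probe_map = sim.generate_probe_map(config)
    return config, matrix, truth, probe_map


@pytest.fixture(scope="session")
def adjusted_matrix(default_sim):
    _, matrix, _, _ = default_sim
    return preprocess.adjust_treatment_arm(matrix, preserve_group=True)


@pytest.fixture(scope="session")
def treatment_arm(adjusted_matrix):
    arm = [
        s for s, g in adjusted_matrix.groups().items() if g in ("vehicle", "treated")
    ]
    return adjusted_matrix.subset_samples(arm)


@pytest.fixture(scope="session")
def signature_result(treatment_arm, default_sim):
    _, _, _, probe_map = default_sim
    return sg.run_signature_stage(treatment_arm, probe_map)


@pytest.fixture
def tiny_matrix():
    """3 probes × 4 samples, two groups in one batch."""
    values = np.array(
        [[2.0, 4.0, 6.0, 8.0], [5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]]
    )
    ann = pd.DataFrame(
        {
            "group": ["vehicle", "vehicle", "treated", "treated"],
            "batch": ["B1"] * 4,
            "agent": ["vehicle", "vehicle", "PG2", "PG2"],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(["P1", "P2", "P3"], ["s1", "s2", "s3", "s4"], values, ann)
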