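import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from convoconn.core import FeatureTable
from convoconn.simulate import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_feature_table(
    n_per_group: int = 5,
    n_conversations: int = 2,
    n_features: int = 3,
    separation: float = 0.0,
    seed: int = 0,
) -> FeatureTable:
    """Small hand-rolled feature table (independent of the simulator)."""
    rng = np.random.default_rng(seed)
    rows = []
    values = []
    for g, label in ((0, "case"), (1, "control")):
        for p in range(n_per_group):
            pid = f"{label}{p:02d}"
            shift = separation * (1.0 if g else -1.0) / 2.0
            for k in range(n_conversations):
                rows.append(
                    {
                        "conversation_id": f"{pid}_c{k + 1}",
                        "participant_id": pid,
                        "group": label,
                    }
                )
                values.append(rng.normal(shift, 1.0, size=n_features))
    data = pd.DataFrame(rows)
    cols = tuple(f"f{j}" for j in range(n_features))
    data[list(cols)] = np.asarray(values)
    return FeatureTable(data=data, feature_columns=cols)


@pytest.fixture
def tiny_table() -> FeatureTable:
    return make_feature_table(n_per_group=3, n_conversations=2, n_features=2, seed=1)


@pytest.fixture
def separable_table() -> FeatureTable:
    return make_feature_table(
        n_per_group=5, n_conversations=2, n_features=3, separation=8.0, seed=2
    )


def small_imaging_config(seed: int = 0, **overrides) -> SimulationConfig:
    """30-node imaging config used by the parameter-recovery tests."""
    nodes = pd.DataFrame(
        {
            "node_id": [f"N{i:02d}" for i in range(30)],
            "hemisphere": ["R"] * 15 + ["L"] * 15,
            "x": [1.0] * 15 + [-1.0] * 15,
            "y": [float(i) for i in range(15)] * 2,
            "z": [0.0] * 30,
        }
    )
    defaults = dict(
        seed=seed,
        nodes=nodes,
        compensation_node_set=tuple(f"N{i:02d}" for i in range(0, 6)),
        partner_node_set=tuple(f"N{i:02d}" for i in range(15, 23))
        + tuple(f"N{i:02d}" for i in range(8, 12)),
        overconnected_node_sets={"region_A": tuple(f"N{i:02d}" for i in range(0, 6))},
        n_timepoints=120,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
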