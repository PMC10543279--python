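import numpy as np
import pandas as pd
import pytest

from gcnbsd.fnc import NetworkAtlas, NETWORK_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_network_atlas():
    """Tiny atlas: 3 components in 2 networks (sizes 2 and 1)."""
    return NetworkAtlas(component_ids=(1, 2, 3),
                        network_of={1: "A", 2: "A", 3: "B"},
                        network_order=("A", "B"))


@pytest.fixture
def mini_atlas7():
    """Small 7-network atlas (14 components, 91 edges) for fast cohorts."""
    counts = {"SC": 2, "AU": 1, "SM": 2, "VI": 2, "CC": 3, "DM": 2, "CB": 2}
    mapping = {}
    cid = 1
    for name in NETWORK_ORDER:
        for _ in range(counts[name]):
            mapping[cid] = name
            cid += 1
    return NetworkAtlas(component_ids=tuple(range(1, cid)),
                        network_of=mapping, network_order=NETWORK_ORDER)


def random_symmetric(rng, c, unit_diag=True):
    m = rng.uniform(-1, 1, size=(c, c))
    m = (m + m.T) / 2
    if unit_diag:
        np.fill_diagonal(m, 1.0)
    return m


@pytest.fixture
def tiny_graph_inputs(rng):
    """Aligned arrays for a 10-subject mixed patient/control graph."""
    n, f = 10, 12
    return dict(
        subject_ids=[f"s{i}" for i in range(n)],
        features=rng.normal(size=(n, f)),
        labels=np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0]),
        age_months=rng.uniform(100, 180, size=n),
        gender=np.array(["M", "F"] * 5),
    )


@pytest.fixture
def longitudinal_fixture():
    """Two biotypes, two subjects each; trajectories mirrored across groups
    (a1 == b1, a2 == b2) so every contrast is exactly null but nondegenerate."""
    trajectories = {
        ("a1", 1): [(0, 20.0), (1, 18.0), (4, 12.0), (8, 10.0)],
        ("a2", 1): [(0, 25.0), (1, 24.0), (4, 18.0), (8, 11.0)],
        ("b1", 2): [(0, 20.0), (1, 18.0), (4, 12.0), (8, 10.0)],
        ("b2", 2): [(0, 25.0), (1, 24.0), (4, 18.0), (8, 11.0)],
    }
    rows = []
    for (sid, _), series in trajectories.items():
        for week, score in series:
            rows.append((sid, "RS_Total", week, score))
    records = pd.DataFrame(rows, columns=["subject_id", "scale", "week", "score"])
    pheno = pd.DataFrame({"subject_id": ["a1", "a2", "b1", "b2"],
                          "biotype": [1, 1, 2, 2],
                          "medication": ["MPH", "MPH", "ATX", "ATX"]})
    return records, pheno
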