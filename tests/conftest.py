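import numpy as np
import pandas as pd
import pytest

import coactnet as cn
from coactnet.network import ThresholdedNetwork
from coactnet.simulate import EdgeModification, GroupSpec, SimScenario


def build_network(
    nodes: list[str],
    edges: dict[tuple[str, str], float],
    level: float = 0.05,
    n: int = 9,
    signed: dict[tuple[str, str], float] | None = None,
) -> ThresholdedNetwork:
    """Construct a ThresholdedNetwork directly from an edge dict (tests only)."""
    k = len(nodes)
    idx = {r: i for i, r in enumerate(nodes)}
    w = np.zeros((k, k))
    s = np.zeros((k, k))
    for (a, b), weight in edges.items():
        i, j = idx[a], idx[b]
        w[i, j] = w[j, i] = weight
        sr = (signed or {}).get((a, b), weight)
        s[i, j] = s[j, i] = sr
    return ThresholdedNetwork(
        level=level,
        weight=pd.DataFrame(w, index=nodes, columns=nodes),
        signed_r=pd.DataFrame(s, index=nodes, columns=nodes),
        n=n,
    )


def two_community_scenario(
    n_subjects: int = 10,
    seed: int = 0,
    modifications: tuple[EdgeModification, ...] = (),
    n_regions: int = 10,
) -> SimScenario:
    """Small two-community scenario with a planted hub R0, group B modified."""
    half = n_regions // 2
    names = [f"R{i}" for i in range(n_regions)]
    comms = (tuple(names[:half]), tuple(names[half:]))
    specs = {
        "A": GroupSpec(n_subjects=n_subjects),
        "B": GroupSpec(n_subjects=n_subjects, edge_modifications=modifications),
    }
    return SimScenario(
        communities=comms,
        group_specs=specs,
        base_corr_within=0.7,
        base_corr_between=0.2,
        hub_regions=("R0",),
        hub_corr=0.6,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def catalogue():
    return cn.default_catalogue()


@pytest.fixture(scope="session")
def study_expressions():
    """One draw of the default study-shaped scenario (both groups)."""
    scenario = cn.study_scenario(rng_seed=12345)
    return cn.simulate_expression(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
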