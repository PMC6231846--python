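"""Shared fixtures: small hand-built networks and fast generator configs."""

import pytest
from hypothesis import HealthCheck, settings

import pcanet as pn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_partial() -> pn.PartialNetwork:
    """10 nodes (4 respondents, 6 nonrespondents), 12 observed edges."""
    records = [pn.NodeRecord(f"r{i}", True) for i in range(4)] + [
        pn.NodeRecord(f"n{i}", False, age=20.0 + i if i % 2 else None,
                      city="chicago" if i == 0 else None)
        for i in range(6)
    ]
    edges = [
        ("r0", "r1"), ("r0", "r2"), ("r1", "r3"),
        ("r0", "n0"), ("r0", "n1"), ("r1", "n1"), ("r1", "n2"),
        ("r2", "n2"), ("r2", "n3"), ("r3", "n4"), ("r3", "n5"), ("r0", "n5"),
    ]
    return pn.PartialNetwork(records, edges)


@pytest.fixture
def small_cfg() -> pn.GeneratorConfig:
    """A fast generator config for unit tests (seconds, not minutes)."""
    return pn.GeneratorConfig(
        n_resp=30,
        n_nonresp_pool=120,
        p_rr=0.15,
        sociability_shape=2.0,
        sociability_rate=0.5,
        theta_true=(-3.0, 0.1, 0.4),
        boundary_k=2,
        seed=42,
    )


@pytest.fixture
def small_dataset(small_cfg):
    return pn.generate_dataset(small_cfg)


def star_network(n_leaves: int, prefix: str = "s") -> pn.Network:
    """K_{1,n}: center '<prefix>c' plus leaves; all respondents."""
    records = [pn.NodeRecord(f"{prefix}c", True)] + [
        pn.NodeRecord(f"{prefix}l{i}", True) for i in range(n_leaves)
    ]
    edges = [(f"{prefix}c", f"{prefix}l{i}") for i in range(n_leaves)]
    return pn.Network(records, edges)


def random_network(rng, n: int, p: float, respondents: bool = True) -> pn.Network:
    """Erdos-Renyi complete (fully observed) network on n nodes."""
    ids = [f"v{i:02d}" for i in range(n)]
    records = [pn.NodeRecord(i, respondents) for i in ids]
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return pn.Network(records, edges)


def random_connected_network(rng, n: int, p: float) -> pn.Network:
    """Rejection-sample an Erdos-Renyi graph until connected."""
    import numpy as np
    from scipy.sparse.csgraph import connected_components

    while True:
        net = random_network(rng, n, p)
        ncomp, _ = connected_components(net.adjacency_matrix(), directed=False)
        if ncomp == 1:
            return net
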