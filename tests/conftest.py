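"""Shared fixtures: small synthetic study arms, generated once per session."""

import numpy as np
import pytest

from netfa import SyntheticSpec, simulate_cohorts


def random_digraph(n, p, rng):
    """Random simple digraph as a DirectedCohortGraph."""
    from netfa import build_graph

    nodes = [f"v{i}" for i in range(n)]
    records = [(nodes[i], nodes[j])
               for i in range(n) for j in range(n)
               if i != j and rng.random() < p]
    return build_graph(records, cohort="test", roster=nodes)


def random_connected_undirected(n, rng):
    """Random connected graph, returned as mutual-dyad digraph records."""
    from netfa import build_graph

    nodes = [f"v{i}" for i in range(n)]
    # random spanning tree + extra edges, then symmetrize
    edges = set()
    order = rng.permutation(n)
    for k in range(1, n):
        a, b = order[k], order[rng.integers(0, k)]
        edges.add((int(min(a, b)), int(max(a, b))))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.add((i, j))
    records = []
    for i, j in edges:
        records.append((nodes[i], nodes[j]))
        records.append((nodes[j], nodes[i]))
    return build_graph(records, cohort="test", roster=nodes)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size study spec for fast unit tests (not the study defaults)."""
    return SyntheticSpec(
        cohort_sizes=(60, 60, 60),
        imaged_per_cohort=(14, 13, 13),
        target_mean_degree=(20.0, 18.0, 14.0),
        target_reciprocity=(0.53, 0.49, 0.48),
        tract_counts={"mirroring": 8, "affective": 5},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_spec):
    return simulate_cohorts(small_spec)


@pytest.fixture(scope="session")
def study_cohorts_one_network():
    """Study-size cohorts with the 49-tract network, shared across tests."""
    spec = SyntheticSpec(tract_counts={"mirroring": 49})
    return spec, simulate_cohorts(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
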