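"""Shared fixtures: small deterministic graphs and profile matrices."""

import itertools

import numpy as np
import pytest

from ctdnet import CoPerturbationNetwork, ProfileMatrix


def make_ids(n, prefix="n"):
    return [f"{prefix}{i:02d}" for i in range(n)]


@pytest.fixture
def path_graph():
    """Six-node weighted path n00-n01-...-n05."""
    ids = make_ids(6)
    net = CoPerturbationNetwork(ids)
    weights = [0.9, 0.5, 0.7, 0.3, 0.6]
    for (a, b), w in zip(zip(ids, ids[1:]), weights):
        net.add_edge(a, b, w)
    return net


@pytest.fixture
def clique_in_sparse():
    """A 4-clique (n00..n03) inside a 16-node graph with a sparse tail."""
    ids = make_ids(16)
    net = CoPerturbationNetwork(ids)
    for a, b in itertools.combinations(ids[:4], 2):
        net.add_edge(a, b, 0.8)
    for a, b in zip(ids[4:], ids[5:]):
        net.add_edge(a, b, 0.2)
    net.add_edge(ids[3], ids[4], 0.1)
    return net


@pytest.fixture
def ten_node_fixture_graph():
    """Reproducible random weighted graph on 10 nodes (for walk replay)."""
    ids = make_ids(10)
    rng = np.random.default_rng(42)
    net = CoPerturbationNetwork(ids)
    for a, b in itertools.combinations(ids, 2):
        if rng.random() < 0.35:
            net.add_edge(a, b, float(rng.uniform(-0.9, 0.9)))
    return net


@pytest.fixture
def small_profiles():
    """5 metabolites x 4 samples with two missing cells."""
    z = np.array([
        [1.0, -0.5, 2.5, 0.1],
        [np.nan, 0.3, -1.2, 2.0],
        [0.0, 0.0, 0.0, np.nan],
        [-3.0, 1.5, 0.2, 0.4],
        [2.2, -2.8, 1.1, -0.6],
    ])
    return ProfileMatrix(
        metabolite_ids=[f"m{i}" for i in range(5)],
        sample_ids=[f"s{j}" for j in range(4)],
        z=z,
        missing_mask=np.isnan(z),
    )


def random_profiles(n_met, n_samp, missing_frac, seed, prefix="m"):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_met, n_samp))
    mask = rng.random(z.shape) < missing_frac
    z = z.copy()
    z[mask] = np.nan
    return ProfileMatrix(
        metabolite_ids=[f"{prefix}{i:03d}" for i in range(n_met)],
        sample_ids=[f"s{j:03d}" for j in range(n_samp)],
        z=z,
        missing_mask=mask,
    )
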