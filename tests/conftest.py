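"""Shared fixtures and the independent brute-force cascade oracle."""

from __future__ import annotations

import copy

import networkx as nx
import numpy as np
import pytest

from msgspread.population import Agent, Message


class ScriptedRNG:
    """Stands in for a Generator, replaying a fixed script of uniform draws."""

    def __init__(self, values):
        self._values = list(values)

    def random(self) -> float:
        return self._values.pop(0)

    def standard_normal(self) -> float:  # pragma: no cover - not used in scripts
        raise AssertionError("scripted RNG has no normal draws")


def fixed_agent(
    id=0, a_affective=0.5, a_cognitive=0.5, t_noticing=0.5, t_posting=0.5, profile=None
) -> Agent:
    return Agent(id, a_affective, a_cognitive, t_noticing, t_posting, profile)


def random_instance(rng: np.random.Generator, max_nodes: int = 6):
    """A random small graph plus randomized agent fields, for oracle checks."""
    n = int(rng.integers(1, max_nodes + 1))
    p = rng.uniform(0.2, 0.9)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    placement = {
        v: Agent(
            id=v,
            a_affective=float(rng.random()),
            a_cognitive=float(rng.random()),
            t_noticing=float(rng.random()),
            t_posting=float(rng.random()),
        )
        for v in g.nodes()
    }
    seed_node = int(rng.integers(n))
    return g, placement, seed_node


def oracle_final_state(g: nx.Graph, placement: dict, msg: Message, seed: int):
    """Closed-form final cascade state, independent of the step engine.

    Decision inputs never change during a run, so each agent has a static
    would-forward predicate; the forwarders are exactly the would-forwarders
    connected to the seed through would-forwarding nodes, the receivers are
    the forwarders plus their neighbourhood, and the noticers are the
    receivers whose noticing threshold the message clears (seed included).
    """
    from msgspread.cascade import decides_to_forward, notices

    would = {
        v: v == seed or (notices(msg, placement[v]) and decides_to_forward(msg, placement[v]))
        for v in g.nodes()
    }
    fsub = g.subgraph([v for v in g.nodes() if would[v]])
    forwarded = set(nx.node_connected_component(fsub, seed))
    received = set(forwarded)
    for v in forwarded:
        received.update(g.neighbors(v))
    noticed = {v for v in received if v == seed or notices(msg, placement[v])}
    return received, noticed, forwarded


def clone_placement(placement: dict) -> dict:
    return {v: copy.deepcopy(a) for v, a in placement.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
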