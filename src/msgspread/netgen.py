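"""Network environments: six topologies, structural metrics, agent placement.

All generators return simple undirected :class:`networkx.Graph` objects with
contiguous node ids ``0..n-1`` and are deterministic given the supplied
``numpy.random.Generator``.  The six environments are an Erdős–Rényi G(n, m)
graph, a Barabási–Albert preferential-attachment tree, a Watts–Strogatz
small-world graph, a static-model scale-free graph, a stochastic block model
with ~20 loosely coupled communities, and (optionally) the SNAP ego-Facebook
friendship graph loaded from an edge list and down-sampled by induced
subgraphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from msgspread.population import Agent

__all__ = [
    "NETWORK_TYPES",
    "EdgeListFormatError",
    "NetworkSpec",
    "SBMSpec",
    "assign_agents",
    "avg_clustering",
    "count_communities",
    "generate_barabasi_albert",
    "generate_network",
    "generate_random_graph",
    "generate_sbm",
    "generate_scale_free",
    "generate_watts_strogatz",
    "graph_metrics",
    "induced_subsample",
    "load_edge_list",
    "pick_seed",
    "write_edge_list",
]

NETWORK_TYPES = (
    "random",
    "barabasi_albert",
    "watts_strogatz",
    "scale_free",
    "sbm",
    "facebook",
)


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class SBMSpec:
    """Realised parameters of one stochastic-block-model draw.

    ``weight_matrix[a, b]`` is an affinity: the expected number of neighbours
    a node in block ``a`` has in block ``b``.  Diagonal entries are drawn
    from ``U(0.01, 0.05) * block_size``; off-diagonal entries from
    ``U(0.0001, 0.01)`` with 60% of them zeroed to break the graph into
    disconnected communities.
    """

    n: int
    n_blocks: int
    block_sizes: tuple[int, ...]
    weight_matrix: np.ndarray


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a network environment.

    ``target_edges`` defaults to ``2 * n`` (the edge budget shared by the
    Erdős–Rényi and scale-free generators); ``ws_k`` / ``ws_beta`` configure
    the Watts–Strogatz ring; ``sf_alpha`` is the scale-free weight exponent.
    """

    type: str
    n: int
    ws_k: int = 4
    ws_beta: float = 0.1
    sf_alpha: float = 2.0
    target_edges: Optional[int] = None
    n_blocks: int = 20
    facebook_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in NETWORK_TYPES:
            raise ValueError(
                f"unknown network type {self.type!r}; expected one of {NETWORK_TYPES}"
            )
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def m(self) -> int:
        return self.target_edges if self.target_edges is not None else 2 * self.n


def _nx_seed(rng: np.random.Generator) -> int:
    # networkx generators take an integer seed; derive one from our stream
    return int(rng.integers(0, 2**31 - 1))


def generate_random_graph(n: int, m: int, rng: np.random.Generator) -> nx.Graph:
    """Uniform simple graph with exactly ``n`` nodes and ``m`` edges (G(n, m))."""
    if m > n * (n - 1) // 2:
        raise ValueError(f"m={m} exceeds the {n * (n - 1) // 2} possible edges")
    return nx.gnm_random_graph(n, m, seed=_nx_seed(rng))


def generate_barabasi_albert(n: int, rng: np.random.Generator) -> nx.Graph:
    """Preferential attachment from a single root, one edge per new node.

    The result is a tree: ``n - 1`` edges, connected, no triangles.
    """
    if n < 2:
        raise ValueError("Barabási–Albert growth needs n >= 2")
    return nx.barabasi_albert_graph(n, 1, seed=_nx_seed(rng))


def generate_watts_strogatz(
    n: int, k: int, beta: float, rng: np.random.Generator
) -> nx.Graph:
    """Ring lattice with ``k`` nearest neighbours, each edge rewired w.p. ``beta``.

    Rewiring avoids self-loops and duplicate edges, so the edge count stays
    exactly ``n * k / 2``.
    """
    if k % 2 != 0 or not 0 < k < n:
        raise ValueError("watts-strogatz requires an even k with 0 < k < n")
    return nx.watts_strogatz_graph(n, k, beta, seed=_nx_seed(rng))


def generate_scale_free(
    n: int, m: int, alpha: float, rng: np.random.Generator
) -> nx.Graph:
    """Static-model scale-free graph with exactly ``m`` edges.

    Node ``i`` (1-based) carries weight ``i ** (-1 / (alpha - 1))``; endpoint
    pairs are sampled with probability proportional to the weight product and
    accepted until ``m`` distinct simple edges exist.  Larger ``alpha``
    flattens the weights toward a uniform G(n, m) graph.
    """
    max_edges = n * (n - 1) // 2
    if m > max_edges:
        raise ValueError(f"m={m} exceeds the {max_edges} possible edges")
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1")
    weights = np.arange(1, n + 1, dtype=float) ** (-1.0 / (alpha - 1.0))
    p = weights / weights.sum()
    edges: set[tuple[int, int]] = set()
    while len(edges) < m:
        batch = 2 * (m - len(edges)) + 16
        us = rng.choice(n, size=batch, p=p)
        vs = rng.choice(n, size=batch, p=p)
        for u, v in zip(us.tolist(), vs.tolist()):
            if u == v:
                continue
            e = (u, v) if u < v else (v, u)
            if e not in edges:
                edges.add(e)
                if len(edges) == m:
                    break
    g = nx.empty_graph(n)
    g.add_edges_from(edges)
    return g


def _largest_remainder_sizes(n: int, shares: np.ndarray) -> list[int]:
    raw = n * shares / shares.sum()
    sizes = np.floor(raw).astype(int)
    remainder = raw - sizes
    shortfall = n - int(sizes.sum())
    for idx in np.argsort(-remainder)[:shortfall]:
        sizes[idx] += 1
    # SBM blocks must be non-empty; borrow from the largest block if needed
    while (sizes == 0).any():
        sizes[int(np.argmin(sizes))] += 1
        sizes[int(np.argmax(sizes))] -= 1
    return sizes.tolist()


def generate_sbm(
    n: int, n_blocks: int, rng: np.random.Generator
) -> tuple[nx.Graph, SBMSpec]:
    """Stochastic block model with random block sizes and a sparse affinity matrix.

    Block sizes are ``n`` split proportionally to ``n_blocks`` uniform draws
    (largest-remainder rounding).  The affinity matrix ``W`` holds expected
    neighbour counts; 60% of its off-diagonal entries are zeroed so that the
    graph falls apart into several components.  Edges are realised by
    translating affinities to independent per-pair probabilities.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n_blocks > n:
        raise ValueError("more blocks than nodes")
    sizes = _largest_remainder_sizes(n, rng.uniform(size=n_blocks))

    w = np.zeros((n_blocks, n_blocks))
    for b, size in enumerate(sizes):
        w[b, b] = rng.uniform(0.01, 0.05) * size
    iu, ju = np.triu_indices(n_blocks, k=1)
    offdiag = rng.uniform(0.0001, 0.01, size=iu.size)
    n_zero = int(math.floor(0.6 * iu.size))
    zero_idx = rng.choice(iu.size, size=n_zero, replace=False)
    offdiag[zero_idx] = 0.0
    w[iu, ju] = offdiag
    w[ju, iu] = offdiag

    # affinity -> per-pair probability: a block-a node expects w[a,b]
    # neighbours in block b, so the expected a-b edge count is
    # w[a,b] * (size_a + size_b) / 2 spread over size_a * size_b pairs
    probs = np.zeros_like(w)
    for a in range(n_blocks):
        for b in range(a, n_blocks):
            if a == b:
                pairs = sizes[a] - 1
                probs[a, a] = min(1.0, w[a, a] / pairs) if pairs > 0 else 0.0
            else:
                expected = w[a, b] * (sizes[a] + sizes[b]) / 2.0
                probs[a, b] = probs[b, a] = min(
                    1.0, expected / (sizes[a] * sizes[b])
                )
    g = nx.stochastic_block_model(sizes, probs.tolist(), seed=_nx_seed(rng))
    g = nx.convert_node_labels_to_integers(nx.Graph(g))
    spec = SBMSpec(n=n, n_blocks=n_blocks, block_sizes=tuple(sizes), weight_matrix=w)
    return g, spec


def load_edge_list(path) -> nx.Graph:
    """Read a SNAP-style undirected edge list (two integer ids per line).

    Self-loops and duplicate edges are dropped; node ids are compacted to
    ``0..n-1`` in order of first appearance.
    """
    relabel: dict[int, int] = {}
    g = nx.Graph()

    def canonical(raw: int) -> int:
        if raw not in relabel:
            relabel[raw] = len(relabel)
            g.add_node(relabel[raw])
        return relabel[raw]

    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected two node ids, got {line!r}"
                )
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: non-integer node id in {line!r}"
                ) from None
            n_lines += 1
            if u == v:
                continue
            g.add_edge(canonical(u), canonical(v))
    if n_lines == 0:
        raise EdgeListFormatError(f"{path}: no edges found")
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a graph in the same two-column plain-text format."""
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u} {v}\n")


def induced_subsample(g: nx.Graph, n: int, rng: np.random.Generator) -> nx.Graph:
    """Induced subgraph on a uniform sample of ``n`` nodes, ids compacted."""
    if n > g.number_of_nodes():
        raise ValueError(
            f"cannot sample {n} nodes from a graph with {g.number_of_nodes()}"
        )
    nodes = rng.choice(np.asarray(g.nodes()), size=n, replace=False)
    sub = g.subgraph(nodes.tolist())
    return nx.convert_node_labels_to_integers(sub, ordering="sorted")


def avg_clustering(g: nx.Graph) -> float:
    """Mean local clustering coefficient (degree < 2 nodes contribute 0)."""
    if g.number_of_nodes() == 0:
        raise ValueError("average clustering of an empty graph is undefined")
    return nx.average_clustering(g, count_zeros=True)


def count_communities(g: nx.Graph) -> int:
    """Number of connected components."""
    return nx.number_connected_components(g)


def count_communities_modularity(g: nx.Graph, rng=None) -> int:
    """Alternative community count via greedy modularity maximisation."""
    if g.number_of_edges() == 0:
        return g.number_of_nodes()
    return len(nx.community.greedy_modularity_communities(g))


def assign_agents(
    agents: Sequence[Agent], g: nx.Graph, mode: str = "identity"
) -> dict[int, Agent]:
    """Place agents on nodes.

    ``identity`` puts agent ``i`` on node ``i``.  ``extraversion_rank``
    matches agents sorted by extraversion to nodes sorted by degree (the most
    extraverted agent occupies the best-connected node), ties broken by id —
    extraverted people hold more social ties, so they get the hubs.
    """
    if len(agents) != g.number_of_nodes():
        raise ValueError(
            f"{len(agents)} agents cannot populate {g.number_of_nodes()} nodes"
        )
    if mode == "identity":
        return {node: agents[i] for i, node in enumerate(sorted(g.nodes()))}
    if mode == "extraversion_rank":
        if any(ag.profile is None for ag in agents):
            raise ValueError("extraversion_rank placement needs personality agents")
        nodes = sorted(g.nodes(), key=lambda v: (-g.degree(v), v))
        ranked = sorted(agents, key=lambda ag: (-ag.profile.extraversion, ag.id))
        return dict(zip(nodes, ranked))
    raise ValueError(
        f"unknown assignment mode {mode!r}; expected 'identity' or 'extraversion_rank'"
    )


def pick_seed(g: nx.Graph, method: str = "degree") -> int:
    """The node the cascade starts from: the most central one.

    Degree centrality by default (betweenness available); ties broken by
    smallest node id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot pick a seed in an empty graph")
    if method == "degree":
        scores = dict(g.degree())
    elif method == "betweenness":
        scores = nx.betweenness_centrality(g)
    else:
        raise ValueError(f"unknown centrality {method!r}")
    return min(scores, key=lambda v: (-scores[v], v))


def graph_metrics(g: nx.Graph) -> dict[str, float]:
    """Edge count, average clustering, and component count for reporting."""
    return {
        "edges": g.number_of_edges(),
        "avg_clustering": avg_clustering(g),
        "components": count_communities(g),
    }


def generate_network(spec: NetworkSpec, rng: np.random.Generator) -> nx.Graph:
    """Realise one network environment from its spec.

    For ``facebook``, the edge list at ``spec.facebook_path`` is loaded and,
    if it holds more than ``spec.n`` nodes, down-sampled to an induced
    subgraph on ``spec.n`` uniformly chosen nodes.
    """
    if spec.type == "random":
        return generate_random_graph(spec.n, spec.m, rng)
    if spec.type == "barabasi_albert":
        return generate_barabasi_albert(spec.n, rng)
    if spec.type == "watts_strogatz":
        return generate_watts_strogatz(spec.n, spec.ws_k, spec.ws_beta, rng)
    if spec.type == "scale_free":
        return generate_scale_free(spec.n, spec.m, spec.sf_alpha, rng)
    if spec.type == "sbm":
        g, _ = generate_sbm(spec.n, spec.n_blocks, rng)
        return g
    if spec.type == "facebook":
        if spec.facebook_path is None:
            raise ValueError("facebook networks need facebook_path set")
        g = load_edge_list(spec.facebook_path)
        if spec.n < g.number_of_nodes():
            g = induced_subsample(g, spec.n, rng)
        return g
    raise ValueError(f"unknown network type {spec.type!r}")
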