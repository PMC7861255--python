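import networkx as nx
import numpy as np
import pytest
from scipy import stats

from msgspread.netgen import (
    EdgeListFormatError,
    NetworkSpec,
    assign_agents,
    avg_clustering,
    count_communities,
    generate_barabasi_albert,
    generate_network,
    generate_random_graph,
    generate_sbm,
    generate_scale_free,
    generate_watts_strogatz,
    induced_subsample,
    load_edge_list,
    pick_seed,
    write_edge_list,
)
from msgspread.population import PersonalityProfile, make_population

from conftest import fixed_agent


def _gen(name, n, rng):
    if name == "random":
        return generate_random_graph(n, 2 * n, rng)
    if name == "barabasi_albert":
        return generate_barabasi_albert(n, rng)
    if name == "watts_strogatz":
        return generate_watts_strogatz(n, 4, 0.1, rng)
    if name == "scale_free":
        return generate_scale_free(n, 2 * n, 2.0, rng)
    if name == "sbm":
        return generate_sbm(n, 10, rng)[0]
    raise AssertionError(name)


GENERATORS = ["random", "barabasi_albert", "watts_strogatz", "scale_free", "sbm"]


@pytest.mark.parametrize("name", GENERATORS)
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_generators_yield_simple_graphs_of_requested_size(name, seed):
    n = 200
    g = _gen(name, n, np.random.default_rng(seed))
    assert g.number_of_nodes() == n
    assert sorted(g.nodes()) == list(range(n))
    assert nx.number_of_selfloops(g) == 0
    expected = {
        "random": 2 * n,
        "barabasi_albert": n - 1,
        "watts_strogatz": 2 * n,
        "scale_free": 2 * n,
    }
    if name in expected:
        assert g.number_of_edges() == expected[name]


@pytest.mark.parametrize("name", GENERATORS)
def test_generator_determinism(name):
    g1 = _gen(name, 150, np.random.default_rng(7))
    g2 = _gen(name, 150, np.random.default_rng(7))
    assert set(g1.edges()) == set(g2.edges())


def test_gnm_full_budget_is_complete_graph(rng):
    g = generate_random_graph(4, 6, rng)
    assert nx.is_isomorphic(g, nx.complete_graph(4))


def test_gnm_rejects_infeasible_edge_count(rng):
    with pytest.raises(ValueError):
        generate_random_graph(4, 7, rng)


def test_barabasi_albert_is_a_tree(rng):
    g = generate_barabasi_albert(500, rng)
    assert nx.is_tree(g)
    assert avg_clustering(g) == 0.0
    assert count_communities(g) == 1


def test_watts_strogatz_lattice_clustering(rng):
    # unrewired ring lattice at k=4: closed form 3(k-2)/(4(k-1)) = 0.5
    g = generate_watts_strogatz(400, 4, 0.0, rng)
    assert avg_clustering(g) == pytest.approx(0.5)


def test_watts_strogatz_rejects_odd_k(rng):
    with pytest.raises(ValueError):
        generate_watts_strogatz(100, 3, 0.1, rng)


def test_rewiring_shortens_paths(rng):
    def mean_path(beta):
        g = generate_watts_strogatz(500, 4, beta, rng)
        cc = g.subgraph(max(nx.connected_components(g), key=len))
        return nx.average_shortest_path_length(cc)

    assert mean_path(1.0) < mean_path(0.0)


def test_scale_free_has_heavier_degree_tail_than_gnm(rng):
    sf_var, er_var = [], []
    for _ in range(15):
        sf = generate_scale_free(400, 800, 2.0, rng)
        er = generate_random_graph(400, 800, rng)
        sf_var.append(np.var([d for _, d in sf.degree()]))
        er_var.append(np.var([d for _, d in er.degree()]))
    assert np.mean(sf_var) > np.mean(er_var)


def test_scale_free_large_alpha_approaches_gnm(rng):
    """alpha -> inf flattens the weights, so degrees look Poissonian."""
    g = generate_scale_free(2000, 4000, 1e9, rng)
    degrees = np.array([d for _, d in g.degree()])
    er = generate_random_graph(2000, 4000, rng)
    er_degrees = np.array([d for _, d in er.degree()])
    assert stats.ks_2samp(degrees, er_degrees).pvalue > 0.01


def test_sbm_block_sizes_and_sparsity(rng):
    for _ in range(5):
        g, spec = generate_sbm(1000, 20, rng)
        assert sum(spec.block_sizes) == 1000
        w = spec.weight_matrix
        off = w[~np.eye(20, dtype=bool)]
        n_offpairs = 20 * 19 // 2
        assert int((off == 0).sum()) == 2 * int(np.floor(0.6 * n_offpairs))
        diag = np.diag(w)
        sizes = np.array(spec.block_sizes)
        assert ((diag >= 0.01 * sizes) & (diag <= 0.05 * sizes)).all()
        nonzero_off = off[off > 0]
        assert ((nonzero_off >= 0.0001) & (nonzero_off <= 0.01)).all()


def test_sbm_usually_disconnected(rng):
    multi = sum(
        count_communities(generate_sbm(1000, 20, rng)[0]) > 1 for _ in range(25)
    )
    assert multi > 12


def test_sbm_rejects_more_blocks_than_nodes(rng):
    with pytest.raises(ValueError):
        generate_sbm(10, 20, rng)


def test_load_edge_list_drops_duplicates_and_self_loops(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("0 1\n1 0\n1 1\n")
    g = load_edge_list(path)
    assert (g.number_of_nodes(), g.number_of_edges()) == (2, 1)


def test_load_edge_list_components(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("0 1\n2 3\n")
    g = load_edge_list(path)
    assert (g.number_of_nodes(), g.number_of_edges()) == (4, 2)
    assert count_communities(g) == 2


def test_load_edge_list_compacts_ids_by_first_appearance(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("10 30\n30 20\n")
    g = load_edge_list(path)
    assert set(g.edges()) == {(0, 1), (1, 2)}


def test_load_edge_list_reports_malformed_line(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("0 1\n0 1 2\n")
    with pytest.raises(EdgeListFormatError, match=":2"):
        load_edge_list(path)
    path.write_text("")
    with pytest.raises(EdgeListFormatError):
        load_edge_list(path)


def test_edge_list_round_trip(tmp_path, rng):
    # the loader compacts ids by first appearance, so the round trip is
    # guaranteed only up to relabelling
    g = generate_watts_strogatz(50, 4, 0.2, rng)  # no isolated nodes
    path = tmp_path / "graph.txt"
    write_edge_list(g, path)
    back = load_edge_list(path)
    assert back.number_of_nodes() == g.number_of_nodes()
    assert back.number_of_edges() == g.number_of_edges()
    assert sorted(d for _, d in back.degree()) == sorted(d for _, d in g.degree())

    path.write_text("0 1\n1 2\n2 3\n")  # first appearance == numeric order
    assert set(load_edge_list(path).edges()) == {(0, 1), (1, 2), (2, 3)}


def test_full_subsample_preserves_graph(rng):
    g = generate_random_graph(40, 80, rng)
    sub = induced_subsample(g, 40, rng)
    assert set(sub.edges()) == {tuple(sorted(e)) for e in g.edges()}
    with pytest.raises(ValueError):
        induced_subsample(g, 41, rng)


def test_subsample_edge_count_matches_inclusion_probability(rng):
    # each edge survives with probability (n/N) * ((n-1)/(N-1))
    g = generate_random_graph(60, 120, rng)
    n, N = 30, 60
    expected = 120 * (n / N) * ((n - 1) / (N - 1))
    counts = [induced_subsample(g, n, rng).number_of_edges() for _ in range(300)]
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expected) < 4 * se + 1e-9


@pytest.mark.parametrize(
    "graph, expected",
    [
        (nx.complete_graph(3), 1.0),
        (nx.star_graph(5), 0.0),
    ],
)
def test_avg_clustering_known_graphs(graph, expected):
    assert avg_clustering(graph) == pytest.approx(expected)


def test_avg_clustering_k4_minus_edge():
    # degree-2 nodes: their two neighbours are linked -> 1 each;
    # degree-3 nodes: two of three neighbour pairs linked -> 2/3 each
    g = nx.complete_graph(4)
    g.remove_edge(0, 1)
    assert avg_clustering(g) == pytest.approx((1 + 1 + 2 / 3 + 2 / 3) / 4)


def test_avg_clustering_rejects_empty_graph():
    with pytest.raises(ValueError):
        avg_clustering(nx.Graph())


def test_count_communities_isolated_nodes():
    assert count_communities(nx.empty_graph(7)) == 7
    assert count_communities(nx.path_graph(7)) == 1


def test_identity_assignment(rng):
    g = nx.path_graph(5)
    agents = make_population(5, "random", rng)
    placement = assign_agents(agents, g, "identity")
    assert all(placement[i].id == i for i in range(5))


def _personality_agents(n, extraversions):
    return [
        fixed_agent(id=i, profile=PersonalityProfile(0.5, 0.5, e, 0.5, 0.5))
        for i, e in enumerate(extraversions)
    ]


def test_extraversion_rank_puts_most_extraverted_on_hub():
    g = nx.star_graph(4)  # node 0 is the hub
    agents = _personality_agents(5, [0.1, 0.9, 0.4, 0.2, 0.3])
    placement = assign_agents(agents, g, "extraversion_rank")
    assert placement[0].profile.extraversion == 0.9


def test_extraversion_rank_is_degree_monotone(rng):
    g = generate_barabasi_albert(60, rng)
    agents = _personality_agents(60, list(np.random.default_rng(5).random(60)))
    placement = assign_agents(agents, g, "extraversion_rank")
    for u in g.nodes():
        for v in g.nodes():
            if g.degree(u) > g.degree(v):
                assert placement[u].profile.extraversion >= placement[v].profile.extraversion


def test_extraversion_rank_requires_profiles(rng):
    g = nx.path_graph(3)
    agents = make_population(3, "random", rng)
    with pytest.raises(ValueError):
        assign_agents(agents, g, "extraversion_rank")
    with pytest.raises(ValueError):
        assign_agents(agents[:2], g, "identity")


@pytest.mark.parametrize(
    "graph, expected",
    [
        (nx.star_graph(6), 0),
        (nx.path_graph(3), 1),
        (nx.cycle_graph(8), 0),  # all degrees tie -> smallest id
    ],
)
def test_pick_seed(graph, expected):
    assert pick_seed(graph) == expected


def test_pick_seed_betweenness_on_star():
    assert pick_seed(nx.star_graph(6), method="betweenness") == 0


def test_pick_seed_rejects_empty_graph():
    with pytest.raises(ValueError):
        pick_seed(nx.Graph())


def test_network_spec_validation():
    with pytest.raises(ValueError):
        NetworkSpec(type="smallworld", n=10)
    spec = NetworkSpec(type="facebook", n=10)
    with pytest.raises(ValueError):
        generate_network(spec, np.random.default_rng(0))


def test_generate_network_dispatch(rng):
    for name in GENERATORS:
        spec = NetworkSpec(type=name, n=100, n_blocks=5)
        g = generate_network(spec, rng)
        assert g.number_of_nodes() == 100
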