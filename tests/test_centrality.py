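"""Shortest-path census, betweenness, closeness, Spearman."""

import numpy as np
import pytest
import networkx as nx

from _oracles import brute_betweenness, brute_closeness, random_diagram

from cldnet import (CLDError, betweenness_centrality, closeness_centrality,
                    exogenous_variables, parse_edge_tables,
                    single_source_shortest_paths, spearman_rank_correlation)


def test_census_chain(chain):
    census = single_source_shortest_paths(chain, "A")
    assert census.distance == {"A": 0, "B": 1, "C": 2}
    assert census.path_count == {"A": 1, "B": 1, "C": 1}


def test_census_diamond_counts_parallel_paths(diamond):
    census = single_source_shortest_paths(diamond, "A")
    assert census.path_count["D"] == 2
    assert census.distance["D"] == 2


def test_census_unreachable_targets_absent(chain):
    census = single_source_shortest_paths(chain, "C")
    assert census.distance == {"C": 0}
    assert census.path_count == {"C": 1}


def test_census_unknown_source(chain):
    with pytest.raises(CLDError, match="unknown source"):
        single_source_shortest_paths(chain, "Z")


def test_census_matches_exhaustive_enumeration(rng):
    from _oracles import adjacency, all_shortest_paths
    for _ in range(25):
        d = random_diagram(rng, n_max=7)
        adj = adjacency(d)
        for source in d.variable_names():
            census = single_source_shortest_paths(d, source)
            for target in d.variable_names():
                if target == source:
                    continue
                paths = all_shortest_paths(adj, source, target)
                if not paths:
                    assert target not in census.distance
                else:
                    assert census.distance[target] == len(paths[0]) - 1
                    assert census.path_count[target] == len(paths)


def test_betweenness_three_node_chain(chain):
    bc = betweenness_centrality(chain)
    # one ordered pair (A,C) routes through B; normalization 1/((3-1)(3-2))
    assert bc == {"A": 0.0, "B": 0.5, "C": 0.0}


def test_betweenness_requires_three_variables():
    d = parse_edge_tables([("A", "B", "+")], [("A", "brain"), ("B", "brain")])
    with pytest.raises(CLDError, match=">= 3"):
        betweenness_centrality(d)


def test_betweenness_in_degree_zero_is_zero(rng):
    from cldnet import GeneratorSpec, generate_random_cld
    for seed in range(5):
        d = generate_random_cld(GeneratorSpec(n_variables=12, n_connections=40,
                                              n_exogenous=3, seed=seed))
        bc = betweenness_centrality(d)
        for v in exogenous_variables(d):
            assert bc[v] == 0.0


def test_betweenness_matches_brute_force_and_networkx(rng):
    for _ in range(60):
        d = random_diagram(rng, n_max=6)
        bc = betweenness_centrality(d)
        oracle = brute_betweenness(d)
        assert bc.keys() == oracle.keys()
        for v in bc:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-12)
        nx_bc = nx.betweenness_centrality(d.to_networkx(), normalized=True)
        for v in bc:
            assert bc[v] == pytest.approx(nx_bc[v], abs=1e-12)


def test_edge_without_new_shortest_paths_leaves_bc_unchanged():
    # E has no incoming edges and D no outgoing ones, so adding E->D creates
    # exactly one new shortest path (the edge itself, with no interior
    # vertices) and disturbs no other pair's census
    variables = [(v, "brain") for v in "ABCDE"]
    chain_edges = [("A", "B", "+"), ("B", "C", "+"), ("C", "D", "+")]
    base = parse_edge_tables(chain_edges, variables)
    extended = parse_edge_tables(chain_edges + [("E", "D", "+")], variables)
    bc_base = brute_betweenness(base)
    bc_ext = betweenness_centrality(extended)
    for v in "ABCDE":
        assert bc_ext[v] == pytest.approx(bc_base[v], abs=1e-12)


def test_closeness_chain(chain):
    cc = closeness_centrality(chain)
    assert cc == {"A": pytest.approx(2 / 3), "B": 1.0, "C": 0.0}


def test_closeness_isolated_variable_zero():
    d = parse_edge_tables([("A", "B", "+")],
                          [("A", "brain"), ("B", "brain"), ("Z", "brain")])
    assert closeness_centrality(d)["Z"] == 0.0


def test_closeness_clique_all_one():
    names = list("ABCD")
    edges = [(u, v, "+") for u in names for v in names if u != v]
    d = parse_edge_tables(edges, [(v, "brain") for v in names])
    assert set(closeness_centrality(d).values()) == {1.0}


def test_closeness_unknown_variant(chain):
    with pytest.raises(CLDError, match="variant"):
        closeness_centrality(chain, "harmonic")


def test_closeness_variants_coincide_when_strongly_connected():
    names = list("ABC")
    edges = [("A", "B", "+"), ("B", "C", "+"), ("C", "A", "+")]
    d = parse_edge_tables(edges, [(v, "brain") for v in names])
    assert closeness_centrality(d, "as_printed") == \
        closeness_centrality(d, "wf_scaled")


@pytest.mark.parametrize("variant", ["as_printed", "wf_scaled"])
def test_closeness_matches_brute_force_and_networkx(rng, variant):
    wf = variant == "wf_scaled"
    for _ in range(40):
        d = random_diagram(rng, n_max=6)
        cc = closeness_centrality(d, variant)
        oracle = brute_closeness(d, variant)
        nx_cc = nx.closeness_centrality(d.to_networkx().reverse(),
                                        wf_improved=wf)
        for v in cc:
            assert cc[v] == pytest.approx(oracle[v], abs=1e-12)
            assert cc[v] == pytest.approx(nx_cc[v], abs=1e-12)


def test_centrality_is_polarity_blind(rng):
    from dataclasses import replace
    from cldnet import CausalLoopDiagram
    d = random_diagram(rng, n_max=6)
    flipped = CausalLoopDiagram(
        variables=list(d.variables),
        connections=[replace(c, polarity=-c.polarity) for c in d.connections])
    assert betweenness_centrality(d) == betweenness_centrality(flipped)
    assert closeness_centrality(d) == closeness_centrality(flipped)


def test_spearman_identity_and_reversal():
    a = {"a": 0.1, "b": 0.5, "c": 0.3, "d": 0.9}
    assert spearman_rank_correlation(a, a) == pytest.approx(1.0)
    reversed_map = {k: -v for k, v in a.items()}
    assert spearman_rank_correlation(a, reversed_map) == pytest.approx(-1.0)


def test_spearman_with_ties_matches_rank_pearson():
    a = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 4.0, "e": 5.0}
    b = {"a": 3.0, "b": 1.0, "c": 4.0, "d": 4.0, "e": 2.0}
    # average ranks (ties get mean rank), then Pearson on the ranks
    ra = np.array([1, 2.5, 2.5, 4, 5])
    rb = np.array([3, 1, 4.5, 4.5, 2])
    expected = np.corrcoef(ra, rb)[0, 1]
    assert spearman_rank_correlation(a, b) == pytest.approx(expected)


def test_spearman_input_validation():
    a = {"a": 1.0, "b": 2.0, "c": 3.0}
    with pytest.raises(CLDError, match="key sets"):
        spearman_rank_correlation(a, {"a": 1.0, "b": 2.0, "z": 3.0})
    with pytest.raises(CLDError, match=">= 3"):
        spearman_rank_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
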