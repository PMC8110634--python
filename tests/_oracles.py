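"""Independent brute-force oracles used by the test suite.

Everything here enumerates exhaustively (simple paths, vertex permutations)
and stays deliberately independent of the package's BFS/Brandes/DFS code
paths it is used to check.  Only practical for diagrams of ~6 variables.
"""

from itertools import permutations

import numpy as np

from cldnet import CausalLoopDiagram, parse_edge_tables


def adjacency(diagram: CausalLoopDiagram) -> dict[str, list[str]]:
    adj = {v.name: [] for v in diagram.variables}
    for c in diagram.connections:
        adj[c.source].append(c.target)
    return adj


def all_shortest_paths(adj, s, t):
    """Every shortest simple s->t path, by exhaustive DFS enumeration."""
    found = []

    def dfs(path):
        u = path[-1]
        for w in adj[u]:
            if w == t:
                found.append(path + [w])
            elif w not in path:
                dfs(path + [w])

    dfs([s])
    if not found:
        return []
    shortest = min(len(p) for p in found)
    return [p for p in found if len(p) == shortest]


def brute_betweenness(diagram: CausalLoopDiagram) -> dict[str, float]:
    adj = adjacency(diagram)
    names = list(adj)
    n = len(names)
    acc = dict.fromkeys(names, 0.0)
    for s in names:
        for t in names:
            if s == t:
                continue
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in names:
                if v in (s, t):
                    continue
                acc[v] += sum(v in p for p in paths) / len(paths)
    return {v: acc[v] / ((n - 1) * (n - 2)) for v in names}


def brute_closeness(diagram: CausalLoopDiagram, variant="as_printed"):
    adj = adjacency(diagram)
    names = list(adj)
    cc = {}
    for v in names:
        dists = {}
        for u in names:
            if u == v:
                continue
            paths = all_shortest_paths(adj, v, u)
            if paths:
                dists[u] = len(paths[0]) - 1
        if not dists:
            cc[v] = 0.0
            continue
        value = len(dists) / sum(dists.values())
        if variant == "wf_scaled":
            value *= len(dists) / (len(names) - 1)
        cc[v] = value
    return cc


def brute_cycles(diagram: CausalLoopDiagram, max_length: int) -> set[tuple[str, ...]]:
    """Simple directed cycles as canonical member tuples, via permutations."""
    edges = diagram.edge_set()
    names = diagram.variable_names()
    cycles = set()
    for k in range(2, max_length + 1):
        for perm in permutations(names, k):
            if perm[0] != min(perm):
                continue  # canonical rotation only
            if all((perm[i], perm[(i + 1) % k]) in edges for i in range(k)):
                cycles.add(perm)
    return cycles


def random_diagram(rng: np.random.Generator, n_max=6, edge_prob=0.35):
    """A small random signed digraph for oracle-equivalence checks."""
    n = int(rng.integers(3, n_max + 1))
    names = [f"n{i}" for i in range(n)]
    edge_rows = []
    for u in names:
        for v in names:
            if u != v and rng.random() < edge_prob:
                edge_rows.append((u, v, "+" if rng.random() < 0.7 else "-"))
    var_rows = [(name, "brain") for name in names]
    return parse_edge_tables(edge_rows, var_rows)
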