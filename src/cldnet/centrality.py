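"""Shortest-path centrality for causal loop diagrams.

All measures treat the diagram as an unweighted digraph and ignore edge
polarity: a shortest path is a sequence of connections with the fewest
mediating variables, which in a qualitative causal map is the pathway least
exposed to interference.

Betweenness of a variable v is the fraction of shortest paths between other
ordered pairs that pass through v, normalized by (N-1)(N-2) with N the
variable count, so values lie in [0, 1].  Endpoints are excluded from the
sum (s != v != t); an in-degree-zero variable therefore scores exactly 0.

Closeness of v is outward: the number of variables reachable from v divided
by the sum of shortest-path distances from v to them ("as_printed").  The
Wasserman-Faust variant additionally scales by (reachable count)/(N-1) to
penalize small reachable sets on disconnected diagrams.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .core import CausalLoopDiagram, CLDError

CLOSENESS_VARIANTS = ("as_printed", "wf_scaled")


@dataclass(frozen=True)
class PathCensus:
    """Single-source BFS census: hop distances and shortest-path counts.

    Unreachable targets are absent from both maps; ``path_count[t]`` is the
    number of distinct shortest source->t paths.
    """

    source: str
    distance: dict[str, int]
    path_count: dict[str, int]


@dataclass(frozen=True)
class CentralityResult:
    betweenness: dict[str, float]
    closeness: dict[str, float]
    closeness_variant: str
    n_variables: int


def single_source_shortest_paths(
    diagram: CausalLoopDiagram, source: str
) -> PathCensus:
    """BFS from ``source`` along directed edges, counting shortest paths."""
    adj = diagram.successors()
    if source not in adj:
        raise CLDError(f"unknown source variable: {source!r}")
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return PathCensus(source=source, distance=dist, path_count=sigma)


def betweenness_centrality(diagram: CausalLoopDiagram) -> dict[str, float]:
    """Normalized betweenness, BC_v = sum over ordered pairs s != t (both
    distinct from v) of sigma(s,t|v)/sigma(s,t), divided by (N-1)(N-2).

    Pairs with no connecting path contribute 0.  Requires N >= 3 for the
    normalization to be defined.
    """
    names = diagram.variable_names()
    n = len(names)
    if n < 3:
        raise CLDError(f"betweenness normalization needs >= 3 variables, got {n}")
    adj = diagram.successors()
    bc = dict.fromkeys(names, 0.0)

    # Brandes' dependency accumulation, one BFS per source.
    for s in names:
        stack: list[str] = []
        preds: dict[str, list[str]] = {v: [] for v in names}
        dist = {s: 0}
        sigma = dict.fromkeys(names, 0)
        sigma[s] = 1
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        delta = dict.fromkeys(names, 0.0)
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]

    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: bc[v] * scale for v in names}


def closeness_centrality(
    diagram: CausalLoopDiagram, variant: str = "as_printed"
) -> dict[str, float]:
    """Outward closeness per variable; a variable reaching nothing gets 0."""
    if variant not in CLOSENESS_VARIANTS:
        raise CLDError(f"unknown closeness variant: {variant!r} "
                       f"(expected one of {CLOSENESS_VARIANTS})")
    names = diagram.variable_names()
    big_n = len(names)
    cc: dict[str, float] = {}
    for v in names:
        census = single_source_shortest_paths(diagram, v)
        reachable = len(census.distance) - 1  # excludes v itself
        if reachable == 0:
            cc[v] = 0.0
            continue
        total = sum(census.distance.values())
        value = reachable / total
        if variant == "wf_scaled" and big_n > 1:
            value *= reachable / (big_n - 1)
        cc[v] = value
    return cc


def centrality_result(
    diagram: CausalLoopDiagram, variant: str = "as_printed"
) -> CentralityResult:
    """Convenience bundle of both measures."""
    return CentralityResult(
        betweenness=betweenness_centrality(diagram),
        closeness=closeness_centrality(diagram, variant),
        closeness_variant=variant,
        n_variables=diagram.n,
    )


def spearman_rank_correlation(
    a: dict[str, float], b: dict[str, float]
) -> float:
    """Spearman rho between two variable->value maps on identical keys.

    Computed as the Pearson correlation of average ranks (ties get the mean
    rank).  Requires at least 3 shared keys.
    """
    if set(a) != set(b):
        raise CLDError("key sets differ between the two centrality maps")
    keys = sorted(a)
    if len(keys) < 3:
        raise CLDError(f"need >= 3 keys for a rank correlation, got {len(keys)}")
    xs = np.array([a[k] for k in keys], dtype=float)
    ys = np.array([b[k] for k in keys], dtype=float)
    rho = scipy.stats.spearmanr(xs, ys).statistic
    return float(rho)
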