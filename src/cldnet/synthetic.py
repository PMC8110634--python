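"""Synthetic diagrams and the in-repo fixture.

Three sources of test input, none requiring a download:

* :func:`generate_random_cld` — random diagrams emulating the structure of
  a group-model-built health CLD: a few dozen variables in three health
  categories, roughly four connections per variable, a handful of
  in-degree-zero (exogenous) variables, a minority of negative edges, and a
  share of reciprocal pairs (direct feedback loops).
* :func:`fixture_from_loop_table` — the diagram implied by a printed
  feedback-loop table, reading each row as a directed cycle.  The bundled
  :data:`TABLE1_LOOPS` transcription covers 30 reinforcing loops (14 direct,
  16 indirect) over 21 variables of the Alzheimer's-disease diagram.
* :func:`planted_cycle_cld` — vertex-disjoint planted cycles with an exactly
  known loop census, for enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import (CATEGORIES, CausalLoopDiagram, CLDError, ConnectionRecord,
                   VariableRecord, normalize_name)

#: Printed loop table of the Alzheimer's-disease diagram: 14 direct (RD) and
#: 16 indirect (RI) reinforcing loops, each row a directed cycle
#: 1st -> 2nd (-> 3rd) -> 1st.
TABLE1_LOOPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("RD1", ("Amyloid beta burden", "Neuroinflammation")),
    ("RD2", ("Oxidative stress", "Neuroinflammation")),
    ("RD3", ("Amyloid beta burden", "Cerebral endothelial dysfunction")),
    ("RD4", ("Brain perfusion", "Cerebral endothelial dysfunction")),
    ("RD5", ("Systemic inflammation", "Morbidity burden")),
    ("RD6", ("Motor function", "Physical activity")),
    ("RD7", ("Physical activity", "Depressive symptoms")),
    ("RD8", ("Excessive alcohol use", "Social relationships")),
    ("RD9", ("Sleep quality", "Experienced stress")),
    ("RD10", ("Depressive symptoms", "Experienced stress")),
    ("RD11", ("Depressive symptoms", "Cognitive functioning")),
    ("RD12", ("Depressive symptoms", "Sleep quality")),
    ("RD13", ("Depressive symptoms", "Social relationships")),
    ("RD14", ("Sleep quality", "Social relationships")),
    ("RI1", ("Oxidative stress", "Neuronal dysfunction", "Circadian misalignment")),
    ("RI2", ("Physical activity", "Neuronal connectivity", "Cognitive functioning")),
    ("RI3", ("Obesity", "Motor function", "Physical activity")),
    ("RI4", ("Morbidity burden", "Motor function", "Physical activity")),
    ("RI5", ("Brain perfusion", "Physical activity", "Cognitive functioning")),
    ("RI6", ("Neuronal connectivity", "Cognitive functioning",
             "Engagement in cognitively demanding tasks")),
    ("RI7", ("Morbidity burden", "Daily functioning", "Social relationships")),
    ("RI8", ("Physical activity", "Sleep quality", "Cognitive functioning")),
    ("RI9", ("Physical activity", "Depressive symptoms", "Social relationships")),
    ("RI10", ("Physical activity", "Sleep quality", "Social relationships")),
    ("RI11", ("Experienced stress", "Depressive symptoms", "Sleep quality")),
    ("RI12", ("Experienced stress", "Sleep quality", "Depressive symptoms")),
    ("RI13", ("Experienced stress", "Depressive symptoms", "Social relationships")),
    ("RI14", ("Social relationships", "Depressive symptoms", "Cognitive functioning")),
    ("RI15", ("Depressive symptoms", "Sleep quality", "Social relationships")),
    ("RI16", ("Depressive symptoms", "Social relationships", "Sleep quality")),
)

# Editorial category assignment for the fixture variables (brain /
# psychosocial where the source figures color them so; physical otherwise).
_FIXTURE_CATEGORIES = {
    "Amyloid beta burden": "brain",
    "Neuroinflammation": "brain",
    "Oxidative stress": "brain",
    "Cerebral endothelial dysfunction": "brain",
    "Brain perfusion": "brain",
    "Neuronal dysfunction": "brain",
    "Neuronal connectivity": "brain",
    "Circadian misalignment": "brain",
    "Depressive symptoms": "psychosocial",
    "Social relationships": "psychosocial",
    "Sleep quality": "psychosocial",
    "Experienced stress": "psychosocial",
    "Cognitive functioning": "psychosocial",
    "Engagement in cognitively demanding tasks": "psychosocial",
    "Daily functioning": "psychosocial",
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random-diagram generator.

    Defaults mirror the reference diagram's structure: 38 variables, 150
    connections (~4 per variable), 3 exogenous variables, about a fifth of
    the edges in reciprocal pairs (the 14 direct loops account for 28 of 150
    connections), a minority of negative edges, and equal category weights.
    """

    n_variables: int = 38
    n_connections: int = 150
    negative_fraction: float = 0.2
    n_exogenous: int = 3
    reciprocal_fraction: float = 0.19
    category_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0


def generate_random_cld(spec: GeneratorSpec) -> CausalLoopDiagram:
    """Random validated diagram matching ``spec`` exactly where it can.

    Guarantees: exactly ``n_connections`` distinct ordered pairs, no
    self-loops; exactly ``n_exogenous`` in-degree-zero variables (every other
    variable receives at least one connection, every exogenous variable
    emits at least one); about ``reciprocal_fraction`` of edges in 2-cycles;
    each polarity negative with probability ``negative_fraction``.
    Deterministic under ``spec.seed``.
    """
    n, m = spec.n_variables, spec.n_connections
    n_ex = spec.n_exogenous
    if n < 2 or not (0 <= n_ex < n):
        raise CLDError("need n_variables >= 2 and 0 <= n_exogenous < n_variables")
    if m > (n - 1) * (n - n_ex):
        raise CLDError(f"{m} connections cannot fit: only {(n - 1) * (n - n_ex)} "
                       f"ordered pairs avoid the {n_ex} exogenous targets")
    if m < (n - n_ex) + (1 if n_ex else 0):
        raise CLDError("too few connections to give every endogenous variable "
                       "an incoming edge")

    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(n)))
    names = [f"V{i + 1:0{width}d}" for i in range(n)]
    exogenous = set(names[:n_ex])
    endogenous = [v for v in names if v not in exogenous]

    edges: dict[tuple[str, str], int] = {}

    def rand_polarity() -> int:
        return -1 if rng.random() < spec.negative_fraction else 1

    # 1. reciprocal pairs (both endpoints must accept incoming edges)
    k_pairs = int(round(spec.reciprocal_fraction * m / 2))
    candidates = list(combinations(endogenous, 2))
    k_pairs = min(k_pairs, len(candidates), m // 2)
    if k_pairs:
        for idx in rng.choice(len(candidates), size=k_pairs, replace=False):
            a, b = candidates[idx]
            edges[(a, b)] = rand_polarity()
            edges[(b, a)] = rand_polarity()

    # 2. every endogenous variable needs an incoming edge; route the first
    #    few from the exogenous variables so they are not isolated
    uncovered = [v for v in endogenous
                 if not any((u, v) in edges for u in names)]
    rng.shuffle(uncovered)
    ex_cycle = list(exogenous)
    for i, v in enumerate(uncovered):
        if i < len(ex_cycle):
            u = ex_cycle[i]
        else:
            while True:
                u = names[rng.integers(n)]
                if u != v and (u, v) not in edges and (v, u) not in edges:
                    break
        edges[(u, v)] = rand_polarity()
    # exogenous variables not used above still need an outgoing edge
    for u in ex_cycle[len(uncovered):]:
        while True:
            v = endogenous[rng.integers(len(endogenous))]
            if (u, v) not in edges:
                break
        edges[(u, v)] = rand_polarity()

    if len(edges) > m:
        raise CLDError("infeasible generator parameters: mandatory edges "
                       f"already exceed n_connections ({len(edges)} > {m})")

    # 3. fill to the exact edge count, avoiding accidental reciprocal pairs
    #    first so the reciprocal fraction stays near its target
    attempts = 0
    while len(edges) < m:
        u = names[rng.integers(n)]
        v = endogenous[rng.integers(len(endogenous))]
        attempts += 1
        if u == v or (u, v) in edges:
            continue
        if (v, u) in edges and attempts < 50 * m:
            continue
        edges[(u, v)] = rand_polarity()

    cat_idx = rng.choice(3, size=n, p=np.asarray(spec.category_weights) /
                         np.sum(spec.category_weights))
    variables = [VariableRecord(name, CATEGORIES[cat_idx[i]])
                 for i, name in enumerate(names)]
    connections = [ConnectionRecord(s, t, p) for (s, t), p in sorted(edges.items())]
    return CausalLoopDiagram(variables, connections)


def fixture_from_loop_table(
    rows=TABLE1_LOOPS,
) -> CausalLoopDiagram:
    """Diagram implied by a loop table, each row read as a directed cycle.

    Rows may be (id, members) pairs or bare member sequences of 2-3 names;
    duplicate edges merge.  Every polarity is set +1 — a canonical
    assignment under which every listed loop is reinforcing (the table
    constrains only the sign product, not individual signs).  Variables get
    the bundled category labels where known, else "physical".
    """
    edges: dict[tuple[str, str], int] = {}
    names: list[str] = []
    for row in rows:
        members = row[1] if (len(row) == 2 and not isinstance(row[1], str)) else row
        members = [normalize_name(x) for x in members if x]
        if len(members) < 2:
            raise CLDError(f"loop row needs >= 2 variables: {row!r}")
        for name in members:
            if name not in names:
                names.append(name)
        cycle = members + [members[0]]
        for a, b in zip(cycle, cycle[1:]):
            edges[(a, b)] = 1
    variables = [VariableRecord(name, _FIXTURE_CATEGORIES.get(name, "physical"))
                 for name in sorted(names)]
    connections = [ConnectionRecord(s, t, p) for (s, t), p in sorted(edges.items())]
    return CausalLoopDiagram(variables, connections)


def table1_fixture() -> CausalLoopDiagram:
    """The bundled 21-variable loop-table fixture.

    This is a subgraph stand-in for the full 38-variable diagram (whose
    complete edge list lives in a separately deposited workbook), sufficient
    for every loop-census check that the printed table supports.
    """
    return fixture_from_loop_table(TABLE1_LOOPS)


def planted_cycle_cld(
    n_direct: int, n_indirect: int, n_balancing: int, seed: int = 0
) -> CausalLoopDiagram:
    """Vertex-disjoint planted cycles with an exactly known census.

    ``n_direct`` 2-cycles and ``n_indirect`` 3-cycles, all edges positive;
    ``n_balancing`` 3-cycles carrying exactly one negative edge.  Because
    the cycles share no vertices, the true loop census equals the requested
    counts exactly.
    """
    if min(n_direct, n_indirect, n_balancing) < 0:
        raise CLDError("cycle counts must be non-negative")
    rng = np.random.default_rng(seed)
    variables: list[VariableRecord] = []
    connections: list[ConnectionRecord] = []

    def add_cycle(prefix: str, i: int, size: int, negative_at: int | None) -> None:
        nodes = [f"{prefix}{i:02d}{chr(ord('a') + j)}" for j in range(size)]
        for j, name in enumerate(nodes):
            variables.append(VariableRecord(name, CATEGORIES[rng.integers(3)]))
        for j in range(size):
            pol = -1 if j == negative_at else 1
            connections.append(ConnectionRecord(nodes[j], nodes[(j + 1) % size], pol))

    for i in range(n_direct):
        add_cycle("d", i, 2, None)
    for i in range(n_indirect):
        add_cycle("i", i, 3, None)
    for i in range(n_balancing):
        add_cycle("b", i, 3, int(rng.integers(3)))
    return CausalLoopDiagram(variables, connections).sorted_copy()
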