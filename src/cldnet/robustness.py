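"""Structural-perturbation robustness of centrality values.

How stable is a variable's centrality if the diagram's wiring contains
small errors?  The ensemble answer: generate many alternative diagrams,
each differing from the original by a handful of random mutations — a
rewiring (A->B becomes A->C), an added connection, or a deleted one — and
summarize each variable's centrality distribution by its quartiles.  The
interquartile range serves as an error bar on the point estimate.

Defaults follow the reference protocol: 1000 alternative diagrams with 5
mutations each, the three mutation kinds equiprobable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CausalLoopDiagram, ConnectionRecord, CLDError
from .centrality import betweenness_centrality, closeness_centrality

KINDS = ("rewire", "add", "delete")

#: alternative reading of "equiprobable": rewiring vs. structural change
KIND_PROBS_REWIRE_HALF = (0.5, 0.25, 0.25)


@dataclass(frozen=True)
class MutationEvent:
    """One applied mutation.  ``rewire`` has before and after (same source
    and polarity), ``add`` only after, ``delete`` only before."""

    kind: str
    before: tuple[str, str, int] | None = None
    after: tuple[str, str, int] | None = None


@dataclass(frozen=True)
class RobustnessSummary:
    """Per-variable centrality quartiles over a seeded mutation ensemble."""

    per_variable: dict[str, dict[str, tuple[float, float, float]]]  # measure -> var -> (q1, median, q3)
    n_replicates: int
    n_mutations: int
    seed: int
    closeness_variant: str
    quartile_method: str = "linear"


def mutate_diagram(
    diagram: CausalLoopDiagram,
    n_mutations: int,
    rng: np.random.Generator,
    kind_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> tuple[CausalLoopDiagram, list[MutationEvent]]:
    """Apply ``n_mutations`` sequential random mutations to a copy.

    Kinds are drawn with ``kind_probs`` over (rewire, add, delete); an
    infeasible draw (e.g. add on a complete digraph, delete on an empty one)
    is redrawn among the feasible kinds.  A rewiring keeps the connection's
    source and polarity and resamples the target uniformly among variables
    that are neither the source nor already a target of that source.  An
    added connection takes a uniformly random absent ordered pair (never a
    self-loop), positive with probability equal to the original diagram's
    positive-edge fraction.  Variables are never added or removed.
    """
    if n_mutations < 0:
        raise CLDError("n_mutations must be >= 0")
    names = sorted(diagram.variable_names())
    n = len(names)
    edges: dict[tuple[str, str], int] = dict(
        sorted(diagram.polarity_map().items()))
    pos_frac = diagram.positive_fraction()
    events: list[MutationEvent] = []
    probs = np.asarray(kind_probs, dtype=float)
    probs = probs / probs.sum()

    for _ in range(n_mutations):
        out_count: dict[str, int] = {}
        for (s, _t) in edges:
            out_count[s] = out_count.get(s, 0) + 1
        rewireable = sorted(e for e in edges if out_count[e[0]] < n - 1)
        feasible = {
            "rewire": bool(rewireable),
            "add": len(edges) < n * (n - 1),
            "delete": bool(edges),
        }
        # redrawing an infeasible kind == drawing from the renormalized
        # distribution over feasible kinds (and cannot spin forever)
        available = [i for i, k in enumerate(KINDS)
                     if feasible[k] and probs[i] > 0]
        if not available:
            raise CLDError("diagram admits no mutation of any configured kind")
        sub = probs[available] / probs[available].sum()
        kind = KINDS[available[rng.choice(len(available), p=sub)]]

        if kind == "delete":
            keys = sorted(edges)
            src, tgt = keys[rng.integers(len(keys))]
            events.append(MutationEvent("delete", before=(src, tgt, edges.pop((src, tgt)))))
        elif kind == "add":
            absent = [(s, t) for s in names for t in names
                      if s != t and (s, t) not in edges]
            src, tgt = absent[rng.integers(len(absent))]
            pol = 1 if rng.random() < pos_frac else -1
            edges[(src, tgt)] = pol
            events.append(MutationEvent("add", after=(src, tgt, pol)))
        else:  # rewire; uniform over edges whose source still has a free target
            src, tgt = rewireable[rng.integers(len(rewireable))]
            taken = {t for (s, t) in edges if s == src}
            candidates = [t for t in names if t != src and t not in taken]
            new_tgt = candidates[rng.integers(len(candidates))]
            pol = edges.pop((src, tgt))
            edges[(src, new_tgt)] = pol
            events.append(MutationEvent("rewire",
                                        before=(src, tgt, pol),
                                        after=(src, new_tgt, pol)))

    mutant = CausalLoopDiagram(
        variables=list(diagram.variables),
        connections=[ConnectionRecord(s, t, p) for (s, t), p in sorted(edges.items())],
    )
    return mutant, events


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic independent substream for one replicate.

    Built from ``SeedSequence([seed, replicate])``, so any subset of
    replicates can be recomputed independently with identical results.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, replicate]))


def centrality_ensemble(
    diagram: CausalLoopDiagram,
    n_replicates: int = 1000,
    n_mutations: int = 5,
    seed: int = 0,
    variant: str = "as_printed",
    kind_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> RobustnessSummary:
    """Quartile summary of BC and CC over a mutation ensemble.

    Replicate r is generated from an independent substream derived from
    (seed, r); the summary is therefore bit-reproducible and invariant to
    the order in which replicates are executed.  Quartiles use linear
    interpolation (numpy's default, recorded in the summary).
    """
    if n_replicates < 1:
        raise CLDError("n_replicates must be >= 1")
    names = diagram.variable_names()
    samples = {"betweenness": {v: np.empty(n_replicates) for v in names},
               "closeness": {v: np.empty(n_replicates) for v in names}}
    for r in range(n_replicates):
        mutant, _ = mutate_diagram(diagram, n_mutations, replicate_rng(seed, r),
                                   kind_probs)
        bc = betweenness_centrality(mutant)
        cc = closeness_centrality(mutant, variant)
        for v in names:
            samples["betweenness"][v][r] = bc[v]
            samples["closeness"][v][r] = cc[v]

    per_variable = {
        measure: {
            v: tuple(np.percentile(vals, [25, 50, 75], method="linear"))
            for v, vals in by_var.items()
        }
        for measure, by_var in samples.items()
    }
    return RobustnessSummary(per_variable=per_variable,
                             n_replicates=n_replicates,
                             n_mutations=n_mutations,
                             seed=seed,
                             closeness_variant=variant)
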