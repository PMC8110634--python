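"""Feedback-loop enumeration and classification.

A feedback loop is a simple directed cycle.  Its polarity product decides
its class: reinforcing (+1, self-strengthening) or balancing (-1,
self-limiting / homeostatic).  Loops of exactly two variables are "direct";
longer ones are "indirect".  A loop whose members all share one spatial-
scale label is "within-scale"; one spanning several labels is "cross-scale".

Cycles are identified up to rotation only, never reversal: A->B->C->A and
A->C->B->A are distinct loops.  The canonical rotation starts at the
lexicographically least member.  Enumeration is a bounded-depth search,
adequate for the short loops (length <= ~6) that remain interpretable in a
qualitative diagram; a full cycle census of arbitrary length is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import pandas as pd

from .core import CausalLoopDiagram, CLDError


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle in canonical rotation.

    ``polarities[i]`` signs the edge members[i] -> members[(i+1) % k]; the
    closing edge comes last.
    """

    members: tuple[str, ...]
    polarities: tuple[int, ...]
    polarity_product: int
    loop_class: str       # reinforcing | balancing
    length_class: str     # direct | indirect
    scale_class: str      # within_scale | cross_scale | unlabeled

    def __len__(self) -> int:
        return len(self.members)


def _canonical_rotation(members: tuple[str, ...],
                        polarities: tuple[int, ...]) -> tuple[tuple[str, ...], tuple[int, ...]]:
    k = members.index(min(members))
    return members[k:] + members[:k], polarities[k:] + polarities[:k]


def _make_loop(members: tuple[str, ...], polarities: tuple[int, ...],
               diagram: CausalLoopDiagram, label_field: str) -> FeedbackLoop:
    members, polarities = _canonical_rotation(members, polarities)
    product = prod(polarities)
    loop = FeedbackLoop(
        members=members,
        polarities=polarities,
        polarity_product=product,
        loop_class="reinforcing" if product == 1 else "balancing",
        length_class="direct" if len(members) == 2 else "indirect",
        scale_class="unlabeled",
    )
    return FeedbackLoop(**{**loop.__dict__,
                           "scale_class": classify_scale(loop, diagram, label_field)})


def classify_scale(loop: FeedbackLoop, diagram: CausalLoopDiagram,
                   label_field: str = "category") -> str:
    """within_scale if all members share one label, cross_scale if they span
    two or more, unlabeled if any member lacks the chosen label field.

    ``label_field="scale"`` uses the explicit spatial-scale annotation;
    ``"category"`` falls back on the brain/physical/psychosocial grouping,
    which every variable carries.
    """
    varmap = diagram.variable_map()
    labels = []
    for name in loop.members:
        record = varmap.get(name)
        if record is None:
            raise CLDError(f"loop member {name!r} not declared in diagram")
        label = getattr(record, label_field)
        if label is None:
            return "unlabeled"
        labels.append(label)
    return "within_scale" if len(set(labels)) == 1 else "cross_scale"


def enumerate_loops(diagram: CausalLoopDiagram, max_length: int,
                    label_field: str = "category") -> list[FeedbackLoop]:
    """All simple directed cycles of length 2..max_length, each once.

    Output order is deterministic: by length, then canonical member tuple.
    """
    if max_length < 2:
        raise CLDError(f"max_length must be >= 2, got {max_length}")
    adj = diagram.successors()
    pol = diagram.polarity_map()
    order = {name: i for i, name in enumerate(sorted(adj))}
    loops: list[FeedbackLoop] = []

    def extend(start: str, path: list[str], signs: list[int]) -> None:
        u = path[-1]
        for w in adj[u]:
            if w == start and len(path) >= 2:
                loops.append(_make_loop(tuple(path), tuple(signs + [pol[(u, w)]]),
                                        diagram, label_field))
            elif (order[w] > order[start] and w not in path
                  and len(path) < max_length):
                extend(start, path + [w], signs + [pol[(u, w)]])

    # Restricting intermediate nodes to those after the start in sort order
    # yields each cycle exactly once, rooted at its least member.
    for start in sorted(adj):
        extend(start, [start], [])

    loops.sort(key=lambda lp: (len(lp.members), lp.members))
    return loops


def loops_containing(diagram: CausalLoopDiagram, variable: str,
                     max_length: int, label_field: str = "category") -> list[FeedbackLoop]:
    """The subset of enumerated loops whose members include ``variable``."""
    if variable not in {v.name for v in diagram.variables}:
        raise CLDError(f"unknown variable: {variable!r}")
    return [lp for lp in enumerate_loops(diagram, max_length, label_field)
            if variable in lp.members]


def loop_table(loops: list[FeedbackLoop]) -> pd.DataFrame:
    """Tabulate loops with ids RD1.. (direct) and RI1.. (indirect).

    Ids follow the deterministic enumeration order.  Loops longer than three
    variables fill only the first three columns and append an ellipsis
    marker in the third.
    """
    rows = []
    n_direct = n_indirect = 0
    for lp in loops:
        if lp.length_class == "direct":
            n_direct += 1
            loop_id = f"RD{n_direct}"
        else:
            n_indirect += 1
            loop_id = f"RI{n_indirect}"
        members = list(lp.members[:3])
        if len(lp.members) > 3:
            members[2] = f"{members[2]} (+{len(lp.members) - 3} more)"
        members += [""] * (3 - len(members))
        rows.append({"loop": loop_id,
                     "1st variable": members[0],
                     "2nd variable": members[1],
                     "3rd variable": members[2],
                     "loop_class": lp.loop_class,
                     "scale_class": lp.scale_class})
    columns = ["loop", "1st variable", "2nd variable", "3rd variable",
               "loop_class", "scale_class"]
    return pd.DataFrame(rows, columns=columns)
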