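"""Node-omission sensitivity of centrality rankings.

Removing a variable (and every connection touching it) probes how much a
diagram's centrality ordering depends on modelling choices about which
variables to include — e.g. whether folding several pathology markers into
one aggregate variable would have changed which variables look central.
The report compares betweenness/closeness before and after removal and
gives each surviving variable's betweenness rank shift; it emits numbers,
not verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CausalLoopDiagram, CLDError, subdiagram
from .centrality import CentralityResult, centrality_result


@dataclass(frozen=True)
class OmissionReport:
    removed: tuple[str, ...]
    centrality_before: CentralityResult
    centrality_after: CentralityResult
    rank_shift: dict[str, int]  # BC rank before - after, over survivors


def _dense_ranks(values: dict[str, float]) -> dict[str, int]:
    # rank 1 = highest value; ties broken by name (ordinal ranks)
    ordered = sorted(values, key=lambda v: (-values[v], v))
    return {name: i + 1 for i, name in enumerate(ordered)}


def omit_and_recompute(
    diagram: CausalLoopDiagram,
    remove: list[str],
    variant: str = "as_printed",
) -> OmissionReport:
    """Recompute both centralities on the induced subdiagram without
    ``remove`` and report per-survivor betweenness rank shifts.

    Rank shifts compare rankings restricted to the survivors, so a positive
    shift means the variable moved up (toward rank 1) after the omission.
    At least 3 variables must survive for the betweenness normalization.
    """
    declared = set(diagram.variable_names())
    unknown = [name for name in remove if name not in declared]
    if unknown:
        raise CLDError(f"unknown variable(s) to remove: {unknown}")
    survivors = [v for v in diagram.variable_names() if v not in set(remove)]
    if len(survivors) < 3:
        raise CLDError(f"only {len(survivors)} variables would survive; "
                       "need >= 3 for betweenness")

    before = centrality_result(diagram, variant)
    after = centrality_result(subdiagram(diagram, survivors), variant)

    ranks_before = _dense_ranks({v: before.betweenness[v] for v in survivors})
    ranks_after = _dense_ranks(after.betweenness)
    shift = {v: ranks_before[v] - ranks_after[v] for v in survivors}
    return OmissionReport(removed=tuple(remove),
                          centrality_before=before,
                          centrality_after=after,
                          rank_shift=shift)
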