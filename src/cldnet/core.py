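"""Data model, validation and I/O for signed causal loop diagrams.

A causal loop diagram (CLD) is a directed graph whose nodes are system
variables and whose edges carry a polarity: ``+1`` when the target moves in
the same direction as the source, ``-1`` when it moves in the opposite
direction.  Variables belong to one of three health categories (brain,
physical, psychosocial) and may carry a characteristic spatial-scale label
(e.g. "cellular", "organ", "person").

The diagram container is deliberately permissive — :func:`validate` reports
invariant violations instead of raising, so that malformed input can be
diagnosed in full.  :func:`parse_edge_tables` is the strict entry point used
by the analysis modules.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

CATEGORIES = ("brain", "physical", "psychosocial")

#: polarity spellings accepted on input, incl. the typographic minus U+2212
_POLARITY_TOKENS = {
    "+": 1, "-": -1, "−": -1,
    "+1": 1, "-1": -1, "−1": -1,
    "1": 1, "positive": 1, "negative": -1,
}

_WS = re.compile(r"\s+")


class CLDError(ValueError):
    """Raised on invalid diagrams, rows, or arguments."""


def normalize_name(name: str) -> str:
    """Trim and collapse internal whitespace; matching is case-sensitive."""
    return _WS.sub(" ", str(name).strip())


def normalize_polarity(token: object) -> int:
    """Map a polarity spelling (+, -, +1, -1, 1, unicode minus...) to ±1."""
    if isinstance(token, bool):
        raise CLDError(f"unknown polarity token: {token!r}")
    if isinstance(token, (int, float)):
        if token == 1:
            return 1
        if token == -1:
            return -1
        raise CLDError(f"unknown polarity token: {token!r}")
    tok = str(token).strip()
    try:
        return _POLARITY_TOKENS[tok]
    except KeyError:
        raise CLDError(f"unknown polarity token: {token!r}") from None


@dataclass(frozen=True)
class VariableRecord:
    """A named node with a health category and optional annotations."""

    name: str
    category: str = "physical"
    scale: str | None = None
    definition: str | None = None


@dataclass(frozen=True)
class ConnectionRecord:
    """A directed signed edge with optional evidence citations."""

    source: str
    target: str
    polarity: int
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    errors: tuple[tuple[str, str], ...] = ()
    warnings: tuple[tuple[str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class CausalLoopDiagram:
    """A signed digraph of variables and connections.

    Construction performs no checking; run :func:`validate` (or build through
    :func:`parse_edge_tables`, which does) before analysis.
    """

    variables: list[VariableRecord] = field(default_factory=list)
    connections: list[ConnectionRecord] = field(default_factory=list)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def m(self) -> int:
        return len(self.connections)

    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable_map(self) -> dict[str, VariableRecord]:
        return {v.name: v for v in self.variables}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(c.source, c.target) for c in self.connections}

    def successors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v.name: [] for v in self.variables}
        for c in self.connections:
            adj[c.source].append(c.target)
        return adj

    def in_degree(self) -> dict[str, int]:
        deg = {v.name: 0 for v in self.variables}
        for c in self.connections:
            deg[c.target] += 1
        return deg

    def polarity_map(self) -> dict[tuple[str, str], int]:
        return {(c.source, c.target): c.polarity for c in self.connections}

    def positive_fraction(self) -> float:
        if not self.connections:
            return 1.0
        return sum(c.polarity == 1 for c in self.connections) / self.m

    def sorted_copy(self) -> "CausalLoopDiagram":
        """Stable ordering: variables by name, connections by (source, target)."""
        return CausalLoopDiagram(
            variables=sorted(self.variables, key=lambda v: v.name),
            connections=sorted(self.connections, key=lambda c: (c.source, c.target)),
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.variables:
            g.add_node(v.name, category=v.category,
                       **({"scale": v.scale} if v.scale is not None else {}))
        for c in self.connections:
            g.add_edge(c.source, c.target, polarity=c.polarity)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalLoopDiagram):
            return NotImplemented
        key_v = lambda d: sorted((v.name, v.category, v.scale) for v in d.variables)
        key_c = lambda d: sorted((c.source, c.target, c.polarity) for c in d.connections)
        return key_v(self) == key_v(other) and key_c(self) == key_c(other)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(diagram: CausalLoopDiagram) -> ValidationReport:
    """Report all invariant violations; never raises.

    Errors: DUPLICATE_NAME, BAD_CATEGORY, EMPTY_NAME, UNDECLARED_VARIABLE,
    SELF_LOOP, DUPLICATE_CONNECTION, BAD_POLARITY.
    Warnings: ISOLATED_VARIABLE (degree 0), MISSING_SCALE.
    """
    errors: list[tuple[str, str]] = []
    warnings: list[tuple[str, str]] = []

    seen: set[str] = set()
    for v in diagram.variables:
        if not v.name:
            errors.append(("EMPTY_NAME", "variable with empty name"))
        if v.name in seen:
            errors.append(("DUPLICATE_NAME", f"variable declared twice: {v.name!r}"))
        seen.add(v.name)
        if v.category not in CATEGORIES:
            errors.append(("BAD_CATEGORY",
                           f"{v.name!r}: category {v.category!r} not in {CATEGORIES}"))
        if v.scale is None:
            warnings.append(("MISSING_SCALE", f"{v.name!r} has no spatial-scale label"))

    pairs: set[tuple[str, str]] = set()
    touched: set[str] = set()
    for c in diagram.connections:
        for endpoint in (c.source, c.target):
            if endpoint not in seen:
                errors.append(("UNDECLARED_VARIABLE",
                               f"connection {c.source!r}->{c.target!r} references "
                               f"undeclared variable {endpoint!r}"))
        if c.source == c.target:
            errors.append(("SELF_LOOP", f"self-loop on {c.source!r}"))
        if (c.source, c.target) in pairs:
            errors.append(("DUPLICATE_CONNECTION",
                           f"duplicate ordered pair {c.source!r}->{c.target!r}"))
        pairs.add((c.source, c.target))
        if c.polarity not in (1, -1):
            errors.append(("BAD_POLARITY",
                           f"{c.source!r}->{c.target!r}: polarity {c.polarity!r}"))
        touched.update((c.source, c.target))

    for v in diagram.variables:
        if v.name not in touched:
            warnings.append(("ISOLATED_VARIABLE", f"{v.name!r} has degree 0"))

    return ValidationReport(errors=tuple(errors), warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_edge_tables(
    edge_rows: Iterable[Mapping[str, object] | Sequence[object]],
    variable_rows: Iterable[Mapping[str, object] | Sequence[object]] = (),
    *,
    auto_declare: bool = False,
    skip_self_loops: bool = False,
) -> CausalLoopDiagram:
    """Build a validated diagram from tabular rows.

    Edge rows carry (source, target, polarity[, evidence]); variable rows
    carry (name, category[, scale[, definition]]).  Rows may be mappings or
    positional sequences.  ``auto_declare=True`` declares endpoint names
    missing from the variable table with category "physical" (reported as a
    warning by :func:`validate` only via MISSING_SCALE); without it an
    undeclared endpoint is an error.  ``skip_self_loops=True`` drops
    self-loop rows instead of raising.

    Raises :class:`CLDError` listing every violation found.
    """
    variables: list[VariableRecord] = []
    declared: set[str] = set()
    for row in variable_rows:
        if isinstance(row, Mapping):
            name = normalize_name(row.get("name", ""))
            category = str(row.get("category") or "physical").strip().lower()
            scale = row.get("scale")
            definition = row.get("definition")
        else:
            seq = list(row)
            name = normalize_name(seq[0])
            category = str(seq[1]).strip().lower() if len(seq) > 1 and seq[1] else "physical"
            scale = seq[2] if len(seq) > 2 else None
            definition = seq[3] if len(seq) > 3 else None
        scale = None if scale in (None, "") or (isinstance(scale, float) and pd.isna(scale)) else str(scale).strip()
        definition = None if definition in (None, "") or (isinstance(definition, float) and pd.isna(definition)) else str(definition)
        variables.append(VariableRecord(name, category, scale, definition))
        declared.add(name)

    connections: list[ConnectionRecord] = []
    problems: list[str] = []
    pairs: set[tuple[str, str]] = set()
    for i, row in enumerate(edge_rows):
        if isinstance(row, Mapping):
            src = normalize_name(row.get("source", ""))
            tgt = normalize_name(row.get("target", ""))
            pol_tok = row.get("polarity")
            ev = row.get("evidence") or ()
        else:
            seq = list(row)
            src, tgt = normalize_name(seq[0]), normalize_name(seq[1])
            pol_tok = seq[2] if len(seq) > 2 else None
            ev = seq[3] if len(seq) > 3 else ()
        if isinstance(ev, str):
            ev = tuple(s.strip() for s in ev.split(";") if s.strip())
        else:
            ev = tuple(ev)

        if src == tgt:
            if skip_self_loops:
                continue
            problems.append(f"row {i}: self-loop {src!r}")
            continue
        try:
            pol = normalize_polarity(pol_tok)
        except CLDError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        if (src, tgt) in pairs:
            problems.append(f"row {i}: duplicate ordered pair {src!r}->{tgt!r}")
            continue
        pairs.add((src, tgt))
        for endpoint in (src, tgt):
            if endpoint not in declared:
                if auto_declare:
                    variables.append(VariableRecord(endpoint, "physical"))
                    declared.add(endpoint)
                else:
                    problems.append(f"row {i}: undeclared variable {endpoint!r}")
        connections.append(ConnectionRecord(src, tgt, pol, ev))

    if problems:
        raise CLDError("invalid edge table:\n  " + "\n  ".join(problems))

    diagram = CausalLoopDiagram(variables, connections).sorted_copy()
    report = validate(diagram)
    if not report.ok:
        raise CLDError("invalid diagram:\n  " +
                       "\n  ".join(f"[{c}] {m}" for c, m in report.errors))
    return diagram


def exogenous_variables(diagram: CausalLoopDiagram) -> set[str]:
    """Variables with in-degree 0: they influence the system without being
    influenced by it."""
    return {name for name, deg in diagram.in_degree().items() if deg == 0}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "variables": {"name": "name", "category": "category",
                  "scale": "scale", "definition": "definition"},
    "connections": {"source": "source", "target": "target",
                    "polarity": "polarity", "evidence": "evidence"},
}


def _frame_to_rows(df: pd.DataFrame, mapping: Mapping[str, str]) -> list[dict]:
    cols = {canonical: actual for canonical, actual in mapping.items()
            if actual in df.columns}
    rows = []
    for _, r in df.iterrows():
        row = {canonical: r[actual] for canonical, actual in cols.items()}
        rows.append({k: (None if pd.isna(v) else v) if not isinstance(v, str) else v
                     for k, v in row.items()})
    return rows


def read_tables(
    edge_path: str | Path,
    variable_path: str | Path | None = None,
    *,
    column_map: Mapping[str, Mapping[str, str]] | None = None,
    auto_declare: bool = False,
) -> CausalLoopDiagram:
    """Read a diagram from CSV/TSV files (UTF-8, header row required).

    ``column_map`` remaps file headers onto the canonical column names, e.g.
    ``{"connections": {"source": "From", "target": "To", "polarity": "Sign"}}``.
    """
    cmap = {**DEFAULT_COLUMNS, **(column_map or {})}
    sep_e = "\t" if str(edge_path).endswith((".tsv", ".tab")) else ","
    edges = pd.read_csv(edge_path, sep=sep_e, dtype=str)
    if variable_path is not None:
        sep_v = "\t" if str(variable_path).endswith((".tsv", ".tab")) else ","
        variables = pd.read_csv(variable_path, sep=sep_v, dtype=str)
        var_rows = _frame_to_rows(variables, cmap["variables"])
    else:
        var_rows = []
        auto_declare = True
    return parse_edge_tables(_frame_to_rows(edges, cmap["connections"]), var_rows,
                             auto_declare=auto_declare)


def read_workbook(
    path: str | Path,
    *,
    variable_sheet: int | str = 0,
    connection_sheet: int | str = 1,
    column_map: Mapping[str, Mapping[str, str]] | None = None,
) -> CausalLoopDiagram:
    """Read a diagram from an XLSX workbook.

    Expected dialect: first sheet = variables (name, category, scale,
    definition), second sheet = connections (source, target, polarity,
    evidence).  Deviating layouts are handled through ``variable_sheet`` /
    ``connection_sheet`` and ``column_map``.
    """
    cmap = {**DEFAULT_COLUMNS, **(column_map or {})}
    variables = pd.read_excel(path, sheet_name=variable_sheet)
    edges = pd.read_excel(path, sheet_name=connection_sheet)
    return parse_edge_tables(_frame_to_rows(edges, cmap["connections"]),
                             _frame_to_rows(variables, cmap["variables"]))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_diagram(diagram: CausalLoopDiagram, format: str = "json") -> str:
    """Serialize to GraphML, DOT or JSON.

    All three are deterministic (variables sorted by name, connections by
    ordered pair).  Polarity travels as an edge attribute; category and scale
    as node attributes.  Negative edges render dashed in DOT, mirroring the
    dotted-line convention for negative connections.
    JSON round-trips exactly through :func:`parse_json`.
    """
    d = diagram.sorted_copy()
    if format == "json":
        payload = {
            "elements": {
                "nodes": [
                    {"id": v.name,
                     "attributes": {k: val for k, val in
                                    (("category", v.category), ("scale", v.scale),
                                     ("definition", v.definition)) if val is not None}}
                    for v in d.variables
                ],
                "edges": [
                    {"from": c.source, "to": c.target, "polarity": c.polarity,
                     **({"evidence": list(c.evidence)} if c.evidence else {})}
                    for c in d.connections
                ],
            }
        }
        return json.dumps(payload, indent=2, ensure_ascii=False)
    if format == "graphml":
        g = nx.DiGraph()
        for v in d.variables:
            attrs = {"category": v.category}
            if v.scale is not None:
                attrs["scale"] = v.scale
            g.add_node(v.name, **attrs)
        for c in d.connections:
            g.add_edge(c.source, c.target, polarity=f"{c.polarity:+d}")
        return "\n".join(nx.generate_graphml(g))
    if format == "dot":
        lines = ["digraph CLD {"]
        for v in d.variables:
            attrs = [f'category="{v.category}"']
            if v.scale is not None:
                attrs.append(f'scale="{v.scale}"')
            lines.append(f'  "{v.name}" [{", ".join(attrs)}];')
        for c in d.connections:
            style = "solid" if c.polarity == 1 else "dashed"
            lines.append(f'  "{c.source}" -> "{c.target}" '
                         f'[polarity="{c.polarity:+d}", style={style}];')
        lines.append("}")
        return "\n".join(lines)
    raise CLDError(f"unknown export format: {format!r} "
                   "(expected one of graphml, dot, json)")


def parse_json(text: str) -> CausalLoopDiagram:
    """Inverse of ``export_diagram(..., format='json')``."""
    payload = json.loads(text)
    nodes = payload["elements"]["nodes"]
    edges = payload["elements"]["edges"]
    var_rows = [{"name": n["id"], **n.get("attributes", {})} for n in nodes]
    edge_rows = [{"source": e["from"], "target": e["to"],
                  "polarity": e["polarity"], "evidence": e.get("evidence", ())}
                 for e in edges]
    return parse_edge_tables(edge_rows, var_rows)


def subdiagram(diagram: CausalLoopDiagram, keep: Iterable[str]) -> CausalLoopDiagram:
    """Induced subdiagram on ``keep``: drops other variables and all their
    incident connections."""
    keep = set(keep)
    return CausalLoopDiagram(
        variables=[v for v in diagram.variables if v.name in keep],
        connections=[c for c in diagram.connections
                     if c.source in keep and c.target in keep],
    ).sorted_copy()
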