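# Methods

## Scope and model

`cldnet` analyzes the *structure* of a signed causal loop diagram; it fits
no dynamics.  The diagram is an unweighted simple digraph: at most one
connection per ordered pair, no self-loops, every connection signed ±1.
Reciprocal pairs (A→B and B→A) are allowed — they are precisely the direct
feedback loops.  Self-loops are rejected because the loop taxonomy starts
at two variables; a permissive parser flag (`skip_self_loops`) drops such
rows with the rest of the table intact.  Variable names are matched
case-sensitively after trimming and collapsing internal whitespace.  An
A→B effect with two mechanisms must be aggregated into one connection by
the user before loading; evidence strings ride along but never act as
weights.

## Centrality

Shortest paths follow edge direction, count hops, and ignore polarity.
Betweenness uses Brandes' accumulation (one BFS per source) with the
normalization `1/((N-1)(N-2))` over ordered pairs, `N` the variable count;
`N ≥ 3` is required for the constant to be defined.  Endpoints are excluded
from the sum (`s ≠ v ≠ t`).  That convention is forced by the semantics of
an exogenous variable: a node with no incoming connections can appear in
shortest paths only as an endpoint, so endpoint exclusion is what makes its
betweenness exactly 0.  Ordered pairs with no connecting path contribute 0.

Closeness is *outward* — it sums distances `d(v,u)` from `v` — because in a
causal map the quantity of interest is how quickly influence propagates
from a variable into the rest of the system.  The default (`as_printed`)
form is `(n-1)/Σ d(v,u)` where `n-1` counts only the variables reachable
from `v`; a variable reaching nothing scores 0 by convention.  On
disconnected diagrams this form can flatter variables with tiny reach, so
the Wasserman–Faust rescaling (`wf_scaled`, multiply by `(n-1)/(N-1)`) is
offered as an explicit variant; the two coincide on strongly connected
diagrams.  Which convention produced a given published figure is often
unstated, so comparisons are reported under both.

Spearman's ρ between the two measures is the Pearson correlation of
average ranks (ties get mean rank), computed by `scipy.stats.spearmanr`
and cross-checked in the tests against a direct rank-Pearson evaluation.

## Robustness ensemble

The ensemble asks how centrality values move if the diagram's wiring
contains small errors.  Each replicate applies `n_mutations` sequential
mutations to a copy (never to the original, and never touching the
variable set).  A mutation kind is drawn from {rewire, add, delete}:

* **rewire** — keep a connection's source and polarity, resample the
  target uniformly among variables that are neither the source nor already
  one of its targets;
* **add** — a uniformly random absent ordered pair (no self-loops),
  positive with probability equal to the original diagram's positive-edge
  fraction (polarity is invisible to centrality, so this choice affects
  only exported mutants);
* **delete** — a uniformly random existing connection.

"Equiprobable" is read as 1/3 each; the alternative reading (1/2 rewire,
1/4 add, 1/4 delete) is exposed as `kind_probs`.  An infeasible kind (add
on a complete digraph, delete on an empty one) is excluded and the
remaining kinds renormalized, which is distributionally identical to
redraw-on-infeasible and keeps the mutation count exact.  Edge-count drift
after `k` mutations is bounded by `k` and equals the adds-minus-deletes
tally of the event log.

Defaults are 1000 replicates × 5 mutations, the protocol used for the
published error bars.  Replicate `r` draws from
`default_rng(SeedSequence([seed, r]))`, so the ensemble is bit-reproducible,
order-independent, and any subset of replicates can be recomputed alone.
Per-variable quartiles (q1, median, q3) use numpy's linear interpolation,
recorded in the summary.  On a 38-variable, 150-connection diagram the full
protocol takes a few seconds on one CPU.

## Feedback loops

Simple directed cycles of length 2..`max_length` are enumerated by a
bounded DFS rooted at each node in lexicographic order, with intermediate
nodes restricted to those sorting after the root — each cycle is found
exactly once, already in its canonical rotation (starting at the least
member).  Cycles are identified up to rotation, never reversal: both
orientations of a triangle are distinct loops, as loop tables in the field
list them.  Default `max_length` is 3; the search is practical to ~6 on
~40-node diagrams, and longer loops are deliberately out of scope (the
census grows combinatorially and long qualitative loops resist
interpretation anyway).

A loop is reinforcing iff its polarity product is +1.  Scale
classification compares member labels: all equal → within-scale, several →
cross-scale, any missing → unlabeled.  When explicit spatial-scale labels
are absent the health category (brain/physical/psychosocial) stands in as
the label, a documented fallback (`label_field`).  Balancing loops are
enumerated and reported even when a given diagram contains none — their
absence is a property of the diagram, not of the code.

`loop_table` assigns ids `RD1..` (direct) and `RI1..` (indirect) in
deterministic enumeration order; these ids therefore agree with a published
table only up to relabeling.

## Node-omission sensitivity

`omit_and_recompute` drops the named variables and every incident
connection, recomputes both centralities on the induced subdiagram, and
reports betweenness rank shifts over the survivors (both rankings
restricted to survivors; dense ordinal ranks, ties broken by name).  At
least three variables must survive.  The report emits numbers, not
verdicts — whether a shift is "minimal" is the caller's judgment.

## Synthetic data

`generate_random_cld` emulates the structure of a group-model-built health
CLD.  Defaults are the reference diagram's stated conditions: 38 variables,
150 connections, 3 exogenous (in-degree-zero) variables.  Two parameters
the reference does not state are fixed once at field-realistic values:
`reciprocal_fraction = 0.19` (the 14 printed direct loops account for 28 of
150 connections) and `negative_fraction = 0.2` (negative connections are a
clear minority in published health CLDs; among short loops, none printed
was balancing).  Category weights default to uniform thirds.  Generation
is exact where the spec is hard (connection count, exogenous count — every
endogenous variable is guaranteed an incoming edge and every exogenous one
an outgoing edge) and approximate where it is soft (reciprocal share,
polarity mix).  What the generator does *not* emulate: degree
heterogeneity and community structure of a real expert-built map, its
bidirectional lifestyle–pathology motifs, or meaningful evidence
annotations.  Passing tests on generated diagrams therefore certify the
algorithms, not any scientific claim about a particular real diagram.

`fixture_from_loop_table` reconstructs the diagram implied by a printed
loop table, reading each row as a directed cycle and merging duplicate
edges; the bundled transcription covers 30 reinforcing loops over 21
variables.  All polarities are set +1 — canonical, since the table
constrains only each loop's sign product, though counterfactual for some
real connections (a mutually negative pair has the same product).  Category
labels are an editorial assignment (brain/psychosocial where the source
figures color them so, physical otherwise).  The edge *union* of a loop
table can admit cycles the table does not list (edges contributed by
different rows compose into new cycles), so fixture-based checks assert
containment of the listed loops and use membership counts restricted to
the listed loops; exact census equality is asserted only for
`planted_cycle_cld`, whose vertex-disjoint construction makes the true
census known.

## Numerical and degenerate-input choices

* Quartiles: numpy `percentile(..., method="linear")`, recorded in every
  robustness summary.
* BFS/DFS tie-breaks: neighbors are visited in insertion order of the
  sorted connection list, making every output deterministic for a fixed
  diagram.
* Exports sort variables by name and connections by ordered pair; JSON
  round-trips exactly, GraphML/DOT carry polarity, category and scale as
  attributes.
* Degenerate inputs: `N < 3` rejects betweenness; a variable reaching
  nothing has closeness 0; an empty loop list yields a header-only table;
  `n_mutations = 0` collapses all quartiles onto the unperturbed value.

## Known limitations

* Centrality on a qualitative diagram is a structural proxy for causal
  importance; it ignores connection strength and dynamics entirely.
* The loop census is truncated at `max_length`; nothing is claimed about
  longer loops beyond membership overlap of the short ones.
* The bundled fixture is a subgraph stand-in: quantities defined on the
  full 38-variable diagram (its exact centrality ranking, its Spearman ρ)
  require the deposited workbook transcribed per `data/README.md`.
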