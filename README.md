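# cldnet — network analysis of signed causal loop diagrams

Causal loop diagrams (CLDs) are qualitative system maps: directed graphs
whose nodes are system variables and whose edges carry a polarity — `+` when
the target moves in the same direction as the source, `-` when it moves
oppositely.  Groups of domain experts build such diagrams to summarize the
hypothesized multicausal structure of complex conditions (the motivating
case is a 38-variable map of sporadic Alzheimer's disease spanning brain,
physical and psychosocial health).  A CLD has no dynamics, but its wiring
alone already answers useful questions: which variables are structurally
central, which feedback loops amplify or dampen perturbations, and how
stable those answers are to small wiring errors.

`cldnet` implements that structural analysis for any signed CLD:

* **Centrality.**  Normalized betweenness
  `BC_v = 1/((N-1)(N-2)) * Σ_{s≠v≠t} σ(s,t|v)/σ(s,t)`,
  where `σ(s,t)` counts shortest directed paths and `σ(s,t|v)` those passing
  through `v`; and outward closeness `CC_v = (n-1)/Σ_u d(v,u)` over the
  `n-1` variables reachable from `v` (a Wasserman–Faust rescaled variant is
  available for disconnected diagrams).  Both ignore polarity.  A variable
  with no incoming connections (exogenous) has `BC = 0` by construction but
  can still score high `CC`.  Spearman's ρ compares the two rankings.
* **Feedback loops.**  Bounded-length enumeration of simple directed
  cycles, each classified as reinforcing (polarity product `+1`) or
  balancing (`-1`), direct (two variables) or indirect (three or more), and
  within-scale or cross-scale by its members' labels.
* **Robustness.**  An ensemble of mutated diagrams (random rewirings,
  additions, deletions of connections — by default 1000 replicates, 5
  mutations each, equiprobable kinds) yields per-variable centrality
  quartiles; the interquartile range is the error bar on each centrality.
* **Sensitivity.**  Node-omission reports: remove chosen variables,
  recompute centralities on the induced subdiagram, and tabulate
  betweenness rank shifts among the survivors.
* **Synthetic data.**  A seeded generator of realistic random CLDs
  (categories, exogenous nodes, reciprocal pairs), a planted-cycle builder
  with an exactly known loop census, and a fixture reconstructed from the
  published table of 30 reinforcing feedback loops.

## Worked example

```python
from cldnet import (table1_fixture, betweenness_centrality,
                    closeness_centrality, spearman_rank_correlation,
                    enumerate_loops, centrality_ensemble)

d = table1_fixture()              # 21 variables, 51 connections
bc = betweenness_centrality(d)
cc = closeness_centrality(d)
for v in sorted(bc, key=bc.get, reverse=True)[:3]:
    print(f"{v}\t{bc[v]:.4f}\t{cc[v]:.4f}")
print("rho =", round(spearman_rank_correlation(bc, cc), 4))
loops = enumerate_loops(d, max_length=3)
print(len(loops), "loops, all",
      {lp.loop_class for lp in loops})
s = centrality_ensemble(d, n_replicates=200, n_mutations=5, seed=7)
print([round(q, 4) for q in s.per_variable["betweenness"]["Depressive symptoms"]])
```

prints

```
Physical activity       0.5039  0.3636
Brain perfusion         0.4421  0.3636
Cerebral endothelial dysfunction        0.3947  0.3125
rho = 0.5935
38 loops, all {'reinforcing'}
[0.0733, 0.089, 0.1294]
```

Physical activity is the most central connector in this loop-table subgraph
(it mediates half of all shortest paths between other variable pairs, after
normalization), every feedback loop implied by the table is reinforcing,
and the quartile triple is the robustness band for the betweenness of
depressive symptoms over 200 mutated diagrams: the point estimate 0.0943
sits inside its interquartile range [0.0733, 0.1294].

The same pipeline runs from the shell:

```sh
cldnet run --edges edges.csv --variables variables.csv --seed 7 \
       --outdir out --export-format graphml
cldnet loops --edges edges.csv --variables variables.csv --containing "Physical activity"
cldnet simulate --n-variables 38 --n-connections 150 --seed 1
```

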