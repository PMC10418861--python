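# hetepath

Metapath-constrained HeteSim relevance ranking and layered hub analysis on
UMLS-style predication knowledge graphs — the computational core of
literature-based drug repurposing: given a graph of subject–PREDICATE–object
assertions extracted from biomedical text (drug TREATS disease, drug AFFECTS
gene, gene ASSOCIATED_WITH disease, ...), rank candidate drugs by how
specifically the literature connects them to a disease and its
standard-of-care therapy.

It is written for computational drug-repurposing and literature-based
discovery work: people who have (or can emulate) a SemMedDB-style predication
extract and want a transparent, deterministic, fully testable ranking
pipeline at desk scale.

## The method

**Knowledge graph.** Nodes are biomedical concepts keyed by CUI (`C` + 7
digits) with a UMLS semantic type (PHSU pharmacologic substance, DSYN
disease, GNGM gene, AAPP protein, CLND clinical drug, TOPP procedure).
Edges are directed predications with a support count; duplicates aggregate,
self-loops are dropped.

**Metapaths.** A metapath is a type-level template
`PHSU -[AFFECTS>]- GNGM -[ASSOCIATED_WITH>]- DSYN` (with `<` marking reverse
traversal). All metapaths of bounded length between the allowed source types
and a target node are enumerated from the data.

**HeteSim.** The relevance of source *s* to target *t* along metapath *P*
splits *P* at its midpoint and walks probability mass inward from both ends
through row-stochastic transition operators:

    HeteSim(s, t | P) = cos( e_s · T_1 ⋯ T_k ,  e_t · T'_L ⋯ T'_{k+1} )

where `T_i` is the row-normalized adjacency of step *i* and `T'_i` of the
reversed step. Odd-length metapaths insert the middle step's edges as
instance nodes and apply the even rule. Scores are in [0, 1]; 0 when either
side cannot reach the midpoint. A brute-force walk enumerator
(`hetesim_brute_force`) provides an independent oracle with no matrix
algebra.

**DWPC.** The degree-weighted path count damps each concrete path by
`∏ degree(v)^(−w)` over its nodes (endpoints included), so paths through
promiscuous hubs — and promiscuous candidate drugs — count less. `w = 0`
recovers the plain path count.

**Simulations and the hub pipeline.** A *simulation* ranks all sources of
allowed types against target(s) by mean HeteSim over all metapaths, min-max
normalized per simulation. The layered pipeline then selects *hubs*
(sources with normalized score ≥ 0.2, up to 14), runs one simulation per
hub, *cross-evaluates* which candidates pass the threshold in how many hub
simulations, *back-evaluates* a designated candidate, and ranks the final
candidates by (recurrence across layers, then mean normalized score).
Unsupervised rank aggregation (mean-rank and an iteratively reweighted
consensus) is available for combining per-metapath or per-target rankings.

**Synthetic graphs.** `hetepath.synthetic` generates SemMedDB-like graphs
with a skewed degree distribution, a disease target, a standard-of-care
drug, planted adjuvant drugs connected through several metapath families,
and high-degree decoy drugs with no planted connection — so the whole
pipeline is testable without any licensed data.

## Worked example

```python
from hetepath import (ConceptNode, KnowledgeGraph, Predication,
                      hetesim_score, parse_metapath)

g = KnowledgeGraph()
for cui, name, st in [("C9000001", "d1", "PHSU"), ("C9000002", "d2", "PHSU"),
                      ("C9000011", "g1", "GNGM"), ("C9000012", "g2", "GNGM"),
                      ("C9000021", "D", "DSYN")]:
    g.add_node(ConceptNode(cui, name, st))
for s, p, o in [("C9000001", "AFFECTS", "C9000011"),
                ("C9000001", "AFFECTS", "C9000012"),
                ("C9000002", "AFFECTS", "C9000011"),
                ("C9000011", "ASSOCIATED_WITH", "C9000021"),
                ("C9000012", "ASSOCIATED_WITH", "C9000021")]:
    g.add_edge(Predication(s, p, o))

mp = parse_metapath("PHSU-[AFFECTS>]-GNGM-[ASSOCIATED_WITH>]-DSYN")
print(hetesim_score(g, "C9000001", "C9000021", mp).value)  # 1.0
print(hetesim_score(g, "C9000002", "C9000021", mp).value)  # 0.7071067811865475
```

Drug `d1` affects both genes in exactly the proportions the disease is
associated with them, so its midpoint gene distribution matches the
disease's perfectly (score 1.0). Drug `d2` covers only one of the two genes:
cos(⟨1,0⟩, ⟨0.5,0.5⟩) = 1/√2 ≈ 0.70711. The `examples/` directory walks
through every capability the same way (I/O, metapaths + DWPC, HeteSim,
simulations, the full hub pipeline, cross-evaluation replay).

A command-line front end wraps the library:

```bash
hetepath generate --seed 1 --out out/        # synthetic graph + ground truth
hetepath run --config run.yaml --out out/    # full layered pipeline
hetepath recover --n-runs 20 --out out/      # planted-signal recovery report
hetepath crosseval --scores hub_scores.tsv --candidate C9200005
```

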