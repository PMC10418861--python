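"""Seeded generator of SemMedDB-like predication graphs with planted truth.

Real predication databases are built from tens of millions of articles and
cannot ship with a desk-scale package, so every stage here is exercised on a
synthetic stand-in that reproduces the features the method cares about:

* a typed multigraph over UMLS-like semantic types with a skewed
  (preferential-attachment) degree distribution;
* a disease target node and a standard-of-care drug that TREATS it;
* a handful of *planted adjuvant drugs* connected to the disease through
  several concrete instances spread over multiple metapath families
  (drug-AFFECTS->gene-ASSOCIATED_WITH->disease; drug-INTERACTS_WITH->
  standard drug-TREATS->disease; drug-TREATS->comorbidity-COEXISTS_WITH->
  disease);
* *popular decoy drugs* with top-5% degree but no instance on the planted
  metapath families — the confound that raw path counts reward and that
  normalized HeteSim / DWPC corrections must not.

Synthetic CUIs live in the reserved C9xxxxxx range so they can never collide
with real UMLS identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hubs import PipelineConfig, PipelineResult, run_pipeline
from .kg import ConceptNode, KnowledgeGraph, Predication
from .simulation import SimulationSpec

logger = logging.getLogger(__name__)

PREDICATES = (
    "TREATS", "INHIBITS", "CAUSES", "AFFECTS",
    "ASSOCIATED_WITH", "INTERACTS_WITH", "PREDISPOSES", "COEXISTS_WITH",
)

# background schema: (subject semtype, predicate, object semtype, weight)
_SCHEMA = (
    ("PHSU", "AFFECTS", "GNGM", 3.0),
    ("PHSU", "AFFECTS", "AAPP", 2.0),
    ("PHSU", "INHIBITS", "AAPP", 1.5),
    ("PHSU", "INTERACTS_WITH", "PHSU", 1.5),
    ("PHSU", "TREATS", "DSYN", 2.0),
    ("PHSU", "CAUSES", "DSYN", 0.5),
    ("CLND", "TREATS", "DSYN", 1.5),
    ("CLND", "AFFECTS", "GNGM", 1.0),
    ("TOPP", "TREATS", "DSYN", 1.0),
    ("GNGM", "ASSOCIATED_WITH", "DSYN", 3.0),
    ("GNGM", "COEXISTS_WITH", "GNGM", 1.0),
    ("GNGM", "CAUSES", "DSYN", 1.0),
    ("AAPP", "ASSOCIATED_WITH", "DSYN", 1.5),
    ("AAPP", "INTERACTS_WITH", "AAPP", 1.0),
    ("AAPP", "AFFECTS", "GNGM", 1.0),
    ("DSYN", "COEXISTS_WITH", "DSYN", 1.0),
    ("DSYN", "PREDISPOSES", "DSYN", 0.5),
)

DEFAULT_N_PER_SEMTYPE = {
    "PHSU": 200, "CLND": 50, "GNGM": 100, "AAPP": 100, "DSYN": 40, "TOPP": 30,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_semtype: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_SEMTYPE)
    )
    background_edge_count: int = 800
    degree_skew: float = 1.0
    n_planted: int = 3
    planted_path_multiplicity: int = 4
    n_popular_decoys: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_semtype.values()):
            raise ValueError("all semtype counts must be positive")
        if self.n_planted < 0 or self.n_popular_decoys < 0:
            raise ValueError("n_planted and n_popular_decoys must be >= 0")
        if self.background_edge_count < 0 or self.degree_skew < 0:
            raise ValueError("background_edge_count and degree_skew must be >= 0")
        needed = 1 + self.n_planted + self.n_popular_decoys
        if self.n_per_semtype.get("PHSU", 0) < needed:
            raise ValueError(
                f"PHSU budget too small: need >= {needed} for standard drug, "
                "planted drugs and decoys"
            )
        if self.planted_path_multiplicity < 0:
            raise ValueError("planted_path_multiplicity must be >= 0")
        if self.n_per_semtype.get("DSYN", 0) < 2 or self.n_per_semtype.get("GNGM", 0) < max(
            1, self.planted_path_multiplicity
        ):
            raise ValueError("DSYN/GNGM budgets too small for planted structure")


@dataclass(frozen=True)
class GroundTruth:
    target_disease_cui: str
    standard_drug_cui: str
    planted_cuis: frozenset[str]
    planted_hub_cuis: frozenset[str]  # genes/diseases wired to planted drugs
    decoy_popular_cuis: frozenset[str]

    def __post_init__(self) -> None:
        if self.planted_cuis & self.decoy_popular_cuis:
            raise ValueError("planted and decoy sets must be disjoint")


def _family_budget(multiplicity: int) -> tuple[int, int, int]:
    """Split the per-drug path multiplicity over the three metapath
    families (shared genes, standard-drug interaction, comorbidity)."""
    if multiplicity == 0:
        return 0, 0, 0
    n_b = 1 if multiplicity >= 2 else 0
    n_c = 1 if multiplicity >= 3 else 0
    n_a = max(multiplicity - n_b - n_c, 1)
    return n_a, n_b, n_c


def generate(config: SyntheticConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build a synthetic predication graph; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    graph = KnowledgeGraph()

    cuis: dict[str, list[str]] = {}
    counter = 9000000
    for semtype in sorted(config.n_per_semtype):
        cuis[semtype] = []
        for i in range(config.n_per_semtype[semtype]):
            cui = f"C{counter}"
            counter += 1
            cuis[semtype].append(cui)
            graph.add_node(ConceptNode(cui, f"{semtype.lower()}_{i}", semtype))

    target = cuis["DSYN"][0]
    comorbid = cuis["DSYN"][1]
    standard = cuis["PHSU"][0]
    planted = cuis["PHSU"][1 : 1 + config.n_planted]
    decoys = cuis["PHSU"][
        1 + config.n_planted : 1 + config.n_planted + config.n_popular_decoys
    ]
    n_a, n_b, n_c = _family_budget(config.planted_path_multiplicity)
    hub_genes = cuis["GNGM"][:n_a]

    def add(s: str, p: str, o: str, support: int = 1) -> None:
        graph.add_edge(Predication(s, p, o, support))

    # planted structure ------------------------------------------------
    add(standard, "TREATS", target, support=5)
    for gene in hub_genes:
        # two predicate families tie each planted hub gene to the target,
        # mirroring well-studied disease genes (associated with + causal)
        add(gene, "ASSOCIATED_WITH", target, support=3)
        add(gene, "CAUSES", target, support=2)
    planted_hubs: set[str] = set(hub_genes)
    if n_c:
        add(comorbid, "COEXISTS_WITH", target, support=2)
        add(comorbid, "PREDISPOSES", target, support=2)
        planted_hubs.add(comorbid)
    for drug in planted:
        for gene in hub_genes:  # family A
            add(drug, "AFFECTS", gene, support=2)
        if n_b:  # family B
            add(drug, "INTERACTS_WITH", standard, support=2)
        if n_c:  # family C
            add(drug, "TREATS", comorbid, support=2)

    # background with preferential attachment -------------------------
    # planted drugs, decoys and planted hubs are wired explicitly; keeping
    # them out of the background pool keeps the planted signal interpretable
    reserved = set(planted) | set(decoys) | planted_hubs
    pool = {st: [c for c in cuis[st] if c not in reserved] for st in cuis}
    degree = {c: 0 for st in cuis for c in cuis[st]}
    for e in graph.edges():
        degree[e.subject_cui] += 1
        degree[e.object_cui] += 1

    schema_w = np.array([w for *_, w in _SCHEMA])
    schema_p = schema_w / schema_w.sum()

    def pick(candidates: list[str], exclude: str | None = None) -> str:
        opts = [c for c in candidates if c != exclude]
        wts = np.array([(degree[c] + 1.0) ** config.degree_skew for c in opts])
        return opts[int(rng.choice(len(opts), p=wts / wts.sum()))]

    for _ in range(config.background_edge_count):
        st_s, pred, st_o, _w = _SCHEMA[int(rng.choice(len(_SCHEMA), p=schema_p))]
        s = pick(pool[st_s])
        o = pick(pool[st_o], exclude=s)
        add(s, pred, o)
        degree[s] += 1
        degree[o] += 1

    # popular decoys: top-5% degree, zero planted-family instances -----
    diseases_near_target = {
        d for d in cuis["DSYN"]
        if d != target and (
            graph.successors(d, "COEXISTS_WITH").__contains__(target)
            or target in graph.successors(d, "COEXISTS_WITH", reverse=True)
            or target in graph.successors(d, "PREDISPOSES")
        )
    }
    genes_near_target = {
        g for g in cuis["GNGM"]
        if target in graph.successors(g, "ASSOCIATED_WITH")
        or target in graph.successors(g, "CAUSES")
    }
    decoy_targets = {
        "AFFECTS_GNGM": [g for g in pool["GNGM"] if g not in genes_near_target],
        "AFFECTS_AAPP": pool["AAPP"],
        "INHIBITS_AAPP": pool["AAPP"],
        "TREATS_DSYN": [
            d for d in pool["DSYN"] if d not in diseases_near_target and d != target
        ],
        "INTERACTS_WITH_PHSU": [
            c for c in pool["PHSU"] if c != standard
        ],
    }
    decoy_kinds = sorted(decoy_targets)
    q95 = float(np.quantile(list(degree.values()), 0.95))
    k_decoy = max(int(np.ceil(q95)) + 5, 40)
    for decoy in decoys:
        added = 0
        while added < k_decoy:
            kind = decoy_kinds[int(rng.integers(len(decoy_kinds)))]
            pred = kind.rsplit("_", 1)[0]
            opts = decoy_targets[kind]
            o = opts[int(rng.integers(len(opts)))]
            if o == decoy:
                continue
            add(decoy, pred, o)
            degree[decoy] += 1
            degree[o] += 1
            added += 1

    truth = GroundTruth(
        target_disease_cui=target,
        standard_drug_cui=standard,
        planted_cuis=frozenset(planted),
        planted_hub_cuis=frozenset(planted_hubs),
        decoy_popular_cuis=frozenset(decoys),
    )
    return graph, truth


def write_ground_truth(truth: GroundTruth, sink: str | Path) -> None:
    """Ground-truth sidecar: one row per special node with its role."""
    rows = [("target_disease", truth.target_disease_cui),
            ("standard_drug", truth.standard_drug_cui)]
    rows += [("planted_adjuvant", c) for c in sorted(truth.planted_cuis)]
    rows += [("planted_hub", c) for c in sorted(truth.planted_hub_cuis)]
    rows += [("popular_decoy", c) for c in sorted(truth.decoy_popular_cuis)]
    pd.DataFrame(rows, columns=["role", "cui"]).to_csv(sink, sep="\t", index=False)


def read_ground_truth(source: str | Path) -> GroundTruth:
    df = pd.read_csv(source, sep="\t", dtype=str)
    by_role: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        by_role.setdefault(row.role, []).append(row.cui)
    return GroundTruth(
        target_disease_cui=by_role["target_disease"][0],
        standard_drug_cui=by_role["standard_drug"][0],
        planted_cuis=frozenset(by_role.get("planted_adjuvant", ())),
        planted_hub_cuis=frozenset(by_role.get("planted_hub", ())),
        decoy_popular_cuis=frozenset(by_role.get("popular_decoy", ())),
    )


# ---------------------------------------------------------------------------
# the two-layer recovery harness
# ---------------------------------------------------------------------------

def default_pipeline_config(
    truth: GroundTruth,
    scoring: str = "hetesim",
    max_len: int = 3,
    threshold: float = 0.2,
    max_hubs: int = 14,
) -> PipelineConfig:
    """The standard two-layer study design on a synthetic graph: a drug
    ranking against {disease, standard drug}, a gene/disease hub-finding run
    against the disease, then per-hub drug/protein/disease simulations."""
    drug_layer = SimulationSpec(
        name="drug_layer",
        target_cuis=(truth.target_disease_cui, truth.standard_drug_cui),
        source_semtypes=frozenset({"PHSU", "CLND", "TOPP"}),
        max_metapath_length=max_len,
        scoring=scoring,
    )
    hub_finder = SimulationSpec(
        name="hub_finder",
        target_cuis=(truth.target_disease_cui,),
        source_semtypes=frozenset({"GNGM", "DSYN"}),
        max_metapath_length=max_len,
        scoring=scoring,
    )
    hub_template = SimulationSpec(
        name="hub",
        target_cuis=("C9999999",),  # replaced per hub
        source_semtypes=frozenset({"PHSU", "AAPP", "DSYN"}),
        max_metapath_length=max_len,
        scoring=scoring,
    )
    return PipelineConfig(
        preliminary=(drug_layer, hub_finder),
        hub_source_simulations=("hub_finder",),
        hub_threshold=threshold,
        max_hubs=max_hubs,
        hub_allowed_semtypes=("GNGM", "DSYN"),
        hub_layer_template=hub_template,
        back_eval_cui=min(truth.planted_cuis) if truth.planted_cuis else None,
        candidate_semtypes=("PHSU", "CLND"),
    )


@dataclass(frozen=True)
class RecoveryRun:
    seed: int
    planted_ranks: tuple[int, ...]  # imputed len(report)+1 when absent
    decoy_ranks: tuple[int, ...]
    n_final: int
    all_planted_in_top_k: bool
    decoy_beats_all_planted: bool
    error: str | None = None


@dataclass(frozen=True)
class RecoveryReport:
    runs: tuple[RecoveryRun, ...]
    top_k: int
    hit_rate: float  # fraction of clean runs with all planted in top k


def _rank_of(final, cui: str) -> int | None:
    for f in final:
        if f.cui == cui:
            return f.rank
    return None


def parameter_recovery_experiment(
    config: SyntheticConfig,
    n_runs: int = 20,
    pipeline_config: PipelineConfig | None = None,
    top_k: int = 10,
    scoring: str = "hetesim",
) -> RecoveryReport:
    """Generate, run the two-layer pipeline, and score planted-drug recovery.

    For seeds ``config.seed + 0 .. + n_runs-1``: build a fresh graph, run
    the pipeline with targets {disease, standard drug}, and record where the
    planted adjuvants land in the final report.  A failed run is recorded
    (``error``) and excluded from the hit rate, not fatal.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs: list[RecoveryRun] = []
    for i in range(n_runs):
        run_seed = config.seed + i
        try:
            graph, truth = generate(replace(config, seed=run_seed))
            pc = pipeline_config or default_pipeline_config(truth, scoring=scoring)
            result: PipelineResult = run_pipeline(graph, pc)
            imputed = len(result.final) + 1
            p_ranks = tuple(
                _rank_of(result.final, c) or imputed for c in sorted(truth.planted_cuis)
            )
            d_ranks = tuple(
                _rank_of(result.final, c) or imputed
                for c in sorted(truth.decoy_popular_cuis)
            )
            all_top = all(r <= top_k for r in p_ranks)
            beats = bool(d_ranks) and bool(p_ranks) and min(d_ranks) < min(p_ranks)
            runs.append(
                RecoveryRun(
                    seed=run_seed,
                    planted_ranks=p_ranks,
                    decoy_ranks=d_ranks,
                    n_final=len(result.final),
                    all_planted_in_top_k=all_top,
                    decoy_beats_all_planted=beats,
                )
            )
        except Exception as exc:  # recorded, not fatal to the experiment
            logger.exception("recovery run with seed %d failed", run_seed)
            runs.append(
                RecoveryRun(
                    seed=run_seed, planted_ranks=(), decoy_ranks=(), n_final=0,
                    all_planted_in_top_k=False, decoy_beats_all_planted=False,
                    error=str(exc),
                )
            )
    clean = [r for r in runs if r.error is None]
    hit_rate = (
        sum(r.all_planted_in_top_k for r in clean) / len(clean) if clean else 0.0
    )
    return RecoveryReport(runs=tuple(runs), top_k=top_k, hit_rate=hit_rate)
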