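"""Metapath evidence propagation and permutation-test disease prioritization.

Three built-in models rank diseases (or phenotypes) by evidence propagated
from a seed gene set through the knowledge graph:

* ``model_1`` — direct literature gene–disease associations (one step);
* ``model_2`` — pathway-mediated: seed genes → shared pathways → pathway
  co-members → their disease associations (three steps);
* ``model_3`` — cross-species pathway-mediated: seed genes → orthologues in a
  bridge taxon → that taxon's pathways → co-members → orthologues back in the
  seed taxon → disease associations (five steps).

The raw relevance score of a target is the number of distinct metapath
instances (edge sequences following the step types) connecting any seed gene
to the target, optionally weighted by edge weights and/or per-source-degree
normalized.  Operationally it is the seed indicator vector pushed through the
chain of per-step adjacency matrices.  Scores are max-normalized per run, and
significance is assessed by re-propagating random same-size seed sets drawn
from the gene universe of the seed's taxon (add-one permutation p-values).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph import (
    SEED_TAXON,
    ConfigurationError,
    GeneSet,
    KnowledgeGraph,
    Metapath,
    MetapathStep,
    ValidationError,
    qualify,
    validate_metapath,
)

__all__ = [
    "PropagationConfig",
    "RelevanceTable",
    "builtin_model",
    "propagate_evidence",
    "normalize_scores",
    "permutation_pvalues",
    "prioritize",
]

logger = logging.getLogger("evfusion.prioritize")

MODEL_NAMES = ("model_1", "model_2", "model_3")


@dataclass(frozen=True)
class PropagationConfig:
    """How evidence moves along a metapath.

    ``step_normalization="per_source_degree"`` divides each step's
    contribution by the source node's degree under that step's link type
    (degree-0 sources contribute nothing).  ``permutation_universe`` picks the
    null gene pool: every gene of the seed's taxon (default, unconditional
    null) or only genes carrying at least one first-step edge.
    """

    metapath: Metapath
    use_edge_weights: bool = False
    step_normalization: str = "none"  # none | per_source_degree
    permutation_universe: str = "taxon"  # taxon | first_step

    def __post_init__(self) -> None:
        if self.step_normalization not in ("none", "per_source_degree"):
            raise ConfigurationError(
                f"unknown step_normalization {self.step_normalization!r}"
            )
        if self.permutation_universe not in ("taxon", "first_step"):
            raise ConfigurationError(
                f"unknown permutation_universe {self.permutation_universe!r}"
            )


@dataclass
class RelevanceTable:
    """Ranked targets with raw/normalized scores and permutation p-values."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {self.metadata[key]}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def builtin_model(
    name: str,
    target_type: str = "disease",
    bridge_taxon: str | None = None,
) -> Metapath:
    """Return one of the three registered prioritization metapaths.

    ``model_3`` needs ``bridge_taxon`` (the non-seed species whose pathway
    annotations carry the evidence); its returning orthologue step is pinned
    to the seed set's taxon, resolved when a propagation runs.
    """
    if name not in MODEL_NAMES:
        raise ConfigurationError(f"unknown model {name!r}; expected {MODEL_NAMES}")
    if target_type not in ("disease", "phenotype"):
        raise ConfigurationError(
            f"target_type must be 'disease' or 'phenotype', got {target_type!r}"
        )
    last = MetapathStep(f"gene_{target_type}")
    if name == "model_1":
        steps = (last,)
    elif name == "model_2":
        steps = (
            MetapathStep("gene_pathway"),
            MetapathStep("gene_pathway", reverse=True),
            last,
        )
    else:
        if bridge_taxon is None:
            raise ConfigurationError("model_3 requires a bridge_taxon")
        steps = (
            MetapathStep("gene_orthologue", taxon=qualify(bridge_taxon, "taxon")),
            MetapathStep("gene_pathway"),
            MetapathStep("gene_pathway", reverse=True),
            MetapathStep("gene_orthologue", taxon=SEED_TAXON),
            last,
        )
    return Metapath(f"{name}:{target_type}", steps)


# -- matrix chain ----------------------------------------------------------


class _Chain:
    """Per-run cache: entity indexes and the per-step sparse matrices."""

    def __init__(
        self, graph: KnowledgeGraph, cfg: PropagationConfig, seed_taxon: str | None
    ) -> None:
        msgs = validate_metapath(graph, cfg.metapath)
        if msgs:
            raise ConfigurationError(
                "invalid metapath "
                + cfg.metapath.name
                + ": "
                + "; ".join(msgs)
            )
        self.graph = graph
        self.cfg = cfg
        self.gene_index = {g: i for i, g in enumerate(graph.entities_of_type("gene"))}
        self._type_index: dict[str, dict[str, int]] = {"gene": self.gene_index}
        self.matrices = [
            self._step_matrix(step, seed_taxon) for step in cfg.metapath.steps
        ]
        self.target_ids = sorted(self._index_for(cfg.metapath.target_entity_type))

    def _index_for(self, entity_type: str) -> dict[str, int]:
        if entity_type not in self._type_index:
            ids = self.graph.entities_of_type(entity_type)
            self._type_index[entity_type] = {x: i for i, x in enumerate(ids)}
        return self._type_index[entity_type]

    def _step_matrix(self, step: MetapathStep, seed_taxon: str | None) -> sp.csr_matrix:
        rows_idx = self._index_for(step.source_entity_type)
        cols_idx = self._index_for(step.target_entity_type)
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        same_type = step.source_entity_type == step.target_entity_type
        for e in self.graph.edges(step.link_type):
            w = e.weight if self.cfg.use_edge_weights else 1.0
            if same_type:
                rows += [rows_idx[e.source], rows_idx[e.target]]
                cols += [cols_idx[e.target], cols_idx[e.source]]
                vals += [w, w]
            elif step.reverse:
                rows.append(rows_idx[e.target])
                cols.append(cols_idx[e.source])
                vals.append(w)
            else:
                rows.append(rows_idx[e.source])
                cols.append(cols_idx[e.target])
                vals.append(w)
        m = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(rows_idx), len(cols_idx))
        )
        if self.cfg.step_normalization == "per_source_degree":
            deg = np.asarray((m != 0).sum(axis=1)).ravel().astype(float)
            inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
            m = sp.diags(inv) @ m
        taxon = step.taxon
        if taxon == SEED_TAXON:
            if seed_taxon is None:
                raise ConfigurationError(
                    "metapath requires the seed taxon but the seed genes "
                    "carry no taxon annotation"
                )
            taxon = seed_taxon
        if taxon is not None:
            keep = np.zeros(len(cols_idx))
            for g, j in cols_idx.items():
                if self.graph.taxon_of_gene.get(g) == taxon:
                    keep[j] = 1.0
            m = m @ sp.diags(keep)
        return sp.csr_matrix(m)

    def push(self, indicators: sp.csr_matrix) -> np.ndarray:
        """Push one or more seed indicator rows through the chain."""
        out = indicators
        for m in self.matrices:
            out = out @ m
        return np.asarray(
            out.todense() if sp.issparse(out) else out, dtype=float
        )


def _seed_in_graph(graph: KnowledgeGraph, seed: GeneSet) -> list[str]:
    qualified = {qualify(g, "gene") for g in seed.members}
    present = sorted(qualified & set(graph.entities_of_type("gene")))
    missing = sorted(qualified - set(present))
    if missing:
        logger.warning(
            "seed set %s: %d gene(s) absent from the graph: %s",
            seed.name,
            len(missing),
            ", ".join(missing),
        )
    return present


def _seed_taxon(graph: KnowledgeGraph, present: Sequence[str]) -> str | None:
    taxa = Counter(graph.taxon_of_gene.get(g) for g in present)
    if not taxa:
        return None
    return taxa.most_common(1)[0][0]


def _indicator(
    chain: _Chain, gene_lists: Sequence[Sequence[str]]
) -> sp.csr_matrix:
    rows, cols = [], []
    for i, genes in enumerate(gene_lists):
        for g in genes:
            rows.append(i)
            cols.append(chain.gene_index[g])
    data = np.ones(len(rows))
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_lists), len(chain.gene_index))
    )


def propagate_evidence(
    graph: KnowledgeGraph, seed: GeneSet, cfg: PropagationConfig
) -> dict[str, float]:
    """Raw relevance scores: target id → propagated evidence mass (> 0 only).

    Equals the sum over all metapath instances from any seed gene to the
    target of the product of step contributions; deterministic and
    independent of seed-member ordering.
    """
    present = _seed_in_graph(graph, seed)
    if not present:
        logger.warning(
            "seed set %s shares no genes with the graph; all scores are zero",
            seed.name,
        )
        return {}
    chain = _Chain(graph, cfg, _seed_taxon(graph, present))
    scores = chain.push(_indicator(chain, [present]))[0]
    return {
        t: float(s) for t, s in zip(chain.target_ids, scores) if s > 0
    }


def normalize_scores(raw: Mapping[str, float]) -> dict[str, float]:
    """Divide every score by the maximum (Table-style relevance in [0, 1]).

    An all-zero (or empty) input is returned unchanged; callers flag that in
    run metadata.
    """
    if any(v < 0 for v in raw.values()):
        raise ValidationError("raw scores must be non-negative")
    top = max(raw.values(), default=0.0)
    if top == 0:
        return dict(raw)
    return {t: v / top for t, v in raw.items()}


def _null_universe(
    graph: KnowledgeGraph,
    cfg: PropagationConfig,
    seed_taxon: str | None,
) -> list[str]:
    genes = [
        g
        for g in graph.entities_of_type("gene")
        if graph.taxon_of_gene.get(g) == seed_taxon
    ]
    if cfg.permutation_universe == "first_step":
        first = cfg.metapath.steps[0].link_type
        genes = [g for g in genes if graph.degree(g, first) > 0]
    return genes


def permutation_pvalues(
    graph: KnowledgeGraph,
    seed: GeneSet,
    cfg: PropagationConfig,
    n_perm: int = 999,
    rng_seed: int = 0,
) -> dict[str, float]:
    """Add-one permutation p-values for every target with a positive score.

    ``n_perm`` random gene sets of size ``|seed ∩ universe|`` are drawn
    without replacement from the null universe; for each target,
    ``p = (1 + #{permutations with score ≥ observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be ≥ 1")
    present = _seed_in_graph(graph, seed)
    seed_taxon = _seed_taxon(graph, present)
    chain = _Chain(graph, cfg, seed_taxon)
    universe = _null_universe(graph, cfg, seed_taxon)
    retained = [g for g in present if g in set(universe)]
    k = len(retained)
    if k == 0:
        return {}
    if k >= len(universe):
        raise ConfigurationError(
            f"seed size {k} must be smaller than the null universe "
            f"({len(universe)} genes)"
        )
    observed = chain.push(_indicator(chain, [present]))[0]

    rng = np.random.default_rng(rng_seed)
    # one row of uniforms per permutation; the k smallest positions form the
    # drawn set — a vectorized sample-without-replacement
    order = np.argsort(rng.random((n_perm, len(universe))), axis=1)[:, :k]
    uni = np.array(universe)
    perm_sets = [uni[row] for row in order]
    null_scores = chain.push(_indicator(chain, perm_sets))

    tol = 1e-9 * np.maximum(1.0, np.abs(observed))
    exceed = (null_scores >= observed[None, :] - tol).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return {
        t: float(p)
        for t, s, p in zip(chain.target_ids, observed, pvals)
        if s > 0
    }


def prioritize(
    graph: KnowledgeGraph,
    seed: GeneSet,
    model: str = "model_1",
    target_type: str = "disease",
    bridge_taxon: str | None = None,
    n_perm: int = 999,
    rng_seed: int = 0,
    top_k: int = 20,
    full_table: bool = False,
    use_edge_weights: bool = False,
    step_normalization: str = "none",
    permutation_universe: str = "taxon",
) -> RelevanceTable:
    """Full pipeline: propagate → normalize → permutation p → rank → top-k.

    Ranks are 1..n over positive-score targets, descending raw score with
    lexicographic target-id tie-break; ``top_k`` truncates the report (pass
    ``full_table=True`` to keep every scored target).
    """
    if top_k < 1:
        raise ConfigurationError("top_k must be ≥ 1")
    mp = builtin_model(model, target_type, bridge_taxon)
    cfg = PropagationConfig(
        metapath=mp,
        use_edge_weights=use_edge_weights,
        step_normalization=step_normalization,
        permutation_universe=permutation_universe,
    )
    raw = propagate_evidence(graph, seed, cfg)
    norm = normalize_scores(raw)
    pvals = permutation_pvalues(graph, seed, cfg, n_perm, rng_seed) if raw else {}
    order = sorted(raw, key=lambda t: (-raw[t], t))
    rows = [
        {
            "target_id": t,
            "target_name": t.partition(":")[2],
            "raw_score": raw[t],
            "relevance_score": norm[t],
            "p_value": pvals[t],
            "rank": i + 1,
        }
        for i, t in enumerate(order)
    ]
    if not full_table:
        rows = rows[:top_k]
    table = pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "target_name",
            "raw_score",
            "relevance_score",
            "p_value",
            "rank",
        ],
    )
    metadata = {
        "seed_set": seed.name,
        "model": model,
        "target_type": target_type,
        "bridge_taxon": bridge_taxon or "",
        "n_permutations": n_perm,
        "rng_seed": rng_seed,
        "top_k": top_k,
        "all_zero": not raw,
        "n_scored_targets": len(raw),
    }
    return RelevanceTable(table=table, metadata=metadata)
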