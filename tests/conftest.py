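"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from evfusion.graph import (
    SEED_TAXON,
    GeneSet,
    KnowledgeGraph,
    MetapathStep,
    entity_type_of,
)


def dfs_path_scores(
    graph: KnowledgeGraph,
    seed_genes: list[str],
    steps: tuple[MetapathStep, ...],
    seed_taxon: str | None = None,
    use_weights: bool = False,
    degree_norm: bool = False,
) -> dict[str, float]:
    """Brute-force oracle: enumerate every metapath instance one edge at a
    time and sum the products of step contributions.  Independent of the
    matrix-chain implementation under test."""
    totals: Counter = Counter()

    def extend(node: str, k: int, contrib: float) -> None:
        if k == len(steps):
            totals[node] += contrib
            return
        step = steps[k]
        taxon = step.taxon
        if taxon == SEED_TAXON:
            taxon = seed_taxon
        for nbr in sorted(graph.neighbors(node, step.link_type)):
            if entity_type_of(nbr) != step.target_entity_type:
                continue
            if taxon is not None and graph.taxon_of_gene.get(nbr) != taxon:
                continue
            w = (
                graph.edge_weight(node, nbr, step.link_type)
                if use_weights
                else 1.0
            )
            if degree_norm:
                w = w / graph.degree(node, step.link_type)
            extend(nbr, k + 1, contrib * w)

    for g in seed_genes:
        if g in set(graph.entities_of_type("gene")):
            extend(g, 0, 1.0)
    return {t: v for t, v in totals.items() if v > 0}


@pytest.fixture
def toy_direct_graph() -> KnowledgeGraph:
    """g1–d1, g2–d1, g1–d2: the path-counting example graph."""
    g = KnowledgeGraph()
    g.add_edge("gene:g1", "disease:d1", "gene_disease")
    g.add_edge("gene:g2", "disease:d1", "gene_disease")
    g.add_edge("gene:g1", "disease:d2", "gene_disease")
    return g


@pytest.fixture
def pathway_bridge_graph() -> KnowledgeGraph:
    """g1 and g2 share pathway P1; only g2 touches d1 (model-2 showcase)."""
    g = KnowledgeGraph()
    g.add_edge("gene:g1", "pathway:P1", "gene_pathway")
    g.add_edge("gene:g2", "pathway:P1", "gene_pathway")
    g.add_edge("gene:g2", "disease:d1", "gene_disease")
    return g


def seed(*genes: str) -> GeneSet:
    return GeneSet.of("seed", genes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
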