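"""Synthetic knowledge graphs and expression matrices with planted truth.

The graph generator emulates the structure the prioritization models
traverse: per-taxon gene/pathway universes, shared disease and phenotype
universes, Erdős–Rényi background edges per link type, one-to-one orthologue
wiring between the seed taxon and each other taxon, and *planted blocks* — a
disease deliberately wired to a random seed gene set either directly
(exercising the literature model), through a dedicated pathway (the pathway
model), or through orthologue-pathway wiring in a bridge taxon (the
cross-species model).

The expression generator emulates a two-group microarray-style experiment:
i.i.d. Gaussian noise, a planted gene set in which a fraction of members gain
a mean shift of δ standard deviations in the second group, and size-matched
decoy sets with no shift.

Every generator returns a :class:`TruthRecord` — the machine-readable ledger
of what was planted — so recovery can be scored without re-reading generator
internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import ConfigurationError, GeneSet, KnowledgeGraph, qualify


def _config_echo(cfg) -> dict:
    # JSON-normalized (tuples -> lists) so truth records round-trip exactly
    return json.loads(json.dumps(dataclasses.asdict(cfg)))

__all__ = [
    "PlantedBlock",
    "PlantedSet",
    "SyntheticGraphConfig",
    "SyntheticExpressionConfig",
    "TruthRecord",
    "generate_graph",
    "generate_expression",
    "overlapping_seed_sets",
]


@dataclass(frozen=True)
class PlantedBlock:
    """One deliberately wired gene→disease association in a synthetic graph.

    ``direct_fraction`` of the seed genes are linked straight to the disease;
    ``via_pathway`` additionally routes evidence through a dedicated pathway
    whose extra (non-seed) members carry the disease links, in the seed taxon
    or — if ``bridge_taxon`` is set — through orthologues in that taxon.
    """

    disease_id: str | None = None
    n_seed_genes: int = 10
    direct_fraction: float = 1.0
    via_pathway: bool = False
    bridge_taxon: str | None = None
    n_bridge_genes: int = 5


@dataclass(frozen=True)
class PlantedSet:
    """One mean-shifted gene set in a synthetic expression matrix."""

    name: str = "planted_set_1"
    size: int = 50
    shifted_fraction: float = 0.5
    delta: float = 1.0  # shift in units of the noise SD


@dataclass(frozen=True)
class SyntheticGraphConfig:
    n_genes: int = 200  # per taxon
    n_diseases: int = 100
    n_phenotypes: int = 50
    n_pathways: int = 20  # per taxon
    taxa: tuple[str, ...] = ("9606", "10090")  # first entry = seed taxon
    p_gene_disease: float = 0.01
    p_gene_phenotype: float = 0.01
    p_gene_pathway: float = 0.05
    orthologue_coverage: float = 0.8
    gene_disease_weight: str = "constant"  # constant | uniform(0.5, 1.5)
    planted: tuple[PlantedBlock, ...] = (PlantedBlock(),)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_gene_disease, self.p_gene_phenotype, self.p_gene_pathway,
                  self.orthologue_coverage):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if len(self.taxa) < 1:
            raise ConfigurationError("need at least one taxon")
        if self.gene_disease_weight not in ("constant", "uniform"):
            raise ConfigurationError(
                f"unknown gene_disease_weight {self.gene_disease_weight!r}"
            )
        ids = [b.disease_id for b in self.planted if b.disease_id is not None]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("planted disease ids must be distinct")
        for b in self.planted:
            if b.n_seed_genes > self.n_genes:
                raise ConfigurationError(
                    f"planted block needs {b.n_seed_genes} seed genes but the "
                    f"taxon has only {self.n_genes}"
                )
            if b.via_pathway and self.n_pathways == 0:
                raise ConfigurationError(
                    "via-pathway wiring requested but n_pathways is 0"
                )
            if b.bridge_taxon is not None and b.bridge_taxon not in self.taxa[1:]:
                raise ConfigurationError(
                    f"bridge taxon {b.bridge_taxon!r} not among non-seed taxa"
                )


@dataclass(frozen=True)
class SyntheticExpressionConfig:
    n_genes: int = 1000
    n_per_group: int = 10
    noise_sd: float = 1.0
    planted: tuple[PlantedSet, ...] = (PlantedSet(),)
    n_decoy_sets: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("each group needs ≥ 2 samples")
        for ps in self.planted:
            if ps.delta < 0:
                raise ConfigurationError("shift δ must be ≥ 0")
            if ps.size > self.n_genes:
                raise ConfigurationError(
                    f"planted set size {ps.size} exceeds n_genes {self.n_genes}"
                )
            if not 0 <= ps.shifted_fraction <= 1:
                raise ConfigurationError("shifted_fraction outside [0, 1]")


@dataclass
class TruthRecord:
    """What the generator planted, plus a full config echo and the rng seed."""

    kind: str  # "graph" | "expression"
    planted: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


# -- graph generation ------------------------------------------------------


def _bipartite_background(
    rng: np.random.Generator,
    sources: list[str],
    targets: list[str],
    p: float,
    weight_mode: str = "constant",
) -> list[tuple[str, str, float]]:
    if not sources or not targets:
        return []
    mask = rng.random((len(sources), len(targets))) < p
    weights = (
        rng.uniform(0.5, 1.5, mask.shape)
        if weight_mode == "uniform"
        else np.ones(mask.shape)
    )
    return [
        (sources[i], targets[j], float(weights[i, j]))
        for i, j in np.argwhere(mask)
    ]


def generate_graph(cfg: SyntheticGraphConfig) -> tuple[KnowledgeGraph, TruthRecord]:
    """Draw a synthetic knowledge graph and its planted-association ledger."""
    rng = np.random.default_rng(cfg.rng_seed)
    taxa = [qualify(t, "taxon") for t in cfg.taxa]
    locals_ = [t.partition(":")[2] for t in taxa]
    genes = {
        t: [f"gene:{loc}.g{i:04d}" for i in range(cfg.n_genes)]
        for t, loc in zip(taxa, locals_)
    }
    diseases = [f"disease:d{i:03d}" for i in range(cfg.n_diseases)]
    planted_ids = [
        b.disease_id or f"disease:planted{j + 1}"
        for j, b in enumerate(cfg.planted)
    ]
    diseases = sorted(set(diseases) | set(planted_ids))
    phenotypes = [f"phenotype:h{i:03d}" for i in range(cfg.n_phenotypes)]
    pathways = {
        t: [f"pathway:{loc}.p{i:03d}" for i in range(cfg.n_pathways)]
        for t, loc in zip(taxa, locals_)
    }

    graph = KnowledgeGraph()
    for t in taxa:
        for g in genes[t]:
            graph.set_taxon(g, t)
    for pool in (diseases, phenotypes):
        for x in pool:
            graph.add_entity(x)
    for t in taxa:
        for pw in pathways[t]:
            graph.add_entity(pw)

    for t in taxa:
        for g, d, w in _bipartite_background(
            rng, genes[t], diseases, cfg.p_gene_disease, cfg.gene_disease_weight
        ):
            graph.add_edge(g, d, "gene_disease", w)
    for t in taxa:
        for g, h, _ in _bipartite_background(
            rng, genes[t], phenotypes, cfg.p_gene_phenotype
        ):
            graph.add_edge(g, h, "gene_phenotype")
    for t in taxa:
        for g, pw, _ in _bipartite_background(
            rng, genes[t], pathways[t], cfg.p_gene_pathway
        ):
            graph.add_edge(g, pw, "gene_pathway")

    # one-to-one orthologue wiring, seed taxon ↔ each other taxon
    seed_taxon = taxa[0]
    for t in taxa[1:]:
        covered = rng.random(cfg.n_genes) < cfg.orthologue_coverage
        for i in np.flatnonzero(covered):
            graph.add_edge(genes[seed_taxon][i], genes[t][i], "gene_orthologue")

    truth = TruthRecord(
        kind="graph", config=_config_echo(cfg), seed=cfg.rng_seed
    )
    for j, block in enumerate(cfg.planted):
        disease = planted_ids[j]
        idx = rng.choice(cfg.n_genes, size=block.n_seed_genes, replace=False)
        seed_genes = sorted(genes[seed_taxon][i] for i in np.sort(idx))
        n_direct = int(round(block.direct_fraction * block.n_seed_genes))
        for g in seed_genes[:n_direct]:
            graph.add_edge(g, disease, "gene_disease", 1.0)
        record = {
            "disease": disease,
            "seed_genes": seed_genes,
            "mode": "direct",
            "pathway": None,
            "bridge_genes": [],
        }
        if block.via_pathway:
            wiring_taxon = (
                qualify(block.bridge_taxon, "taxon")
                if block.bridge_taxon is not None
                else seed_taxon
            )
            loc = wiring_taxon.partition(":")[2]
            pathway = f"pathway:{loc}.planted{j + 1}"
            seed_pos = {genes[seed_taxon].index(g) for g in seed_genes}
            pool = sorted(set(range(cfg.n_genes)) - seed_pos)
            bridge_pos = sorted(
                rng.choice(pool, size=min(block.n_bridge_genes, len(pool)),
                           replace=False)
            )
            if wiring_taxon == seed_taxon:
                for g in seed_genes:
                    graph.add_edge(g, pathway, "gene_pathway")
                bridge_genes = [genes[seed_taxon][i] for i in bridge_pos]
                for g in bridge_genes:
                    graph.add_edge(g, pathway, "gene_pathway")
                    graph.add_edge(g, disease, "gene_disease", 1.0)
            else:
                # route through orthologues: partners of seed genes join the
                # bridge-taxon pathway; extra bridge members map back to
                # seed-taxon partners that carry the disease links
                for g in seed_genes:
                    i = genes[seed_taxon].index(g)
                    partner = genes[wiring_taxon][i]
                    graph.add_edge(g, partner, "gene_orthologue")
                    graph.add_edge(partner, pathway, "gene_pathway")
                bridge_genes = [genes[wiring_taxon][i] for i in bridge_pos]
                for i, bg in zip(bridge_pos, bridge_genes):
                    back = genes[seed_taxon][i]
                    graph.add_edge(bg, pathway, "gene_pathway")
                    graph.add_edge(back, bg, "gene_orthologue")
                    graph.add_edge(back, disease, "gene_disease", 1.0)
            record["mode"] = (
                "orthologue_pathway" if wiring_taxon != seed_taxon else "pathway"
            )
            record["pathway"] = pathway
            record["bridge_genes"] = bridge_genes
        truth.planted.append(record)
    return graph, truth


def overlapping_seed_sets(
    seed_genes: list[str],
    gene_pool: list[str],
    n_sets: int = 5,
    rng_seed: int = 0,
) -> list[GeneSet]:
    """Derive partly overlapping seed sets from one planted seed gene list.

    The first set is the full planted list; each further set keeps a random
    ~70% of it and adds two random outside genes, mimicking curated gene
    lists that share a core but differ at the margins.
    """
    rng = np.random.default_rng(rng_seed)
    sets = [GeneSet.of("seed_set_1", seed_genes, "planted seed genes")]
    outside = sorted(set(gene_pool) - set(seed_genes))
    for i in range(1, n_sets):
        keep = max(1, int(round(0.7 * len(seed_genes))))
        core = rng.choice(sorted(seed_genes), size=keep, replace=False)
        extra = (
            rng.choice(outside, size=min(2, len(outside)), replace=False)
            if outside
            else []
        )
        sets.append(
            GeneSet.of(
                f"seed_set_{i + 1}",
                list(core) + list(extra),
                "partly overlapping variant",
            )
        )
    return sets


# -- expression generation -------------------------------------------------


def generate_expression(
    cfg: SyntheticExpressionConfig,
) -> tuple[pd.DataFrame, pd.Series, list[GeneSet], TruthRecord]:
    """Draw a two-group expression matrix with planted enriched gene sets.

    Returns (matrix genes × samples, sample → group labels, gene sets
    including decoys, truth record).  Group-2 ("case") means of the shifted
    member genes are raised by δ·SD; everything else is pure noise.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_per_group
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    samples = [f"ctrl{i + 1:02d}" for i in range(n)] + [
        f"case{i + 1:02d}" for i in range(n)
    ]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples)
    matrix = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n))

    truth = TruthRecord(
        kind="expression", config=_config_echo(cfg), seed=cfg.rng_seed
    )
    sets: list[GeneSet] = []
    available = list(range(cfg.n_genes))
    for ps in cfg.planted:
        pool = available if len(available) >= ps.size else list(range(cfg.n_genes))
        members = sorted(rng.choice(pool, size=ps.size, replace=False))
        available = [i for i in available if i not in set(members)]
        n_shift = int(round(ps.shifted_fraction * ps.size))
        shifted = members[:n_shift]
        matrix[np.ix_(shifted, range(n, 2 * n))] += ps.delta * cfg.noise_sd
        sets.append(
            GeneSet.of(ps.name, [gene_ids[i] for i in members], "planted")
        )
        truth.planted.append(
            {
                "set": ps.name,
                "members": [gene_ids[i] for i in members],
                "shifted": [gene_ids[i] for i in shifted],
                "delta": ps.delta,
            }
        )
    decoy_size = cfg.planted[0].size if cfg.planted else 50
    for d in range(cfg.n_decoy_sets):
        pool = available if len(available) >= decoy_size else list(range(cfg.n_genes))
        members = sorted(rng.choice(pool, size=decoy_size, replace=False))
        available = [i for i in available if i not in set(members)]
        name = f"decoy_set_{d + 1}"
        sets.append(
            GeneSet.of(name, [gene_ids[i] for i in members], "decoy, no shift")
        )
        truth.planted.append(
            {
                "set": name,
                "members": [gene_ids[i] for i in members],
                "shifted": [],
                "delta": 0.0,
            }
        )
    expr = pd.DataFrame(matrix, index=gene_ids, columns=samples)
    return expr, groups, sets, truth
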