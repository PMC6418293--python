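"""Heterogeneous knowledge graph of genes, diseases, phenotypes, pathways and taxa.

The graph is multipartite: entities carry one of five types and edges carry a
link type drawn from a fixed registry (gene-disease, gene-phenotype,
gene-pathway, gene-orthologue, gene-taxon).  All link types are undirected
associations; direction only matters for metapath traversal, which is defined
in :mod:`evfusion.prioritize`.

Entity ids are namespaced strings such as ``gene:VPS4A`` or
``disease:C0006142``: the namespace (text before the first colon) must be one
of the five entity types and the local part is free-form (it may itself
contain colons, e.g. ``gene:hsa:VPS4A``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "ENTITY_TYPES",
    "LINK_TYPES",
    "SEED_TAXON",
    "ParseError",
    "ValidationError",
    "ConfigurationError",
    "Entity",
    "LinkType",
    "Edge",
    "GeneSet",
    "MetapathStep",
    "Metapath",
    "KnowledgeGraph",
    "entity_type_of",
    "qualify",
    "load_gene_disease_edges",
    "load_gene_phenotype_edges",
    "load_gmt",
    "load_orthologues",
    "read_gmt_sets",
    "write_gmt_sets",
    "read_seed_sets",
    "validate_metapath",
]

ENTITY_TYPES = ("gene", "disease", "phenotype", "pathway", "taxon")

#: sentinel taxon filter resolved to the seed set's taxon at propagation time
SEED_TAXON = "__seed_taxon__"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Input violated a domain invariant (types, weights, taxa)."""


class ConfigurationError(ValueError):
    """A run configuration is internally inconsistent."""


def entity_type_of(entity_id: str) -> str:
    """Return the entity type encoded in the id's namespace prefix."""
    ns, sep, local = entity_id.partition(":")
    if not sep or not local:
        raise ValidationError(
            f"entity id {entity_id!r} must look like '<type>:<local>'"
        )
    if ns not in ENTITY_TYPES:
        raise ValidationError(
            f"entity id {entity_id!r} has unknown namespace {ns!r}; "
            f"expected one of {ENTITY_TYPES}"
        )
    return ns


def qualify(raw: str, entity_type: str) -> str:
    """Prefix ``raw`` with the entity-type namespace unless already qualified."""
    if raw.startswith(entity_type + ":"):
        return raw
    return f"{entity_type}:{raw}"


@dataclass(frozen=True)
class Entity:
    id: str
    entity_type: str

    def __post_init__(self) -> None:
        derived = entity_type_of(self.id)
        if derived != self.entity_type:
            raise ValidationError(
                f"entity {self.id!r} declared as {self.entity_type!r} but its "
                f"namespace says {derived!r}"
            )

    @property
    def local(self) -> str:
        return self.id.partition(":")[2]


@dataclass(frozen=True)
class LinkType:
    name: str
    source_type: str
    target_type: str
    directedness: str = "undirected"


#: the fixed registry of link types the three prioritization models traverse
LINK_TYPES: Mapping[str, LinkType] = {
    lt.name: lt
    for lt in (
        LinkType("gene_disease", "gene", "disease"),
        LinkType("gene_phenotype", "gene", "phenotype"),
        LinkType("gene_pathway", "gene", "pathway"),
        LinkType("gene_orthologue", "gene", "gene"),
        LinkType("gene_taxon", "gene", "taxon"),
    )
}


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    link_type: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.link_type not in LINK_TYPES:
            raise ValidationError(f"unknown link type {self.link_type!r}")
        if self.weight < 0:
            raise ValidationError(
                f"edge {self.source}--{self.target} has negative weight "
                f"{self.weight}"
            )
        lt = LINK_TYPES[self.link_type]
        st, tt = entity_type_of(self.source), entity_type_of(self.target)
        if (st, tt) != (lt.source_type, lt.target_type):
            raise ValidationError(
                f"edge endpoints ({st},{tt}) do not match link type "
                f"{self.link_type!r} ({lt.source_type},{lt.target_type})"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (the seed lists, e.g. EV biogenesis genes)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    @classmethod
    def of(cls, name: str, members: Iterable[str], description: str = "") -> "GeneSet":
        return cls(name, frozenset(members), description)


@dataclass(frozen=True)
class MetapathStep:
    """One traversal step: a link type, optionally reversed, optionally
    restricted to target genes of one taxon (orthologue steps only)."""

    link_type: str
    reverse: bool = False
    taxon: str | None = None

    @property
    def source_entity_type(self) -> str:
        lt = LINK_TYPES[self.link_type]
        return lt.target_type if self.reverse else lt.source_type

    @property
    def target_entity_type(self) -> str:
        lt = LINK_TYPES[self.link_type]
        return lt.source_type if self.reverse else lt.target_type


@dataclass(frozen=True)
class Metapath:
    """Ordered link-type sequence carrying evidence from seed genes to targets."""

    name: str
    steps: tuple[MetapathStep, ...]

    def __post_init__(self) -> None:
        # chain compatibility is diagnosed by validate_metapath (returned,
        # not raised) and enforced when a propagation actually runs
        if not self.steps:
            raise ValidationError(f"metapath {self.name!r} has no steps")

    @property
    def target_entity_type(self) -> str:
        return self.steps[-1].target_entity_type


def _chain_messages(steps: Sequence[MetapathStep]) -> list[str]:
    msgs: list[str] = []
    unknown = [s.link_type for s in steps if s.link_type not in LINK_TYPES]
    if unknown:
        return [f"unknown link type {lt!r}" for lt in unknown]
    if steps and steps[0].source_entity_type != "gene":
        msgs.append(
            f"first step {steps[0].link_type!r} must start at genes, "
            f"starts at {steps[0].source_entity_type!r}"
        )
    for k in range(len(steps) - 1):
        a, b = steps[k], steps[k + 1]
        if a.target_entity_type != b.source_entity_type:
            msgs.append(
                f"step {k + 1} ends at {a.target_entity_type!r} but step "
                f"{k + 2} ({b.link_type!r}) starts at {b.source_entity_type!r}"
            )
    if steps and steps[-1].target_entity_type not in ("disease", "phenotype"):
        msgs.append(
            f"last step ends at {steps[-1].target_entity_type!r}; metapaths "
            "must end at diseases or phenotypes"
        )
    for k, s in enumerate(steps):
        if s.taxon is not None and s.target_entity_type != "gene":
            msgs.append(f"step {k + 1} has a taxon filter but does not end at genes")
    return msgs


class KnowledgeGraph:
    """Typed multipartite graph backed by a :class:`networkx.MultiGraph`.

    Edges are keyed by link type; duplicate (source, target, link_type)
    triples collapse keeping the maximum weight, so re-loading the same file
    is idempotent.  Gene→taxon annotations (``taxon_of_gene``) automatically
    materialize a ``gene_taxon`` edge.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()
        self.taxon_of_gene: dict[str, str] = {}

    # -- construction ------------------------------------------------------

    def add_entity(self, entity_id: str) -> str:
        etype = entity_type_of(entity_id)
        if entity_id not in self._g:
            self._g.add_node(entity_id, entity_type=etype)
        return entity_id

    def add_edge(
        self, source: str, target: str, link_type: str, weight: float = 1.0
    ) -> None:
        lt = LINK_TYPES.get(link_type)
        if lt is not None and lt.source_type != lt.target_type:
            # undirected association: accept either endpoint order
            if (
                entity_type_of(source) == lt.target_type
                and entity_type_of(target) == lt.source_type
            ):
                source, target = target, source
        edge = Edge(source, target, link_type, weight)  # validates types/weight
        if link_type == "gene_orthologue":
            ta = self.taxon_of_gene.get(source)
            tb = self.taxon_of_gene.get(target)
            if ta is None or tb is None:
                raise ValidationError(
                    f"orthologue edge {source}--{target}: both genes need a "
                    "taxon annotation (set_taxon or load_orthologues first)"
                )
            if ta == tb:
                raise ValidationError(
                    f"orthologue edge {source}--{target} joins two genes of "
                    f"the same taxon {ta!r}"
                )
        self.add_entity(source)
        self.add_entity(target)
        u, v = edge.source, edge.target
        if self._g.has_edge(u, v, key=link_type):
            old = self._g[u][v][link_type]["weight"]
            self._g[u][v][link_type]["weight"] = max(old, weight)
        else:
            self._g.add_edge(u, v, key=link_type, weight=weight)

    def set_taxon(self, gene_id: str, taxon_id: str) -> None:
        entity_type_of(gene_id)
        entity_type_of(taxon_id)
        prev = self.taxon_of_gene.get(gene_id)
        if prev is not None and prev != taxon_id:
            raise ValidationError(
                f"gene {gene_id!r} already assigned to taxon {prev!r}, "
                f"cannot reassign to {taxon_id!r}"
            )
        self.taxon_of_gene[gene_id] = taxon_id
        self.add_edge(gene_id, taxon_id, "gene_taxon")

    def add_edges(self, edges: Iterable[Edge]) -> None:
        for e in edges:
            self.add_edge(e.source, e.target, e.link_type, e.weight)

    # -- queries -----------------------------------------------------------

    @property
    def n_entities(self) -> int:
        return self._g.number_of_nodes()

    def entities(self) -> list[Entity]:
        return [
            Entity(n, d["entity_type"]) for n, d in sorted(self._g.nodes(data=True))
        ]

    def entities_of_type(self, entity_type: str) -> list[str]:
        return sorted(
            n for n, d in self._g.nodes(data=True) if d["entity_type"] == entity_type
        )

    def genes(self, taxon: str | None = None) -> list[str]:
        gs = self.entities_of_type("gene")
        if taxon is None:
            return gs
        return [g for g in gs if self.taxon_of_gene.get(g) == taxon]

    def has_link_type(self, link_type: str) -> bool:
        return any(True for _ in self.edges(link_type))

    def edges(self, link_type: str | None = None) -> Iterator[Edge]:
        """Iterate edges in canonical orientation (link-type source first)."""
        for u, v, key, data in self._g.edges(keys=True, data=True):
            if link_type is not None and key != link_type:
                continue
            lt = LINK_TYPES[key]
            if entity_type_of(u) != lt.source_type or (
                lt.source_type == lt.target_type and u > v
            ):
                u, v = v, u
            yield Edge(u, v, key, data["weight"])

    def neighbors(self, node: str, link_type: str) -> set[str]:
        if node not in self._g:
            return set()
        return {
            v for _, v, key in self._g.edges(node, keys=True) if key == link_type
        }

    def edge_weight(self, u: str, v: str, link_type: str) -> float | None:
        if self._g.has_edge(u, v, key=link_type):
            return self._g[u][v][link_type]["weight"]
        return None

    def degree(self, node: str, link_type: str) -> int:
        return len(self.neighbors(node, link_type))

    # -- persistence -------------------------------------------------------

    def save(self, directory: str) -> None:
        """Write the TSV/GMT dialects: entities.tsv, gene_disease.tsv,
        gene_phenotype.tsv, gene_pathway.gmt, orthologues.tsv."""
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "entities.tsv"), "w", encoding="utf-8") as fh:
            fh.write("entity_id\tentity_type\ttaxon\n")
            for ent in self.entities():
                taxon = self.taxon_of_gene.get(ent.id, "")
                fh.write(f"{ent.id}\t{ent.entity_type}\t{taxon}\n")
        for lt, fname in (
            ("gene_disease", "gene_disease.tsv"),
            ("gene_phenotype", "gene_phenotype.tsv"),
        ):
            with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
                fh.write(f"gene_id\t{lt.split('_')[1]}_id\tscore\n")
                for e in sorted(self.edges(lt), key=lambda e: (e.source, e.target)):
                    fh.write(f"{e.source}\t{e.target}\t{e.weight:.17g}\n")
        pathways: dict[str, list[str]] = {}
        for e in self.edges("gene_pathway"):
            pathways.setdefault(e.target, []).append(e.source)
        with open(
            os.path.join(directory, "gene_pathway.gmt"), "w", encoding="utf-8"
        ) as fh:
            for pw in sorted(pathways):
                genes = "\t".join(sorted(pathways[pw]))
                fh.write(f"{pw}\t-\t{genes}\n")
        with open(
            os.path.join(directory, "orthologues.tsv"), "w", encoding="utf-8"
        ) as fh:
            fh.write("gene_a\ttaxon_a\tgene_b\ttaxon_b\n")
            for e in sorted(
                self.edges("gene_orthologue"), key=lambda e: (e.source, e.target)
            ):
                ta = self.taxon_of_gene[e.source]
                tb = self.taxon_of_gene[e.target]
                fh.write(f"{e.source}\t{ta}\t{e.target}\t{tb}\n")

    @classmethod
    def load(cls, directory: str) -> "KnowledgeGraph":
        graph = cls()
        ent_path = os.path.join(directory, "entities.tsv")
        if os.path.exists(ent_path):
            for lineno, fields in _iter_tsv(ent_path, skip_header=True):
                if len(fields) != 3:
                    raise ParseError(
                        f"{ent_path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                eid, _etype, taxon = fields
                graph.add_entity(eid)
                if taxon:
                    graph.set_taxon(eid, taxon)
        for lt, fname in (
            ("gene_disease", "gene_disease.tsv"),
            ("gene_phenotype", "gene_phenotype.tsv"),
        ):
            path = os.path.join(directory, fname)
            if os.path.exists(path):
                graph.add_edges(
                    _load_bipartite_edges(path, lt, score_column="score")
                )
        gmt = os.path.join(directory, "gene_pathway.gmt")
        if os.path.exists(gmt):
            graph.add_edges(load_gmt(gmt))
        orth = os.path.join(directory, "orthologues.tsv")
        if os.path.exists(orth):
            load_orthologues(orth, graph=graph)
        return graph

    @classmethod
    def from_config(cls, config_path: str) -> "KnowledgeGraph":
        """Build a graph from a YAML manifest of source files.

        Recognized keys: ``gene_disease``, ``gene_phenotype`` (TSV paths),
        ``gene_pathway_gmt`` (GMT path), ``orthologues`` (TSV path),
        ``score_column`` (column name enabling weighted gene-disease edges).
        Relative paths resolve against the manifest's directory.
        """
        with open(config_path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(config_path))

        def _resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base, p)

        graph = cls()
        score_col = cfg.get("score_column")
        if "orthologues" in cfg:
            load_orthologues(_resolve(cfg["orthologues"]), graph=graph)
        if "gene_disease" in cfg:
            graph.add_edges(
                load_gene_disease_edges(_resolve(cfg["gene_disease"]), score_col)
            )
        if "gene_phenotype" in cfg:
            graph.add_edges(
                load_gene_phenotype_edges(_resolve(cfg["gene_phenotype"]), score_col)
            )
        if "gene_pathway_gmt" in cfg:
            graph.add_edges(load_gmt(_resolve(cfg["gene_pathway_gmt"])))
        return graph


# -- file readers ----------------------------------------------------------


def _iter_tsv(path: str, skip_header: bool) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        first_data = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if skip_header and first_data:
                first_data = False
                continue
            yield lineno, line.split("\t")


def _load_bipartite_edges(
    path: str, link_type: str, score_column: str | None
) -> list[Edge]:
    target_type = LINK_TYPES[link_type].target_type
    edges: list[Edge] = []
    for lineno, fields in _iter_tsv(path, skip_header=True):
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
            )
        gene = qualify(fields[0], "gene")
        target = qualify(fields[1], target_type)
        weight = 1.0
        if score_column is not None:
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: score column requested but row has "
                    f"only {len(fields)} columns"
                )
            try:
                weight = float(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: score {fields[2]!r} is not numeric"
                ) from exc
            if weight < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative score {weight}"
                )
        edges.append(Edge(gene, target, link_type, weight))
    return _collapse(edges)


def _collapse(edges: Iterable[Edge]) -> list[Edge]:
    best: dict[tuple[str, str, str], Edge] = {}
    for e in edges:
        key = (e.source, e.target, e.link_type)
        prev = best.get(key)
        if prev is None or e.weight > prev.weight:
            best[key] = e
    return list(best.values())


def load_gene_disease_edges(path: str, score_column: str | None = None) -> list[Edge]:
    """Read a DisGeNet-style TSV (gene_id, disease_id[, score]) into edges.

    Weights default to 1.0; pass ``score_column`` to carry the numeric third
    column as the edge weight.  Duplicate rows collapse to the maximum weight.
    """
    return _load_bipartite_edges(path, "gene_disease", score_column)


def load_gene_phenotype_edges(path: str, score_column: str | None = None) -> list[Edge]:
    return _load_bipartite_edges(path, "gene_phenotype", score_column)


def load_gmt(path: str, link_type: str = "gene_pathway") -> list[Edge]:
    """Read a Broad-dialect GMT file into gene→pathway edges.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; the set name
    becomes a pathway entity and each member contributes one edge.
    """
    target_type = LINK_TYPES[link_type].target_type
    edges: list[Edge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene; got {len(fields)} fields"
                )
            pathway = qualify(fields[0], target_type)
            for raw in dict.fromkeys(fields[2:]):
                if raw:
                    edges.append(Edge(qualify(raw, "gene"), pathway, link_type))
    return _collapse(edges)


def load_orthologues(
    path: str, graph: KnowledgeGraph | None = None
) -> list[Edge]:
    """Read a 4-column orthologue TSV (gene_a, taxon_a, gene_b, taxon_b).

    Each row yields one undirected cross-taxon ``gene_orthologue`` edge; taxon
    annotations are registered on the graph (if given).  A row whose two taxa
    coincide, or that conflicts with an existing annotation, raises
    :class:`ValidationError`.
    """
    own = graph if graph is not None else KnowledgeGraph()
    edges: list[Edge] = []
    for lineno, fields in _iter_tsv(path, skip_header=True):
        if len(fields) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 columns, got {len(fields)}"
            )
        gene_a = qualify(fields[0], "gene")
        taxon_a = qualify(fields[1], "taxon")
        gene_b = qualify(fields[2], "gene")
        taxon_b = qualify(fields[3], "taxon")
        if taxon_a == taxon_b:
            raise ValidationError(
                f"{path}:{lineno}: orthologue row joins two genes of the same "
                f"taxon {taxon_a!r}"
            )
        try:
            own.set_taxon(gene_a, taxon_a)
            own.set_taxon(gene_b, taxon_b)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        edge = Edge(gene_a, gene_b, "gene_orthologue")
        own.add_edge(gene_a, gene_b, "gene_orthologue")
        edges.append(edge)
    return _collapse(edges)


def read_gmt_sets(path: str) -> list[GeneSet]:
    """Read a GMT file as plain gene sets, keeping member ids as written."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene; got {len(fields)} fields"
                )
            members = [f for f in fields[2:] if f]
            sets.append(GeneSet.of(fields[0], members, fields[1]))
    return sets


def write_gmt_sets(sets: Sequence[GeneSet], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description or '-'}\t{members}\n")


def read_seed_sets(path: str) -> list[GeneSet]:
    """Read seed gene lists: a GMT file, or a one-id-per-line text file."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    stripped = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if stripped and all("\t" in ln for ln in stripped):
        return read_gmt_sets(path)
    name = os.path.splitext(os.path.basename(path))[0]
    members = [ln.strip() for ln in stripped]
    if not members:
        raise ParseError(f"{path}: no gene ids found")
    return [GeneSet.of(name, members)]


def validate_metapath(graph: KnowledgeGraph, mp: Metapath) -> list[str]:
    """Return diagnostics (empty list = valid on this graph)."""
    msgs = _chain_messages(mp.steps)
    for k, step in enumerate(mp.steps):
        if step.link_type in LINK_TYPES and not graph.has_link_type(step.link_type):
            msgs.append(
                f"step {k + 1}: graph has no {step.link_type!r} edges"
            )
    return msgs
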