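"""Metabolic model parsing, currency-metabolite removal, and gene-centric projection.

A metabolic model is a bipartite graph of metabolite and reaction nodes plus
reaction-to-gene associations.  Projecting it onto genes yields an undirected
simple graph in which two genes are adjacent whenever reactions associated
with them share at least one metabolite.  Because very high-degree "currency"
metabolites (ATP and friends) would short-circuit the projection, a top
fraction of metabolites by reaction degree can be removed beforehand.
"""

from __future__ import annotations

import csv
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "MetabolicModel",
    "GeneNetwork",
    "CurrencyReport",
    "ModelParseError",
    "read_metabolic_model",
    "remove_currency_metabolites",
    "project_gene_network",
    "restrict_to_measured",
    "write_edgelist",
    "write_graphml",
]


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed; carries the offending line."""


@dataclass(frozen=True)
class MetabolicModel:
    """Bipartite metabolite-reaction incidence plus reaction->gene associations."""

    metabolites: frozenset[str]
    reactions: frozenset[str]
    incidence: frozenset[tuple[str, str]]  # (reaction, metabolite)
    gene_map: frozenset[tuple[str, str]]  # (reaction, gene)

    def __post_init__(self) -> None:
        for rxn, met in self.incidence:
            if rxn not in self.reactions:
                raise ValueError(f"incidence references undeclared reaction {rxn!r}")
            if met not in self.metabolites:
                raise ValueError(f"incidence references undeclared metabolite {met!r}")
        for rxn, _gene in self.gene_map:
            if rxn not in self.reactions:
                raise ValueError(f"gene_map references undeclared reaction {rxn!r}")
        if self.metabolites & self.genes:
            clash = sorted(self.metabolites & self.genes)[:3]
            raise ValueError(f"gene and metabolite ID namespaces overlap: {clash}")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _r, g in self.gene_map)

    def metabolite_degrees(self) -> dict[str, int]:
        """Number of distinct incident reactions per metabolite (0 if isolated)."""
        deg = {m: 0 for m in self.metabolites}
        for _rxn, met in self.incidence:
            deg[met] += 1
        return deg


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected simple graph over gene identifiers."""

    nodes: frozenset[str]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"edge {set(e)!r} is not an unordered pair of distinct genes")
            if not e <= self.nodes:
                raise ValueError(f"edge {set(e)!r} references genes outside the node set")

    @classmethod
    def from_pairs(cls, nodes: Iterable[str], pairs: Iterable[tuple[str, str]]) -> "GeneNetwork":
        return cls(frozenset(nodes), frozenset(frozenset(p) for p in pairs))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_tuples(self) -> list[tuple[str, str]]:
        """Edges as sorted (a, b) tuples, sorted overall; deterministic."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(self.edge_tuples())
        return g


@dataclass(frozen=True)
class CurrencyReport:
    """What was removed as currency metabolites, ordered by degree descending."""

    removed_metabolites: tuple[tuple[str, int], ...]
    fraction: float

    def __post_init__(self) -> None:
        degs = [d for _m, d in self.removed_metabolites]
        if degs != sorted(degs, reverse=True):
            raise ValueError("removed metabolites must be sorted by degree descending")


def read_metabolic_model(path: str | Path, format: str = "triple-tsv") -> MetabolicModel:
    """Read a metabolic model from disk.

    ``triple-tsv`` is the canonical format: a header line then rows
    ``kind<TAB>reaction<TAB>partner`` where kind ``RM`` declares a
    reaction-metabolite incidence and ``RG`` a reaction-gene association.
    Duplicate rows collapse to one pair.  ``sbml`` reads a minimal SBML
    Level 3 subset (species, reactions, flattened gene-product associations).
    """
    path = Path(path)
    if format == "triple-tsv":
        return _read_triple_tsv(path)
    if format == "sbml":
        return _read_sbml_subset(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_triple_tsv(path: Path) -> MetabolicModel:
    metabolites: set[str] = set()
    reactions: set[str] = set()
    incidence: set[tuple[str, str]] = set()
    gene_map: set[tuple[str, str]] = set()

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)

    for lineno, row in enumerate(rows, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if lineno == 1 and row[0].strip().lower() == "kind":
            continue  # header
        if len(row) != 3:
            raise ModelParseError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(row)}")
        kind, rxn, partner = (f.strip() for f in row)
        if not rxn or not partner:
            raise ModelParseError(f"{path}:{lineno}: empty reaction or partner field")
        if kind == "RM":
            reactions.add(rxn)
            metabolites.add(partner)
            incidence.add((rxn, partner))
        elif kind == "RG":
            reactions.add(rxn)
            gene_map.add((rxn, partner))
        else:
            raise ModelParseError(f"{path}:{lineno}: unknown kind {kind!r} (expected RM or RG)")

    model = MetabolicModel(frozenset(metabolites), frozenset(reactions),
                           frozenset(incidence), frozenset(gene_map))
    orphan = {r for r in reactions if not any(rx == r for rx, _m in incidence)}
    if orphan:
        warnings.warn(f"{len(orphan)} reaction(s) have no incident metabolite "
                      f"(e.g. {sorted(orphan)[:3]})", stacklevel=2)
    return model


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_sbml_subset(path: Path) -> MetabolicModel:
    """Flatten an SBML L3/FBC file: species, reactions, gene-product refs.

    Boolean GPR structure is ignored; every referenced gene product is
    associated with the reaction.
    """
    tree = ET.parse(path)
    root = tree.getroot()

    gp_label: dict[str, str] = {}
    for el in root.iter():
        if _local(el.tag) == "geneProduct":
            attrs = {_local(k): v for k, v in el.attrib.items()}
            gid = attrs.get("id", "")
            if gid:
                gp_label[gid] = attrs.get("label", gid)

    metabolites: set[str] = set()
    incidence: set[tuple[str, str]] = set()
    gene_map: set[tuple[str, str]] = set()
    reactions: set[str] = set()

    for el in root.iter():
        if _local(el.tag) == "species" and el.get("id"):
            metabolites.add(el.get("id"))

    for rxn_el in root.iter():
        if _local(rxn_el.tag) != "reaction":
            continue
        rid = rxn_el.get("id")
        if not rid:
            continue
        reactions.add(rid)
        for el in rxn_el.iter():
            tag = _local(el.tag)
            if tag == "speciesReference" and el.get("species"):
                incidence.add((rid, el.get("species")))
            elif tag == "geneProductRef":
                ref = None
                for k, v in el.attrib.items():
                    if _local(k) == "geneProduct":
                        ref = v
                if ref:
                    gene_map.add((rid, gp_label.get(ref, ref)))

    return MetabolicModel(frozenset(metabolites), frozenset(reactions),
                          frozenset(incidence), frozenset(gene_map))


def remove_currency_metabolites(model: MetabolicModel,
                                fraction: float) -> tuple[MetabolicModel, CurrencyReport]:
    """Delete the top ``ceil(fraction * n_metabolites)`` metabolites by reaction degree.

    Degree ties at the cutoff are broken by lexicographic metabolite ID so that
    removal sets are nested across increasing fractions.  Reactions and genes
    are retained even if left metabolite-free.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"fraction must lie in [0, 1); got {fraction!r}")
    n_remove = math.ceil(fraction * len(model.metabolites))
    if n_remove == 0:
        return model, CurrencyReport((), fraction)

    deg = model.metabolite_degrees()
    ranked = sorted(deg, key=lambda m: (-deg[m], m))
    removed = ranked[:n_remove]
    removed_set = set(removed)

    new_model = MetabolicModel(
        metabolites=frozenset(model.metabolites - removed_set),
        reactions=model.reactions,
        incidence=frozenset((r, m) for r, m in model.incidence if m not in removed_set),
        gene_map=model.gene_map,
    )
    report = CurrencyReport(tuple((m, deg[m]) for m in removed), fraction)
    return new_model, report


def project_gene_network(model: MetabolicModel) -> GeneNetwork:
    """Project the bipartite model onto its genes.

    Two distinct genes are adjacent iff some reaction of one and some reaction
    of the other share a metabolite.  A reaction shares every one of its
    metabolites with itself, so genes annotated to the same reaction are
    adjacent whenever that reaction has at least one metabolite.
    """
    rxn_genes: dict[str, set[str]] = {}
    for rxn, gene in model.gene_map:
        rxn_genes.setdefault(rxn, set()).add(gene)

    met_rxns: dict[str, set[str]] = {}
    for rxn, met in model.incidence:
        met_rxns.setdefault(met, set()).add(rxn)

    edges: set[frozenset[str]] = set()
    for met, rxns in met_rxns.items():
        pool: set[str] = set()
        for rxn in rxns:
            pool |= rxn_genes.get(rxn, set())
        pool_l = sorted(pool)
        for i, g in enumerate(pool_l):
            for h in pool_l[i + 1:]:
                edges.add(frozenset((g, h)))

    return GeneNetwork(model.genes, frozenset(edges))


def restrict_to_measured(network: GeneNetwork, measured_genes: Iterable[str]) -> GeneNetwork:
    """Induced subgraph on ``nodes & measured_genes`` (exact for a pairwise projection)."""
    keep = network.nodes & frozenset(measured_genes)
    return GeneNetwork(keep, frozenset(e for e in network.edges if e <= keep))


def write_edgelist(network: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in network.edge_tuples():
            fh.write(f"{a}\t{b}\n")


def write_graphml(network: GeneNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), path)
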