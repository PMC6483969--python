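import numpy as np
import pytest

from mcnet.network_builder import GeneNetwork, MetabolicModel


@pytest.fixture
def tiny_model() -> MetabolicModel:
    """Two reactions sharing one metabolite, one gene each."""
    return MetabolicModel(
        metabolites=frozenset({"m1"}),
        reactions=frozenset({"R1", "R2"}),
        incidence=frozenset({("R1", "m1"), ("R2", "m1")}),
        gene_map=frozenset({("R1", "gA"), ("R2", "gB")}),
    )


@pytest.fixture
def triangle_plus_isolate() -> GeneNetwork:
    """Three mutually connected genes plus one isolated gene."""
    return GeneNetwork.from_pairs(
        ["gA", "gB", "gC", "gD"],
        [("gA", "gB"), ("gB", "gC"), ("gA", "gC")],
    )


def random_model(rng: np.random.Generator, n_reactions: int = 8,
                 n_metabolites: int = 6, n_genes: int = 6) -> MetabolicModel:
    """Small random bipartite model for oracle-equivalence tests."""
    mets = [f"m{i}" for i in range(n_metabolites)]
    rxns = [f"R{i}" for i in range(n_reactions)]
    genes = [f"g{i}" for i in range(n_genes)]
    incidence = {(r, m) for r in rxns for m in mets if rng.random() < 0.3}
    gene_map = {(rxns[int(rng.integers(n_reactions))], g) for g in genes}
    for g in genes:
        if rng.random() < 0.4:
            gene_map.add((rxns[int(rng.integers(n_reactions))], g))
    return MetabolicModel(frozenset(mets), frozenset(rxns),
                          frozenset(incidence), frozenset(gene_map))


def brute_force_projection(model: MetabolicModel) -> set[frozenset[str]]:
    """O(|R|^2) enumeration of reaction pairs sharing a metabolite."""
    rxn_mets = {r: set() for r in model.reactions}
    for r, m in model.incidence:
        rxn_mets[r].add(m)
    rxn_genes = {r: set() for r in model.reactions}
    for r, g in model.gene_map:
        rxn_genes[r].add(g)
    edges = set()
    for r1 in model.reactions:
        for r2 in model.reactions:
            if rxn_mets[r1] & rxn_mets[r2]:
                for g in rxn_genes[r1]:
                    for h in rxn_genes[r2]:
                        if g != h:
                            edges.add(frozenset((g, h)))
    return edges
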