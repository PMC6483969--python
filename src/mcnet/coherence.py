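"""Per-sample metabolic network coherence (MC) z-scores.

The connectivity of the subnetwork induced by a gene set is the fraction of
its nodes having at least one neighbor inside the set.  MC standardizes the
observed connectivity of a sample's salient genes against a simulated null of
equally sized gene sets drawn uniformly without replacement from the network's
node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import derive_seed
from .network_builder import (GeneNetwork, MetabolicModel, project_gene_network,
                              remove_currency_metabolites, restrict_to_measured)
from .salience import ExpressionMatrix, SalienceMatrix, dichotomize

__all__ = [
    "NullDistribution",
    "MCValue",
    "MCProfile",
    "UndefinedConnectivityError",
    "IndexedNetwork",
    "subnetwork_connectivity",
    "null_connectivity",
    "mc_score",
    "mc_profile",
    "sensitivity_sweep",
    "write_mc_tsv",
    "read_mc_tsv",
]

DEFAULT_N_DRAWS = 2000
REASON_SET_TOO_SMALL = "set_too_small"
REASON_DEGENERATE_NULL = "degenerate_null"


class UndefinedConnectivityError(ValueError):
    """Gene set has empty intersection with the network's nodes."""


class IndexedNetwork:
    """Gene network indexed for fast induced-subgraph degree queries.

    Holds a dense boolean adjacency matrix over the (sorted) node list; fine
    for metabolic-scale networks (a few thousand nodes).
    """

    def __init__(self, network: GeneNetwork):
        self.nodes = sorted(network.nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        n = len(self.nodes)
        self.adj = np.zeros((n, n), dtype=bool)
        for a, b in network.edge_tuples():
            i, j = self.index[a], self.index[b]
            self.adj[i, j] = self.adj[j, i] = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_indices(self, gene_set: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index[g] for g in gene_set if g in self.index),
                           dtype=np.intp)

    def connectivity_of(self, idx: np.ndarray) -> float:
        if idx.size == 0:
            raise UndefinedConnectivityError("gene set does not intersect network nodes")
        if idx.size == 1:
            return 0.0
        sub = self.adj[np.ix_(idx, idx)]
        return float(sub.any(axis=1).mean())


@dataclass(frozen=True)
class NullDistribution:
    """Connectivity null for random k-sets of network nodes."""

    set_size: int
    draws: tuple[float, ...]
    n_draws: int
    seed: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if len(self.draws) != self.n_draws:
            raise ValueError("len(draws) must equal n_draws")


@dataclass(frozen=True)
class MCValue:
    mc: float | None
    k: int
    reason: str | None = None


@dataclass
class MCProfile:
    """Per-sample MC z-scores with provenance; ``mc`` is NaN where missing."""

    table: pd.DataFrame  # columns: sample, mc, k, reason
    config: dict

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def mc_series(self) -> pd.Series:
        return pd.Series(self.table["mc"].to_numpy(dtype=float),
                         index=self.table["sample"], name="mc")


def subnetwork_connectivity(network: GeneNetwork | IndexedNetwork,
                            gene_set: Iterable[str]) -> float:
    """Fraction of induced-subgraph nodes with degree >= 1 inside the set."""
    ix = network if isinstance(network, IndexedNetwork) else IndexedNetwork(network)
    return ix.connectivity_of(ix.to_indices(set(gene_set)))


def null_connectivity(network: GeneNetwork | IndexedNetwork, k: int,
                      n_draws: int = DEFAULT_N_DRAWS, seed: int = 0) -> NullDistribution:
    """Simulate connectivity of ``n_draws`` uniform k-subsets of network nodes."""
    ix = network if isinstance(network, IndexedNetwork) else IndexedNetwork(network)
    if not (2 <= k <= ix.n_nodes):
        raise ValueError(f"k must lie in [2, {ix.n_nodes}]; got {k}")
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    n = ix.n_nodes
    for i in range(n_draws):
        idx = rng.choice(n, size=k, replace=False)
        draws[i] = ix.connectivity_of(idx)
    return NullDistribution(set_size=k, draws=tuple(draws.tolist()), n_draws=n_draws,
                            seed=seed, mean=float(draws.mean()),
                            sd=float(draws.std(ddof=1)))


def mc_score(network: GeneNetwork | IndexedNetwork, salient_genes: Iterable[str],
             n_draws: int = DEFAULT_N_DRAWS, seed: int = 0,
             _null_cache: dict[int, NullDistribution] | None = None) -> MCValue:
    """z-score of the observed salient-set connectivity against its size-matched null.

    The set size k counts salient genes *after* intersection with the network.
    Missing (with a reason code) when k < 2 or the null is degenerate.
    """
    ix = network if isinstance(network, IndexedNetwork) else IndexedNetwork(network)
    if ix.n_nodes == 0:
        raise ValueError("network is empty")
    idx = ix.to_indices(set(salient_genes))
    k = int(idx.size)
    if k < 2:
        return MCValue(mc=None, k=k, reason=REASON_SET_TOO_SMALL)

    if _null_cache is not None and k in _null_cache:
        null = _null_cache[k]
    else:
        null = null_connectivity(ix, k, n_draws=n_draws, seed=derive_seed(seed, k))
        if _null_cache is not None:
            _null_cache[k] = null
    if null.sd == 0:
        return MCValue(mc=None, k=k, reason=REASON_DEGENERATE_NULL)
    obs = ix.connectivity_of(idx)
    return MCValue(mc=(obs - null.mean) / null.sd, k=k)


def mc_profile(network: GeneNetwork | IndexedNetwork, sal: SalienceMatrix,
               n_draws: int = DEFAULT_N_DRAWS, seed: int = 0,
               currency_fraction: float | None = None) -> MCProfile:
    """MC z-score for every sample of a salience matrix.

    Null distributions are cached per set size k within the run, each with a
    deterministic per-k seed derived from the master seed, so two samples with
    equal k (and a fortiori identical salient sets) share one null.
    """
    ix = network if isinstance(network, IndexedNetwork) else IndexedNetwork(network)
    cache: dict[int, NullDistribution] = {}
    states = sal.states.to_numpy(dtype=bool)
    gene_list = np.asarray(sal.genes, dtype=object)
    rows = []
    for j, sample in enumerate(sal.samples):
        genes_j = gene_list[states[:, j]]
        val = mc_score(ix, genes_j, n_draws=n_draws, seed=seed, _null_cache=cache)
        rows.append((sample, np.nan if val.mc is None else val.mc, val.k, val.reason))
    table = pd.DataFrame(rows, columns=["sample", "mc", "k", "reason"])
    config = {"q": sal.q, "currency_fraction": currency_fraction,
              "n_draws": n_draws, "seed": seed}
    return MCProfile(table=table, config=config)


def sensitivity_sweep(model: MetabolicModel, expr: ExpressionMatrix,
                      currency_fractions: Iterable[float], quantiles: Iterable[float],
                      n_draws: int = DEFAULT_N_DRAWS, seed: int = 0) -> pd.DataFrame:
    """Recompute MC over the cross-product of currency fractions and salience quantiles.

    Returns a long-format table (fraction, q, sample, mc, k).
    """
    fractions = list(currency_fractions)
    qs = list(quantiles)
    if not fractions or not qs:
        raise ValueError("currency_fractions and quantiles must be nonempty")
    parts = []
    for frac in fractions:
        pruned, _report = remove_currency_metabolites(model, frac)
        network = restrict_to_measured(project_gene_network(pruned), expr.genes)
        ix = IndexedNetwork(network)
        for q in qs:
            sal = dichotomize(expr, q)
            prof = mc_profile(ix, sal, n_draws=n_draws, seed=seed, currency_fraction=frac)
            part = prof.table[["sample", "mc", "k"]].copy()
            part.insert(0, "q", q)
            part.insert(0, "fraction", frac)
            parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_mc_tsv(profile: MCProfile, path: str | Path) -> None:
    profile.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_mc_tsv(path: str | Path) -> pd.Series:
    """Read a per-sample MC table back as a Series indexed by sample ID."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return pd.Series(df["mc"].to_numpy(dtype=float), index=df["sample"], name="mc")
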