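"""Coupled synthetic metabolic-model / genotype / expression datasets.

Generates a hub-heavy bipartite model (planted currency metabolites),
Hardy-Weinberg dosage genotypes with one causal QTL, and expression data with
individual-varying, network-coherent salient co-regulation.  Salient sets are
planted first and continuous expression values are synthesized around them,
so tail-quantile dichotomization recovers the planted salience matrix
exactly and downstream recovery tests have a ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_seed
from .genetics import META_COLUMNS, DosagePanel, write_vcf
from .network_builder import GeneNetwork, MetabolicModel
from .salience import ExpressionMatrix, write_expression_tsv

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_model",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_covariates",
    "make_fixture",
    "planted_tail_counts",
    "write_model_tsv",
]

HUB_INCLUSION_PROB = 0.8  # per-reaction probability of including each hub metabolite


@dataclass(frozen=True)
class SimulationConfig:
    n_metabolites: int = 80
    n_reactions: int = 120
    n_genes: int = 150
    currency_hub_count: int = 4
    mean_metabolites_per_reaction: float = 3.0
    n_samples: int = 300
    q_salience: float = 0.02
    coherence_base: float = 0.3       # c0: baseline probability of a coherent profile
    qtl_effect: float = 0.15          # added to c0 per causal minor allele
    coherence_noise_sd: float = 0.05
    qtl_maf: float = 0.3
    n_null_snps: int = 49
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_metabolites", "n_reactions", "n_genes", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.currency_hub_count < 0:
            raise ValueError("currency_hub_count must be >= 0")
        if self.currency_hub_count > self.n_metabolites:
            raise ValueError("more currency hubs than metabolites")
        if not (0 < self.q_salience < 0.5):
            raise ValueError("q_salience must lie in (0, 0.5)")
        if not (0 <= self.coherence_base + 2 * self.qtl_effect <= 1):
            raise ValueError("coherence_base + 2*qtl_effect must lie in [0, 1]")
        if not (0 < self.qtl_maf <= 0.5):
            raise ValueError("qtl_maf must lie in (0, 0.5]")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be >= 0")

    @property
    def hub_fraction(self) -> float:
        """Currency fraction that removes exactly the planted hubs."""
        return self.currency_hub_count / self.n_metabolites


@dataclass
class SimulatedTruth:
    """Ground truth serialized alongside a simulated dataset."""

    coherence_propensity: np.ndarray       # c_i per sample, in [0, 1]
    coherent: np.ndarray                   # realized coherent/incoherent flag
    causal_snp: str
    gene_modules: dict[str, int]           # connected-component assignment
    salience: pd.DataFrame                 # planted genes x samples binary states
    s_low: int
    s_high: int

    def to_json_dict(self) -> dict:
        return {
            "coherence_propensity": [float(c) for c in self.coherence_propensity],
            "coherent": [bool(b) for b in self.coherent],
            "causal_snp": self.causal_snp,
            "gene_modules": self.gene_modules,
            "s_low": self.s_low,
            "s_high": self.s_high,
        }


def planted_tail_counts(n_samples: int, q: float) -> tuple[int, int]:
    """Exact number of lower/upper-tail salient entries per gene implied by the
    dichotomization convention for ``n_samples`` distinct values."""
    x = np.arange(n_samples, dtype=float)
    lo = np.quantile(x, q)
    hi = np.quantile(x, 1.0 - q)
    return int((x <= lo).sum()), int((x >= hi).sum())


def simulate_model(cfg: SimulationConfig, seed: int | None = None) -> MetabolicModel:
    """Hub-heavy bipartite model: the first ``currency_hub_count`` metabolites
    join most reactions (degree >> median), the rest attach sparsely."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mets = [f"m{i:04d}" for i in range(cfg.n_metabolites)]
    rxns = [f"R{i:04d}" for i in range(cfg.n_reactions)]
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    hubs = mets[:cfg.currency_hub_count]
    others = mets[cfg.currency_hub_count:]

    incidence: set[tuple[str, str]] = set()
    for rxn in rxns:
        for hub in hubs:
            if rng.random() < HUB_INCLUSION_PROB:
                incidence.add((rxn, hub))
        if others:
            n_extra = max(1, rng.poisson(cfg.mean_metabolites_per_reaction))
            n_extra = min(n_extra, len(others))
            for met in rng.choice(len(others), size=n_extra, replace=False):
                incidence.add((rxn, others[met]))

    gene_map: set[tuple[str, str]] = set()
    for i, gene in enumerate(genes):
        gene_map.add((rxns[i % cfg.n_reactions], gene))
        if rng.random() < 0.3:  # a second association for some genes
            gene_map.add((rxns[rng.integers(cfg.n_reactions)], gene))

    return MetabolicModel(frozenset(mets), frozenset(rxns),
                          frozenset(incidence), frozenset(gene_map))


def simulate_genotypes(cfg: SimulationConfig, seed: int | None = None
                       ) -> tuple[DosagePanel, str]:
    """HWE dosage genotypes: ``n_null_snps`` null SNPs plus one causal SNP at
    ``qtl_maf``, evenly spaced on one synthetic chromosome."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_snps = cfg.n_null_snps + 1
    causal_idx = cfg.n_null_snps // 2
    mafs = rng.uniform(0.1, 0.45, size=n_snps)
    mafs[causal_idx] = cfg.qtl_maf

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    ids = [f"snp{i:04d}" for i in range(n_snps)]
    dosage = rng.binomial(2, mafs[:, None], size=(n_snps, cfg.n_samples)).astype(float)

    snps = pd.DataFrame({
        "chrom": "1",
        "pos": [10_000 * (i + 1) for i in range(n_snps)],
        "minor": "A",
        "major": "G",
    }, index=pd.Index(ids, name="snp"))
    panel = DosagePanel(snps, pd.DataFrame(dosage, index=snps.index, columns=samples))
    return panel, ids[causal_idx]


def _adjacency_lists(network: GeneNetwork, genes: list[str]) -> list[list[int]]:
    index = {g: i for i, g in enumerate(genes)}
    adj: list[list[int]] = [[] for _ in genes]
    for a, b in network.edge_tuples():
        adj[index[a]].append(index[b])
        adj[index[b]].append(index[a])
    return adj


def _gene_modules(adj: list[list[int]], genes: list[str]) -> dict[str, int]:
    module = {}
    seen = [False] * len(genes)
    comp = 0
    for start in range(len(genes)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        while stack:
            u = stack.pop()
            module[genes[u]] = comp
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comp += 1
    return module


def _grow_neighborhood(adj: list[list[int]], rng: np.random.Generator,
                       capacity: np.ndarray, need: int, n_genes: int) -> list[int]:
    """Breadth-first growth from a random seed node, restricted to genes with
    remaining planting capacity; restarts on exhaustion, tops up at random."""
    chosen: list[int] = []
    visited = np.zeros(n_genes, dtype=bool)
    while len(chosen) < need and not visited.all():
        unvisited = np.flatnonzero(~visited)
        start = int(rng.choice(unvisited))
        queue = [start]
        visited[start] = True
        while queue and len(chosen) < need:
            u = queue.pop(0)
            if capacity[u] > 0 and u not in chosen:
                chosen.append(u)
            neigh = [v for v in adj[u] if not visited[v]]
            rng.shuffle(neigh)
            for v in neigh:
                visited[v] = True
                queue.append(v)
    return chosen[:need]


def simulate_expression(network: GeneNetwork, panel: DosagePanel, causal_snp: str,
                        cfg: SimulationConfig, seed: int | None = None
                        ) -> tuple[ExpressionMatrix, SimulatedTruth]:
    """Plant salience first, then synthesize continuous expression around it.

    Per sample i, the coherence propensity is
    ``c_i = clamp(c0 + qtl_effect * dosage_i + noise, 0, 1)``.  With
    probability c_i the sample's salient genes are grown as a connected
    neighborhood (breadth-first from a random seed node); otherwise they are
    drawn uniformly.  Per-gene salient counts are held at the exact tail
    counts implied by the dichotomization convention, so
    ``dichotomize(expr, q_salience)`` returns the planted matrix exactly.
    """
    if not network.nodes:
        raise ValueError("network must be nonempty")
    if causal_snp not in panel.snps.index:
        raise ValueError(f"causal SNP {causal_snp!r} not in panel")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    genes = sorted(network.nodes)
    samples = panel.samples
    G, n = len(genes), len(samples)
    s_low, s_high = planted_tail_counts(n, cfg.q_salience)
    m = s_low + s_high
    if m < 2 or m >= n:
        raise ValueError(f"q={cfg.q_salience} with n={n} samples leaves no usable tails")

    adj = _adjacency_lists(network, genes)
    dosage = panel.dosage.loc[causal_snp, samples].to_numpy(dtype=float)
    dosage = np.nan_to_num(dosage, nan=float(np.nanmean(dosage)))
    c = np.clip(cfg.coherence_base + cfg.qtl_effect * dosage
                + rng.normal(0.0, cfg.coherence_noise_sd, size=n), 0.0, 1.0)
    coherent = rng.random(n) < c

    # per-sample salient budgets summing exactly to G*m
    total = G * m
    k = np.full(n, total // n, dtype=int)
    extra = rng.choice(n, size=total % n, replace=False)
    k[extra] += 1
    budget_cap = max(G - 1, 1)
    if (k > budget_cap).any():
        warnings.warn("per-sample salient budget exceeds network size; capped",
                      stacklevel=2)
    np.minimum(k, budget_cap, out=k)

    capacity = np.full(G, m, dtype=int)
    S = np.zeros((G, n), dtype=np.int8)
    for i in rng.permutation(n):
        need = int(k[i])
        if need == 0:
            continue
        if coherent[i]:
            chosen = _grow_neighborhood(adj, rng, capacity, need, G)
        else:
            avail = np.flatnonzero(capacity > 0)
            take = min(need, avail.size)
            chosen = list(rng.choice(avail, size=take, replace=False)) if take else []
        for g in chosen:
            S[g, i] = 1
            capacity[g] -= 1

    # top up genes whose quota was not met, on random non-salient samples
    for g in np.flatnonzero(capacity > 0):
        free = np.flatnonzero(S[g] == 0)
        fill = rng.choice(free, size=int(capacity[g]), replace=False)
        S[g, fill] = 1
        capacity[g] = 0

    # synthesize values: lows < background < highs, all distinct a.s.
    values = rng.uniform(-3.0, 3.0, size=(G, n))
    for g in range(G):
        sal = np.flatnonzero(S[g] == 1)
        lows = rng.choice(sal, size=s_low, replace=False)
        highs = np.setdiff1d(sal, lows)
        values[g, lows] = rng.uniform(-9.0, -8.0, size=s_low)
        values[g, highs] = rng.uniform(8.0, 9.0, size=highs.size)

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            dataset="simulated")
    truth = SimulatedTruth(
        coherence_propensity=c,
        coherent=coherent,
        causal_snp=causal_snp,
        gene_modules=_gene_modules(adj, genes),
        salience=pd.DataFrame(S, index=genes, columns=samples),
        s_low=s_low,
        s_high=s_high,
    )
    return expr, truth


def simulate_covariates(cfg: SimulationConfig, samples: list[str],
                        seed: int | None = None) -> pd.DataFrame:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return pd.DataFrame({
        "sex": rng.choice(["F", "M"], size=len(samples)),
        "population": rng.choice(["POP1", "POP2"], size=len(samples)),
    }, index=pd.Index(samples, name="sample"))


def write_model_tsv(model: MetabolicModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\treaction\tpartner\n")
        for rxn, met in sorted(model.incidence):
            fh.write(f"RM\t{rxn}\t{met}\n")
        for rxn, gene in sorted(model.gene_map):
            fh.write(f"RG\t{rxn}\t{gene}\n")


def make_fixture(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete on-disk dataset bundle readable by the pipeline.

    Files: model.tsv, expression.tsv, genotypes.vcf, covariates.tsv,
    salience_truth.tsv, truth.json.  Deterministic per (cfg, cfg.seed).
    """
    from .network_builder import project_gene_network, remove_currency_metabolites

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = simulate_model(cfg, seed=derive_seed(cfg.seed, 1))
    panel, causal = simulate_genotypes(cfg, seed=derive_seed(cfg.seed, 2))
    pruned, _ = remove_currency_metabolites(model, cfg.hub_fraction)
    network = project_gene_network(pruned)
    expr, truth = simulate_expression(network, panel, causal, cfg,
                                      seed=derive_seed(cfg.seed, 3))
    covars = simulate_covariates(cfg, panel.samples, seed=derive_seed(cfg.seed, 4))

    paths = {
        "model": outdir / "model.tsv",
        "expression": outdir / "expression.tsv",
        "vcf": outdir / "genotypes.vcf",
        "covariates": outdir / "covariates.tsv",
        "salience_truth": outdir / "salience_truth.tsv",
        "truth": outdir / "truth.json",
    }
    write_model_tsv(model, paths["model"])
    write_expression_tsv(expr, paths["expression"])
    write_vcf(panel, paths["vcf"])
    covars.to_csv(paths["covariates"], sep="\t")
    truth.salience.to_csv(paths["salience_truth"], sep="\t", index_label="gene")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        payload = truth.to_json_dict()
        payload["config"] = asdict(cfg)
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths
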