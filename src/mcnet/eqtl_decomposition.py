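"""Trans-eQTL rank tests, binary-distance Ward clustering, and sub-cluster decomposition.

Per (gene, SNP) pair, expression is compared across hard-called genotype
classes with a Kruskal-Wallis test.  Genes are then clustered by the
asymmetric binary dissimilarity of their salience profiles with Ward linkage
(Lance-Williams recurrence on the *raw* dissimilarities, matching R's
``hclust(method="ward.D")``), and the dendrogram is cut into 2, 3, ...
sub-clusters until the gene-wise minimum eQTL p-values show nominally
significant heterogeneity between sub-clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform

from ._util import kruskal_pvalue
from .genetics import DosagePanel
from .salience import ExpressionMatrix, SalienceMatrix

__all__ = [
    "EqtlMatrix",
    "EqtlThresholds",
    "Dendrogram",
    "ClusterDecomposition",
    "trans_eqtl",
    "eqtl_significance",
    "min_p_per_gene",
    "binary_distance",
    "ward_cluster",
    "decompose_subclusters",
    "select_target_subcluster",
    "hypergeometric_enrichment",
]


@dataclass
class EqtlMatrix:
    """genes x snps Kruskal-Wallis p-values and per-pair sample counts."""

    p: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if self.p.shape != self.n.shape:
            raise ValueError("p and n matrices must share dimensions")


@dataclass(frozen=True)
class EqtlThresholds:
    per_snp_corrected: float    # 0.05 / m_eff
    study_wide: float           # 0.05 / (m_eff * n_genes)


@dataclass
class Dendrogram:
    """Agglomerative hierarchy over genes: scipy linkage matrix + leaf labels.

    ``linkage_matrix`` heights are on the raw-dissimilarity (ward.D) scale.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        """Partition into exactly k groups; labels 1..k, deterministic."""
        if not (1 <= k <= len(self.labels)):
            raise ValueError(f"k must lie in [1, {len(self.labels)}]")
        flat = cut_tree(self._scipy_z(), n_clusters=k).ravel() + 1
        return pd.Series(flat, index=self.labels, name="cluster")

    def _scipy_z(self) -> np.ndarray:
        z = self.linkage_matrix.copy()
        z[:, 2] = np.sqrt(z[:, 2])  # back to the monotone scale scipy expects
        return z

    def to_newick(self) -> str:
        tree = to_tree(self._scipy_z())

        def rec(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return rec(tree, tree.dist) + ";"


@dataclass
class ClusterDecomposition:
    """Outcome of the significance-driven sub-cluster split.

    ``n_subclusters`` is None when no split up to k_max reached significance.
    """

    dendrogram: Dendrogram
    n_subclusters: int | None
    labels: pd.Series | None
    medians: dict[int, float] | None
    sizes: dict[int, int] | None
    kw_p_by_k: dict[int, float]
    alpha: float


def trans_eqtl(expr: ExpressionMatrix, panel: DosagePanel) -> EqtlMatrix:
    """Kruskal-Wallis test of expression across hard-called genotype classes.

    Dosages are rounded to 0/1/2; empty classes are dropped; pairs with fewer
    than two classes (e.g. monomorphic SNPs) get a missing p.
    """
    shared = [s for s in expr.samples if s in set(panel.samples)]
    if not shared:
        raise ValueError("no shared samples between expression and panel")
    E = expr.values[shared].to_numpy(dtype=float)
    D = panel.dosage[shared].to_numpy(dtype=float)

    genes, snps = expr.genes, panel.snp_ids
    P = np.full((len(genes), len(snps)), np.nan)
    N = np.zeros((len(genes), len(snps)), dtype=int)

    for j in range(len(snps)):
        d = D[j]
        obs = np.isfinite(d)
        calls = np.clip(np.round(d[obs]), 0, 2).astype(int)
        masks = [calls == g for g in (0, 1, 2)]
        masks = [m for m in masks if m.sum() >= 1]
        if len(masks) < 2:
            continue  # monomorphic after hard-calling: whole column missing
        n_pair = int(obs.sum())
        for i in range(len(genes)):
            e = E[i, obs]
            groups = [e[m] for m in masks]
            if any(~np.isfinite(g).all() for g in groups):
                groups = [g[np.isfinite(g)] for g in groups]
                groups = [g for g in groups if g.size >= 1]
                if len(groups) < 2:
                    continue
            P[i, j] = kruskal_pvalue(groups)
            N[i, j] = n_pair
    return EqtlMatrix(pd.DataFrame(P, index=genes, columns=snps),
                      pd.DataFrame(N, index=genes, columns=snps))


def eqtl_significance(eqtl: EqtlMatrix, m_eff: float, n_genes: int
                      ) -> tuple[EqtlThresholds, pd.DataFrame, pd.DataFrame]:
    """Bonferroni thresholds and hit matrices at the per-SNP-corrected and
    study-wide levels."""
    if m_eff < 1 or n_genes < 1:
        raise ValueError("m_eff and n_genes must be >= 1")
    thr = EqtlThresholds(per_snp_corrected=0.05 / m_eff,
                         study_wide=0.05 / (m_eff * n_genes))
    hits_regional = eqtl.p < thr.per_snp_corrected
    hits_study = eqtl.p < thr.study_wide
    return thr, hits_regional, hits_study


def min_p_per_gene(eqtl: EqtlMatrix) -> pd.Series:
    """Row-wise minimum p over non-missing entries; all-missing genes dropped."""
    mins = eqtl.p.min(axis=1, skipna=True)
    dropped = mins.index[mins.isna()]
    if len(dropped):
        warnings.warn(f"{len(dropped)} gene(s) with no computable eQTL p dropped",
                      stacklevel=2)
    return mins.dropna()


def binary_distance(sal: SalienceMatrix) -> pd.DataFrame:
    """Asymmetric binary dissimilarity between gene salience profiles.

    d(g, h) = (# samples where exactly one is salient) / (# samples where at
    least one is salient); joint absences are ignored.  Pairs of never-salient
    genes get d = 0 (they are indistinguishable under this metric).
    """
    X = sal.states.to_numpy(dtype=np.int64)
    both = X @ X.T
    row = X.sum(axis=1)
    union = row[:, None] + row[None, :] - both
    mismatch = union - both
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(union > 0, mismatch / np.maximum(union, 1), 0.0)
    if (union == 0).any() and (row == 0).any():
        warnings.warn("never-salient gene pair(s) assigned distance 0", stacklevel=2)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sal.genes, columns=sal.genes)


def ward_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Ward linkage on the given dissimilarities, not squared first (ward.D).

    Implemented by feeding sqrt(d) to scipy's Ward (whose Lance-Williams
    update runs in the squared domain) and squaring the resulting merge
    heights, which reproduces the ward.D recurrence on d exactly.
    """
    if dist.shape[0] < 2:
        raise ValueError("need >= 2 genes to cluster")
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if (arr < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(arr, checks=False)
    z = linkage(np.sqrt(condensed), method="ward")
    z[:, 2] = z[:, 2] ** 2
    return Dendrogram(linkage_matrix=z, labels=list(dist.index))


def decompose_subclusters(dendro: Dendrogram, gene_min_p: pd.Series,
                          alpha: float = 0.05, k_max: int = 10) -> ClusterDecomposition:
    """Cut the dendrogram into k = 2, 3, ... groups until the gene-wise minimum
    eQTL p-values differ significantly (Kruskal-Wallis p < alpha) between groups.

    Cutting at successive k is equivalent to gradually lowering a height
    threshold through the merge heights.  Only genes with a non-missing
    minimum p enter the tests.  Returns "no decomposition" (``n_subclusters``
    None) if no k up to ``k_max`` is significant.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    usable = gene_min_p.dropna()
    usable = usable[usable.index.isin(dendro.labels)]
    kw_by_k: dict[int, float] = {}
    k_cap = min(k_max, len(dendro.labels))
    for k in range(2, k_cap + 1):
        labels = dendro.cut(k)
        groups = [usable[labels.index[labels == c].intersection(usable.index)].to_numpy()
                  for c in range(1, k + 1)]
        groups = [g for g in groups if g.size >= 1]
        if len(groups) < 2:
            kw_by_k[k] = np.nan
            continue
        p = kruskal_pvalue(groups)
        kw_by_k[k] = p
        if p < alpha:
            medians = {}
            sizes = {}
            for c in range(1, k + 1):
                members = labels.index[labels == c]
                sizes[c] = int(len(members))
                vals = usable[members.intersection(usable.index)]
                medians[c] = float(vals.median()) if len(vals) else np.nan
            return ClusterDecomposition(dendro, k, labels, medians, sizes,
                                        kw_by_k, alpha)
    return ClusterDecomposition(dendro, None, None, None, None, kw_by_k, alpha)


def select_target_subcluster(decomp: ClusterDecomposition) -> frozenset[str]:
    """Genes of the sub-cluster with the smallest median minimum eQTL p.

    Ties are broken by smaller cluster size, then by cluster label.
    """
    if decomp.n_subclusters is None:
        raise ValueError("no decomposition available (no significant split found)")
    assert decomp.medians is not None and decomp.sizes is not None
    candidates = [c for c in decomp.medians if np.isfinite(decomp.medians[c])]
    if not candidates:
        raise ValueError("no sub-cluster has a computable median")
    best = min(candidates, key=lambda c: (decomp.medians[c], decomp.sizes[c], c))
    labels = decomp.labels
    return frozenset(labels.index[labels == best])


def hypergeometric_enrichment(gene_set: frozenset[str] | set[str],
                              annotation: Mapping[str, set[str]],
                              background: frozenset[str] | set[str],
                              min_term_genes: int = 10) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene set against term annotations.

    Terms with fewer than ``min_term_genes`` genes in the background are
    excluded; p-values are Bonferroni-corrected over the tested terms.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set must be nonempty")
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background")
    M, n = len(background), len(gene_set)
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & background
        K = len(term_genes)
        if K < min_term_genes:
            continue
        k = len(term_genes & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append((term, k, K, p))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0) if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def write_eqtl_tsv(eqtl: EqtlMatrix, path: str | Path) -> None:
    eqtl.p.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
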