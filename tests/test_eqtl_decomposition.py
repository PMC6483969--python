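import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcnet.eqtl_decomposition import (Dendrogram, binary_distance,
                                      decompose_subclusters, eqtl_significance,
                                      hypergeometric_enrichment, min_p_per_gene,
                                      select_target_subcluster, trans_eqtl,
                                      ward_cluster, EqtlMatrix)
from mcnet.salience import ExpressionMatrix, SalienceMatrix
from .test_genetics import hwe_panel, make_panel


def expr_matrix(values, genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestTransEqtl:
    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        n = 150
        panel = hwe_panel(rng, [0.3, 0.4], n)
        expr = expr_matrix(rng.normal(size=(100, n)))
        eqtl = trans_eqtl(expr, panel)
        ps = eqtl.p.to_numpy().ravel()
        ps = ps[np.isfinite(ps)]
        frac = (ps < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_power_strong_shift(self):
        rng = np.random.default_rng(1)
        n = 300
        panel = hwe_panel(rng, [0.4], n)
        d = panel.dosage.iloc[0].to_numpy()
        e = 2.0 * d + rng.normal(0, 1, n)  # 2 SD shift per allele
        eqtl = trans_eqtl(expr_matrix([e]), panel)
        assert eqtl.p.iloc[0, 0] < 1e-6

    def test_monomorphic_snp_missing_column(self):
        rng = np.random.default_rng(2)
        poly = rng.binomial(2, 0.4, 60).astype(float)
        panel = make_panel(np.vstack([np.zeros(60), poly]), pos=[1000, 2000])
        expr = expr_matrix(rng.normal(size=(5, 60)))
        eqtl = trans_eqtl(expr, panel)
        assert eqtl.p["snp0"].isna().all()
        assert eqtl.p["snp1"].notna().all()

    def test_no_shared_samples(self):
        rng = np.random.default_rng(3)
        panel = hwe_panel(rng, [0.3], 10)
        expr = expr_matrix(rng.normal(size=(2, 10)),
                           samples=[f"X{j}" for j in range(10)])
        with pytest.raises(ValueError, match="shared"):
            trans_eqtl(expr, panel)


class TestEqtlSignificance:
    def test_regional_and_study_wide_thresholds(self):
        eqtl = EqtlMatrix(pd.DataFrame([[0.5]]), pd.DataFrame([[10]]))
        thr, _hr, _hs = eqtl_significance(eqtl, m_eff=45, n_genes=1348)
        assert thr.per_snp_corrected == pytest.approx(0.05 / 45)
        assert thr.per_snp_corrected == pytest.approx(1.1e-3, rel=0.02)
        assert thr.study_wide == pytest.approx(0.05 / (45 * 1348))
        assert thr.study_wide == pytest.approx(8.2e-7, rel=0.02)

    def test_trivial_thresholds(self):
        eqtl = EqtlMatrix(pd.DataFrame([[0.04]]), pd.DataFrame([[10]]))
        thr, hr, hs = eqtl_significance(eqtl, m_eff=1, n_genes=1)
        assert thr.per_snp_corrected == 0.05 and thr.study_wide == 0.05
        assert hr.iloc[0, 0] and hs.iloc[0, 0]


class TestMinP:
    def test_row_minimum(self):
        eqtl = EqtlMatrix(pd.DataFrame([[0.2, 0.01, 0.5]], index=["g"]),
                          pd.DataFrame([[5, 5, 5]], index=["g"]))
        assert min_p_per_gene(eqtl).loc["g"] == 0.01

    def test_all_missing_dropped(self):
        eqtl = EqtlMatrix(pd.DataFrame([[np.nan, np.nan], [0.3, 0.1]],
                                       index=["bad", "ok"]),
                          pd.DataFrame([[0, 0], [5, 5]], index=["bad", "ok"]))
        with pytest.warns(UserWarning, match="dropped"):
            mins = min_p_per_gene(eqtl)
        assert list(mins.index) == ["ok"]

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        P = rng.uniform(size=(20, 8))
        eqtl = EqtlMatrix(pd.DataFrame(P), pd.DataFrame(np.full((20, 8), 9)))
        mins = min_p_per_gene(eqtl)
        for i in range(20):
            assert mins.iloc[i] == pytest.approx(min(P[i]))


def sal_matrix(states, genes=None):
    arr = np.asarray(states, dtype=np.int8)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"S{j}" for j in range(arr.shape[1])]
    return SalienceMatrix(pd.DataFrame(arr, index=genes, columns=samples), q=0.02)


class TestBinaryDistance:
    def test_identical_rows_zero(self):
        d = binary_distance(sal_matrix([[1, 0, 1], [1, 0, 1]]))
        assert d.iloc[0, 1] == 0.0

    def test_hand_count(self):
        # rows (1,0,1) and (1,1,0): one joint, two mismatches -> 2/3
        d = binary_distance(sal_matrix([[1, 0, 1], [1, 1, 0]]))
        assert d.iloc[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_supports_one(self):
        d = binary_distance(sal_matrix([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert d.iloc[0, 1] == 1.0

    def test_never_salient_pair_zero_with_warning(self):
        with pytest.warns(UserWarning, match="never-salient"):
            d = binary_distance(sal_matrix([[0, 0, 0], [0, 0, 0]]))
        assert d.iloc[0, 1] == 0.0

    def test_metric_properties_and_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        states = (rng.random((12, 30)) < 0.2).astype(int)
        d = binary_distance(sal_matrix(states))
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all() and (arr <= 1).all()
        perm = rng.permutation(30)
        d2 = binary_distance(sal_matrix(states[:, perm]))
        assert np.allclose(arr, d2.to_numpy())


def block_distance(sizes, within=0.1, between=0.9, rng=None, noise=0.0):
    """Planted-partition distance matrix with optional noise."""
    n = sum(sizes)
    labels = np.concatenate([[i] * s for i, s in enumerate(sizes)])
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if rng is not None and noise > 0:
        jitter = rng.uniform(0, noise, size=(n, n))
        jitter = (jitter + jitter.T) / 2
        D = D + jitter
    np.fill_diagonal(D, 0.0)
    genes = [f"g{i:02d}" for i in range(n)]
    return pd.DataFrame(D, index=genes, columns=genes), labels


class TestWardCluster:
    def test_two_tight_groups_recovered(self):
        rng = np.random.default_rng(6)
        dist, truth = block_distance([8, 7], rng=rng, noise=0.05)
        dendro = ward_cluster(dist)
        got = dendro.cut(2).to_numpy()
        # same partition up to label swap
        assert (pd.crosstab(got, truth).to_numpy() > 0).sum() == 2

    def test_two_genes_merge_at_distance(self):
        dist = pd.DataFrame([[0.0, 0.42], [0.42, 0.0]], index=["a", "b"],
                            columns=["a", "b"])
        dendro = ward_cluster(dist)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.42)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        dist, _ = block_distance([5, 5, 5], rng=rng, noise=0.05)
        dendro = ward_cluster(dist)
        perm = rng.permutation(len(dist))
        dist_p = dist.iloc[perm, perm]
        dendro_p = ward_cluster(dist_p)
        for k in (2, 3):
            a = dendro.cut(k)
            b = dendro_p.cut(k).loc[a.index]
            assert (pd.crosstab(a, b).to_numpy() > 0).sum(axis=1).max() == 1

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(8)
        dist, _ = block_distance([4, 4, 4], rng=rng, noise=0.3)
        z = ward_cluster(dist).linkage_matrix
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_cut_produces_exactly_k(self):
        rng = np.random.default_rng(9)
        dist, _ = block_distance([6, 6], rng=rng, noise=0.4)
        dendro = ward_cluster(dist)
        for k in range(2, 12):
            assert dendro.cut(k).nunique() == k

    def test_single_gene_rejected(self):
        dist = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            ward_cluster(dist)

    def test_newick_parses(self):
        rng = np.random.default_rng(10)
        dist, _ = block_distance([3, 3], rng=rng, noise=0.1)
        nwk = ward_cluster(dist).to_newick()
        import io

        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(dist.index)


def four_block_setup(rng, sizes=(10, 10, 10, 10)):
    """Blocks A,B merge tightly; C,D merge at a higher height; the k=2 cut
    gives {A+B} vs {C+D} with matched min-p mixtures (not significant), and
    the k=3 cut exposes C (all small min-p) vs D (all large)."""
    nA, nB, nC, nD = sizes
    n = sum(sizes)
    genes = [f"g{i:02d}" for i in range(n)]
    labels = np.concatenate([[0] * nA, [1] * nB, [2] * nC, [3] * nD])
    base = np.array([[0.05, 0.30, 0.95, 0.95],
                     [0.30, 0.05, 0.95, 0.95],
                     [0.95, 0.95, 0.05, 0.60],
                     [0.95, 0.95, 0.60, 0.05]])
    D = base[np.ix_(labels, labels)].astype(float)
    jit = rng.uniform(0, 0.02, size=(n, n))
    D += (jit + jit.T) / 2
    np.fill_diagonal(D, 0.0)
    dist = pd.DataFrame(D, index=genes, columns=genes)
    # min-p: A and C small, B and D large -> k=2 groups are identical mixtures
    min_p = np.concatenate([rng.uniform(0.001, 0.01, nA),
                            rng.uniform(0.2, 0.9, nB),
                            rng.uniform(0.001, 0.01, nC),
                            rng.uniform(0.2, 0.9, nD)])
    return dist, pd.Series(min_p, index=genes), labels


class TestDecomposition:
    def test_planted_branch_found_at_k3(self):
        rng = np.random.default_rng(11)
        dist, min_p, labels = four_block_setup(rng)
        dendro = ward_cluster(dist)
        decomp = decompose_subclusters(dendro, min_p, alpha=0.05, k_max=8)
        assert decomp.n_subclusters == 3
        assert decomp.kw_p_by_k[2] >= 0.05 and decomp.kw_p_by_k[3] < 0.05
        target = select_target_subcluster(decomp)
        planted_c = {g for g, l in zip(dist.index, labels) if l == 2}
        assert target == planted_c

    def test_identical_min_p_no_decomposition(self):
        rng = np.random.default_rng(12)
        dist, _, _ = four_block_setup(rng)
        flat = pd.Series(0.5, index=dist.index)
        dendro = ward_cluster(dist)
        decomp = decompose_subclusters(dendro, flat, alpha=0.05, k_max=6)
        assert decomp.n_subclusters is None
        with pytest.raises(ValueError, match="no decomposition"):
            select_target_subcluster(decomp)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(13)
        dist, min_p, _ = four_block_setup(rng)
        dendro = ward_cluster(dist)
        k_tight = decompose_subclusters(dendro, min_p, alpha=0.01, k_max=8).n_subclusters
        k_loose = decompose_subclusters(dendro, min_p, alpha=0.2, k_max=8).n_subclusters
        assert k_loose is not None
        if k_tight is not None:
            assert k_loose <= k_tight

    def test_k_max_validation(self):
        rng = np.random.default_rng(14)
        dist, min_p, _ = four_block_setup(rng)
        with pytest.raises(ValueError):
            decompose_subclusters(ward_cluster(dist), min_p, k_max=1)

    def test_median_tie_break(self):
        dendro = ward_cluster(pd.DataFrame(
            np.array([[0, .1, .9, .9, .9], [.1, 0, .9, .9, .9],
                      [.9, .9, 0, .1, .1], [.9, .9, .1, 0, .1],
                      [.9, .9, .1, .1, 0]]),
            index=list("abcde"), columns=list("abcde")))
        min_p = pd.Series([0.01, 0.01, 0.01, 0.01, 0.01], index=list("abcde"))
        labels = dendro.cut(2)
        decomp = decompose_subclusters(dendro, pd.Series(
            [0.001, 0.002, 0.5, 0.6, 0.7], index=list("abcde")), alpha=0.2, k_max=4)
        if decomp.n_subclusters is not None:
            target = select_target_subcluster(decomp)
            assert target == {"a", "b"}


class TestEnrichment:
    def test_maximal_enrichment(self):
        background = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        annotation = {"hit": set(gene_set)}
        df = hypergeometric_enrichment(gene_set, annotation, background)
        assert df.iloc[0]["p"] < 1e-10

    def test_disjoint_term_p_one(self):
        background = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        annotation = {"elsewhere": {f"g{i}" for i in range(50, 65)}}
        df = hypergeometric_enrichment(gene_set, annotation, background)
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_small_terms_excluded(self):
        background = {f"g{i}" for i in range(50)}
        annotation = {"small": {"g0", "g1"}}
        df = hypergeometric_enrichment({"g0"}, annotation, background)
        assert df.empty

    def test_brute_force_tail_oracle(self):
        background = {f"g{i}" for i in range(12)}
        gene_set = {f"g{i}" for i in range(5)}
        term = {f"g{i}" for i in range(3, 13) if i < 12}  # 9 genes... adjust below
        term = {f"g{i}" for i in range(2, 12)}  # 10 genes in background
        df = hypergeometric_enrichment(gene_set, {"t": term}, background,
                                       min_term_genes=10)
        k_obs = len(term & gene_set)
        M, K, n = 12, len(term), 5
        # enumerate all C(12,5) draws
        total = hits = 0
        for draw in itertools.combinations(sorted(background), 5):
            total += 1
            if len(set(draw) & term) >= k_obs:
                hits += 1
        assert df.iloc[0]["p"] == pytest.approx(hits / total)

    def test_gene_set_subset_required(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {}, {"a", "b"})
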