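"""Linear-model association of MC with dosage genotypes, plus rank tests.

One ordinary-least-squares fit per SNP on complete cases, with MC as the
continuous response, the SNP's minor-allele dosage as the focal regressor,
and covariates (categorical columns reference-coded).  A conditional scan
appends a top SNP's dosage to the covariates to search for independent
signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import kruskal_pvalue
from .coherence import MCProfile
from .genetics import DosagePanel

__all__ = [
    "GENOMEWIDE_ALPHA",
    "gwas_scan",
    "conditional_scan",
    "significance_thresholds",
    "group_heterogeneity",
    "manhattan_qq_export",
    "build_design",
]

GENOMEWIDE_ALPHA = 5e-8

RESULT_COLUMNS = ["snp", "chrom", "pos", "beta", "se", "t", "p", "n", "flag"]


def build_design(covars: pd.DataFrame | None, samples: Sequence[str],
                 adjust: Iterable[str] | None = None) -> pd.DataFrame:
    """Intercept plus selected covariate columns for the given samples.

    Categorical (non-numeric) columns are expanded to indicator columns with
    the lexicographically first level as reference; numeric columns pass
    through.  Included categorical columns must have >= 2 observed levels.
    """
    design = pd.DataFrame({"const": 1.0}, index=pd.Index(samples))
    if covars is None or adjust is None:
        return design
    cols = list(adjust)
    missing = [c for c in cols if c not in covars.columns]
    if missing:
        raise ValueError(f"covariate column(s) not found: {missing}")
    sub = covars.loc[list(samples), cols]
    for col in cols:
        s = sub[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            design[col] = s.astype(float)
        else:
            levels = sorted(s.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {col!r} has < 2 levels")
            for lev in levels[1:]:  # reference = lexicographically first level
                design[f"{col}[{lev}]"] = (s.astype(str) == lev).astype(float)
    return design


def _ols_focal(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float] | None:
    """OLS of y on X; returns (beta, se, t, p) for the last column, or None if
    the design is rank-deficient."""
    n, p = X.shape
    if n < p + 2:
        return None
    beta, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        return None
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    if se == 0:
        return None
    t = float(beta[-1]) / se
    pval = float(2.0 * stats.t.sf(abs(t), dof))
    return float(beta[-1]), se, t, max(pval, np.finfo(float).tiny)


def gwas_scan(mc: MCProfile | pd.Series, panel: DosagePanel,
              covars: pd.DataFrame | None = None,
              adjust: Iterable[str] | None = None,
              skip_snps: Iterable[str] = ()) -> pd.DataFrame:
    """Per-SNP OLS of MC on minor-allele dosage with covariate adjustment.

    Samples with missing MC are excluded; each SNP uses its own complete
    cases.  Monomorphic SNPs and rank-deficient designs are emitted with a
    flag and missing p.
    """
    y_all = mc.mc_series() if isinstance(mc, MCProfile) else mc
    y_all = y_all.dropna()
    samples = [s for s in panel.samples if s in y_all.index]
    if covars is not None:
        samples = [s for s in samples if s in covars.index]
    if not samples:
        raise ValueError("no shared samples between MC, panel and covariates")

    base = build_design(covars, samples, adjust)
    Xbase = base.to_numpy(dtype=float)
    y = y_all.loc[samples].to_numpy(dtype=float)
    dosage = panel.dosage[samples].to_numpy(dtype=float)
    skip = set(skip_snps)

    rows = []
    for i, snp in enumerate(panel.snp_ids):
        chrom = panel.snps["chrom"].iloc[i]
        pos = int(panel.snps["pos"].iloc[i])
        if snp in skip:
            rows.append((snp, chrom, pos, np.nan, np.nan, np.nan, np.nan, 0, "skipped"))
            continue
        d = dosage[i]
        obs = np.isfinite(d)
        n_used = int(obs.sum())
        if n_used < Xbase.shape[1] + 3:
            rows.append((snp, chrom, pos, np.nan, np.nan, np.nan, np.nan, n_used,
                         "insufficient_n"))
            continue
        dv = d[obs]
        if dv.std() == 0:
            rows.append((snp, chrom, pos, np.nan, np.nan, np.nan, np.nan, n_used,
                         "monomorphic"))
            continue
        X = np.column_stack([Xbase[obs], dv])
        fit = _ols_focal(X, y[obs])
        if fit is None:
            rows.append((snp, chrom, pos, np.nan, np.nan, np.nan, np.nan, n_used,
                         "collinear"))
            continue
        beta, se, t, pval = fit
        rows.append((snp, chrom, pos, beta, se, t, pval, n_used, ""))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def conditional_scan(mc: MCProfile | pd.Series, panel: DosagePanel,
                     covars: pd.DataFrame | None = None,
                     adjust: Iterable[str] | None = None,
                     top_snp: str = "") -> pd.DataFrame:
    """GWAS scan with the top SNP's dosage as an extra covariate (top SNP skipped)."""
    if top_snp not in panel.snps.index:
        raise ValueError(f"top SNP {top_snp!r} not present in panel")
    top = panel.dosage.loc[top_snp]
    cond = pd.DataFrame({"__top_dosage": top.astype(float)})
    cond = cond.dropna()
    if covars is not None:
        covars = covars.join(cond, how="inner")
    else:
        covars = cond
    adj = list(adjust) if adjust is not None else []
    adj.append("__top_dosage")
    return gwas_scan(mc, panel, covars, adjust=adj, skip_snps=[top_snp])


def significance_thresholds(n_snps_genomewide: int | None = None,
                            m_eff_region: float = 1.0) -> tuple[float, float]:
    """(genome-wide, regional) significance thresholds.

    Genome-wide is the conventional 5e-8 regardless of SNP count; the regional
    threshold is 0.05 Bonferroni-corrected by the LD-effective test count.
    """
    if m_eff_region < 1:
        raise ValueError("m_eff_region must be >= 1")
    return GENOMEWIDE_ALPHA, 0.05 / m_eff_region


def group_heterogeneity(values: Sequence[float] | pd.Series,
                        labels: Sequence) -> float:
    """Two-sided Wilcoxon rank-sum (2 groups) or Kruskal-Wallis (>2) p-value.

    The Wilcoxon test is enumerated exactly for tie-free samples with both
    group sizes <= 25, else the normal approximation with continuity
    correction is used.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have equal length")
    mask = np.isfinite(v)
    v, lab = v[mask], lab[mask]
    groups = [v[lab == g] for g in pd.unique(lab)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with non-missing values")
    if len(groups) == 2:
        a, b = groups
        tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (tie_free and max(a.size, b.size) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        return float(res.pvalue)
    return kruskal_pvalue(groups)


def manhattan_qq_export(results: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Plot-ready Manhattan and QQ tables plus the genomic inflation factor.

    Returns (manhattan, qq, lambda_gc) where manhattan has columns
    (snp, chrom, pos, minus_log10_p), qq has (expected, observed) -log10
    quantiles, and lambda_gc is the median-based inflation factor.
    """
    usable = results.dropna(subset=["p"])
    if usable.empty:
        raise ValueError("no usable association results")
    manhattan = usable[["snp", "chrom", "pos"]].copy()
    manhattan["minus_log10_p"] = -np.log10(usable["p"].to_numpy())

    p_sorted = np.sort(usable["p"].to_numpy())
    m = p_sorted.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    # both columns ascending: i-th smallest observed against i-th smallest expected
    qq = pd.DataFrame({"expected": -np.log10(expected)[::-1],
                       "observed": -np.log10(p_sorted)[::-1]})

    chi2_obs = stats.chi2.isf(p_sorted, df=1)
    lambda_gc = float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))
    return manhattan, qq, lambda_gc
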