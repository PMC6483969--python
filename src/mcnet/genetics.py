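"""Genotype QC, LD utilities, PCA, and the LD-effective number of tests.

Genotypes are carried as minor-allele dosages in [0, 2] (fractional after
imputation, NaN where missing) in a SNPs x samples panel with per-SNP
metadata (chromosome, 1-based position, minor/major alleles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosagePanel",
    "QCCriteria",
    "EffectiveTestCount",
    "hwe_test",
    "snp_qc",
    "ld_r2",
    "ld_prune",
    "genotype_pca",
    "effective_tests",
    "read_vcf",
    "write_vcf",
    "read_panel_tsv",
    "write_panel_tsv",
]

AUTOSOMES = {str(i) for i in range(1, 23)}
SOFT_DOSAGE_TOL = 0.1      # |dosage - round| beyond this is "materially fractional"
SOFT_DOSAGE_MAX_FRAC = 0.1  # >10% such samples marks the SNP soft

META_COLUMNS = ["chrom", "pos", "minor", "major"]


@dataclass
class DosagePanel:
    """SNPs x samples minor-allele dosage matrix plus per-SNP metadata.

    ``snps`` is indexed by SNP ID with columns chrom (str), pos (int, 1-based),
    minor, major.  ``dosage`` shares the SNP index; columns are sample IDs.
    """

    snps: pd.DataFrame
    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.snps.index) != list(self.dosage.index):
            raise ValueError("snps and dosage must share an identical SNP index")
        if self.snps.index.has_duplicates:
            raise ValueError("SNP IDs must be unique")
        missing = [c for c in META_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"snps metadata missing columns {missing}")
        if (self.snps["pos"].to_numpy() < 0).any():
            raise ValueError("positions must be nonnegative")
        arr = self.dosage.to_numpy(dtype=float)
        if arr.size and np.isfinite(arr).any():
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr) < -1e-9 or np.nanmax(arr) > 2 + 1e-9:
                    raise ValueError("dosages must lie in [0, 2] (or be missing)")

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_frequency(self) -> pd.Series:
        """Dosage-estimated frequency of the allele the dosage counts."""
        return self.dosage.mean(axis=1, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def polarize_minor(self) -> "DosagePanel":
        """Flip SNPs whose counted allele has frequency > 0.5 to minor-allele dosage."""
        f = self.allele_frequency()
        flip = f > 0.5
        if not flip.any():
            return self
        dosage = self.dosage.copy()
        snps = self.snps.copy()
        dosage.loc[flip] = 2.0 - dosage.loc[flip]
        minor = snps.loc[flip, "minor"].copy()
        snps.loc[flip, "minor"] = snps.loc[flip, "major"]
        snps.loc[flip, "major"] = minor
        return DosagePanel(snps, dosage)

    def subset_snps(self, ids: Iterable[str]) -> "DosagePanel":
        ids = [s for s in ids if s in self.snps.index]
        return DosagePanel(self.snps.loc[ids], self.dosage.loc[ids])

    def subset_samples(self, samples: Iterable[str]) -> "DosagePanel":
        cols = [s for s in samples if s in self.dosage.columns]
        return DosagePanel(self.snps, self.dosage[cols])

    def region(self, chrom: str, start: int, end: int) -> "DosagePanel":
        """SNPs with position in the closed interval [start, end] on chrom."""
        mask = (self.snps["chrom"].astype(str) == str(chrom)) & \
               (self.snps["pos"] >= start) & (self.snps["pos"] <= end)
        return DosagePanel(self.snps.loc[mask], self.dosage.loc[mask])


@dataclass(frozen=True)
class QCCriteria:
    min_call_rate: float = 0.99
    min_maf: float = 0.05
    min_minor_homs: int = 5
    min_hwe_p: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1):
            raise ValueError("min_call_rate must lie in [0, 1]")
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must lie in [0, 0.5)")
        if self.min_minor_homs < 0:
            raise ValueError("min_minor_homs must be >= 0")
        if not (0 <= self.min_hwe_p <= 1):
            raise ValueError("min_hwe_p must lie in [0, 1]")


@dataclass(frozen=True)
class EffectiveTestCount:
    m_eff: float
    method: str = "li-ji-2005"

    def __post_init__(self) -> None:
        if self.m_eff < 1:
            raise ValueError("m_eff must be >= 1")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against Hardy-Weinberg proportions.

    Monomorphic markers (one allele absent) return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    if p_hat == 0.0 or p_hat == 1.0:
        return 1.0
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat ** 2, 2 * n * p_hat * q_hat, n * q_hat ** 2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hard_calls(dosage_row: np.ndarray) -> np.ndarray:
    """Round dosages to 0/1/2; NaN preserved."""
    calls = np.round(dosage_row)
    return np.clip(calls, 0, 2)


def snp_qc(panel: DosagePanel, criteria: QCCriteria = QCCriteria(),
           autosomes_only: bool = True) -> tuple[DosagePanel, pd.DataFrame]:
    """Filter SNPs by call rate, autosomal location, MAF, minor-homozygote count and HWE.

    The report lists, per SNP, pass/fail, the first failing criterion, and a
    ``soft`` flag.  SNPs with materially fractional dosages (imputed) are
    flagged soft and the hard-call criteria (minor homozygotes, HWE) are
    skipped for them.
    """
    dosage = panel.dosage.to_numpy(dtype=float)
    n_samples = dosage.shape[1]
    rows = []
    for i, snp in enumerate(panel.snp_ids):
        d = dosage[i]
        obs = np.isfinite(d)
        n_obs = int(obs.sum())
        reason = None
        soft = False

        call_rate = n_obs / n_samples if n_samples else 0.0
        if call_rate < criteria.min_call_rate:
            reason = "min_call_rate"

        chrom = str(panel.snps["chrom"].iloc[i])
        if reason is None and autosomes_only:
            if chrom.removeprefix("chr") not in AUTOSOMES:
                reason = "autosome"

        if reason is None:
            if n_obs == 0:
                reason = "min_maf"
            else:
                f = np.nanmean(d) / 2.0
                maf = min(f, 1.0 - f)
                if not maf > criteria.min_maf:
                    reason = "min_maf"

        if reason is None and n_obs > 0:
            dv = d[obs]
            frac_soft = float((np.abs(dv - np.round(dv)) > SOFT_DOSAGE_TOL).mean())
            soft = frac_soft > SOFT_DOSAGE_MAX_FRAC
            if not soft:
                calls = _hard_calls(dv)
                minor_dose = calls if np.nanmean(dv) <= 1.0 else 2 - calls
                n_minor_hom = int((minor_dose == 2).sum())
                if n_minor_hom < criteria.min_minor_homs:
                    reason = "min_minor_homs"
                else:
                    n2 = int((calls == 2).sum())
                    n1 = int((calls == 1).sum())
                    n0 = int((calls == 0).sum())
                    if hwe_test(n2, n1, n0) < criteria.min_hwe_p:
                        reason = "min_hwe_p"

        rows.append((snp, reason is None, reason, soft))

    report = pd.DataFrame(rows, columns=["snp", "pass", "fail_reason", "soft"])
    report = report.set_index("snp")
    kept = [s for s in panel.snp_ids if report.loc[s, "pass"]]
    return panel.subset_snps(kept), report


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over pairwise-complete dosage entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2:
        raise ValueError("need >= 2 complete pairs for r^2")
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("r^2 undefined for zero-variance dosage vector")
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(panel: DosagePanel, r2_max: float = 0.8,
             window_bp: int = 500_000) -> DosagePanel:
    """Greedy left-to-right LD pruning within a bp window, per chromosome.

    A SNP is dropped if its r^2 with any *retained* SNP at most ``window_bp``
    upstream exceeds ``r2_max``.  ``window_bp == 0`` retains everything.
    """
    if window_bp <= 0:
        return panel
    order = panel.snps.sort_values(["chrom", "pos"], kind="stable").index
    dosage = panel.dosage
    kept: list[str] = []
    kept_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for snp in order:
        chrom = str(panel.snps.loc[snp, "chrom"])
        pos = int(panel.snps.loc[snp, "pos"])
        drop = False
        for prev_pos, prev_snp in reversed(kept_by_chrom.get(chrom, [])):
            if pos - prev_pos > window_bp:
                break
            try:
                r2 = ld_r2(dosage.loc[snp].to_numpy(), dosage.loc[prev_snp].to_numpy())
            except ValueError:
                continue  # degenerate pair: cannot assess LD, keep scanning
            if r2 > r2_max:
                drop = True
                break
        if not drop:
            kept.append(snp)
            kept_by_chrom.setdefault(chrom, []).append((pos, snp))
    keep_in_original_order = [s for s in panel.snp_ids if s in set(kept)]
    return panel.subset_snps(keep_in_original_order)


def genotype_pca(panel: DosagePanel, n_components: int = 10
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-SNP standardized dosages; returns sample scores and variance fractions."""
    if len(panel.samples) < 2 or panel.n_snps < 2:
        raise ValueError("need >= 2 samples and >= 2 SNPs for PCA")
    X = panel.dosage.to_numpy(dtype=float).T  # samples x snps
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / np.where(sd[keep] == 0, 1, sd[keep])
    if X.shape[1] == 0:
        scores = pd.DataFrame(np.zeros((len(panel.samples), n_components)),
                              index=panel.samples,
                              columns=[f"PC{i+1}" for i in range(n_components)])
        return scores, np.zeros(n_components)

    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size and S[0] > 0 else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating",
                      stacklevel=2)
    k = min(n_components, max(rank, 0))
    total_var = float((S ** 2).sum())
    scores_arr = U[:, :k] * S[:k]
    scores = pd.DataFrame(scores_arr, index=panel.samples,
                          columns=[f"PC{i+1}" for i in range(k)])
    var_frac = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, var_frac


def effective_tests(panel: DosagePanel) -> EffectiveTestCount:
    """LD-effective number of tests via the Li & Ji (2005) eigenvalue rule.

    m_eff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ] over the
    eigenvalues of the SNP dosage correlation matrix (pairwise complete).
    """
    if panel.n_snps < 1:
        raise ValueError("need >= 1 SNP")
    if panel.n_snps == 1:
        return EffectiveTestCount(1.0)
    corr = panel.dosage.T.corr().to_numpy()
    bad = ~np.isfinite(corr)
    if bad.any():
        warnings.warn("degenerate correlation entries imputed to 0", stacklevel=2)
        corr[bad] = 0.0
        np.fill_diagonal(corr, 1.0)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    m_eff = min(max(m_eff, 1.0), float(panel.n_snps))
    return EffectiveTestCount(m_eff)


# ---------------------------------------------------------------------------
# I/O

def read_vcf(path: str | Path, polarize: bool = True) -> DosagePanel:
    """Read a VCF into a dosage panel.

    Prefers the DS FORMAT field; falls back to hard GT converted to 0/1/2
    ALT-allele counts.  Multi-allelic sites are skipped with a warning.  By
    default the panel is re-polarized to minor-allele dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    meta_rows, dosage_rows, ids = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < -0.5) | (d > 2.5), np.nan, d)
        else:
            gt = np.asarray(var.gt_types, dtype=float)
            d = np.where(gt == 3, np.nan, gt)
        ids.append(snp_id)
        meta_rows.append((str(var.CHROM), int(var.POS), var.ALT[0], var.REF))
        dosage_rows.append(d)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic site(s)", stacklevel=2)
    snps = pd.DataFrame(meta_rows, columns=META_COLUMNS, index=pd.Index(ids, name="snp"))
    dosage = pd.DataFrame(np.array(dosage_rows, dtype=float).reshape(len(ids), -1),
                          index=snps.index, columns=samples)
    panel = DosagePanel(snps, dosage)
    return panel.polarize_minor() if polarize else panel


def write_vcf(panel: DosagePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF with GT (hard call) and DS fields.

    REF is the major allele and ALT the minor allele, so DS equals the stored
    minor-allele dosage.
    """
    chroms = list(dict.fromkeys(str(c) for c in panel.snps["chrom"]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mcnet\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        dosage = panel.dosage.to_numpy(dtype=float)
        order = panel.snps.sort_values(["chrom", "pos"], kind="stable").index
        pos_of = {s: i for i, s in enumerate(panel.snp_ids)}
        for snp in order:
            i = pos_of[snp]
            meta = panel.snps.loc[snp]
            fields = [str(meta["chrom"]), str(int(meta["pos"])), snp,
                      str(meta["major"]), str(meta["minor"]), ".", "PASS", ".", "GT:DS"]
            for d in dosage[i]:
                if not np.isfinite(d):
                    fields.append("./.:.")
                    continue
                call = int(np.clip(round(d), 0, 2))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[call]
                fields.append(f"{gt}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


def read_panel_tsv(path: str | Path, polarize: bool = True) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    df = df.set_index("snp")
    snps = df[META_COLUMNS].copy()
    snps["pos"] = snps["pos"].astype(int)
    dosage = df.drop(columns=META_COLUMNS).astype(float)
    panel = DosagePanel(snps, dosage)
    return panel.polarize_minor() if polarize else panel


def write_panel_tsv(panel: DosagePanel, path: str | Path) -> None:
    out = pd.concat([panel.snps, panel.dosage], axis=1)
    out.to_csv(path, sep="\t", index_label="snp", float_format="%.6g")
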