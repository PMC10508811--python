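"""Latent-factor SNP association and heterogeneity statistics.

Builds on a measurement model previously fit to the genetic correlation
matrix (see :mod:`psychstruct.factor_models`). For each SNP the genetic
covariance matrix is conceptually expanded with a SNP row (SNP variance
2 MAF (1 - MAF)); with the measurement parameters held at their no-SNP
solution, the common-pathway model (SNP -> factor only) is a generalized
least squares problem that is linear in the SNP -> factor path, so the
per-SNP estimate, its SE, and the fit decrement against the saturated
independent-pathways model (SNP -> every indicator) are closed-form:

    b_hat = a' W s / (a' W a),    W = Sigma_s^-1,   a_i = lambda_i
    Q_SNP = s' W s - (a' W s)^2 / (a' W a)   ~  chi2(m - 1)

where s are the standardized SNP-indicator genetic covariances and Sigma_s
their sampling covariance, built from the per-indicator GWAS standard
errors and the LDSC cross-trait intercepts (which capture the error
correlation induced by sample overlap). Q_Trait replaces the SNP row with
an external trait's genetic correlations and their jackknife covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .factor_models import CfaFit, ModelSpec
from .ldsc import GeneticCov, lambda_gc, standardized_cov

__all__ = [
    "FactorGwasSummary",
    "factor_gwas",
    "snp_factor_assoc",
    "qsnp",
    "qsnp_from_scan",
    "qtrait",
    "factor_neff",
    "gwas_summary",
    "qtrait_significant_share",
    "write_factor_gwas",
]

FACTOR_GWAS_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "MAF", "BETA", "SE", "Z", "N", "NEFF", "INFO",
    "QCHISQ", "QDF", "QP",
]


@dataclass
class FactorGwasSummary:
    mean_chisq: float
    q_mean_chisq: float
    lambda_gc: float
    n_hat: float
    loci_count: int
    q_loci_count: int


def _factor_measurement(fit: CfaFit, factor: str):
    """Indicators of a factor with their (simple-structure) loadings."""
    if factor not in fit.loadings.columns:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    lam = fit.loadings[factor]
    inds = [i for i in lam.index if lam[i] != 0.0]
    if len(inds) < 2:
        raise ValueError(
            f"factor {factor!r} has {len(inds)} indicator(s); heterogeneity "
            "statistics are undefined for single-indicator factors"
        )
    return inds, lam[inds].to_numpy()


def _scaling_d(gcov: GeneticCov, idx) -> np.ndarray:
    """sqrt observed-scale h2 per indicator; non-positive estimates are
    floored at 1e-4 with a warning (the indicator's standardized SNP effects
    then carry near-infinite sampling variance and contribute ~nothing)."""
    import warnings

    diag = np.diag(gcov.S)[idx]
    if np.any(diag < 1e-4):
        bad = [gcov.traits[i] for i, v in zip(idx, diag) if v < 1e-4]
        warnings.warn(f"non-positive h2 estimate for {bad}; floored at 1e-4")
        diag = np.clip(diag, 1e-4, None)
    return np.sqrt(diag)


def _error_cov(se: np.ndarray, intercept_corr: np.ndarray) -> np.ndarray:
    """Sampling covariance of the SNP-indicator covariances: the SEs scaled
    by the cross-trait-intercept correlation structure (sample overlap)."""
    return np.outer(se, se) * intercept_corr


def factor_gwas(
    gcov: GeneticCov,
    fit: CfaFit,
    studies: list[pd.DataFrame],
    spec: ModelSpec,
    factor: str,
) -> pd.DataFrame:
    """SNP -> latent factor association scan with per-SNP Q_SNP.

    ``studies`` are the munged indicator sumstats, in the order of
    ``gcov.traits``; only the named factor's indicators enter. Effects are
    reported per allele (unstandardized genotype), so BETA/SE follow the
    usual sumstats convention and the factor N-hat formula applies directly.
    """
    del spec  # measurement comes from the fitted solution
    traits = list(gcov.traits)
    inds, lam = _factor_measurement(fit, factor)
    idx = [traits.index(t) for t in inds]
    m = len(inds)

    d = _scaling_d(gcov, idx)
    icorr = gcov.estimation_error_corr()[np.ix_(idx, idx)]

    aligned = [studies[i] for i in idx]
    base = aligned[0][["SNP", "CHR", "BP", "A1", "A2", "MAF"]].copy()
    shared = base["SNP"]
    for s in aligned[1:]:
        shared = shared[shared.isin(set(s["SNP"]))]
    base = base.set_index("SNP").loc[shared]
    Z = np.column_stack(
        [s.set_index("SNP").loc[shared, "Z"].to_numpy(dtype=float) for s in aligned]
    )
    N = np.column_stack(
        [s.set_index("SNP").loc[shared, "N"].to_numpy(dtype=float) for s in aligned]
    )
    maf = base["MAF"].to_numpy(dtype=float)
    var_snp = 2.0 * maf * (1.0 - maf)

    # standardized (genetic-scale) SNP-indicator covariances and their SEs;
    # per-SNP scaling cancels in b/SE so precompute the SNP-free parts
    s_std = Z / np.sqrt(N) / d  # n_snp x m
    se_std = 1.0 / (np.sqrt(N) * d)

    n_snps = len(base)
    beta = np.empty(n_snps)
    se = np.empty(n_snps)
    q = np.empty(n_snps)
    for j in range(n_snps):
        Sig = _error_cov(se_std[j], icorr)
        W = np.linalg.inv(Sig)
        a = lam
        aWa = float(a @ W @ a)
        aWs = float(a @ W @ s_std[j])
        beta[j] = aWs / aWa
        se[j] = 1.0 / np.sqrt(aWa)
        q[j] = float(s_std[j] @ W @ s_std[j]) - aWs**2 / aWa
    q = np.clip(q, 0.0, None)
    q_df = m - 1
    q_p = chi2_dist.sf(q, q_df)

    # convert to per-allele units
    beta_allele = beta / np.sqrt(var_snp)
    se_allele = se / np.sqrt(var_snp)
    neff = float(np.round(np.mean(1.0 / se**2)))
    out = base.reset_index()
    out["BETA"] = beta_allele
    out["SE"] = se_allele
    out["Z"] = beta / se
    out["N"] = neff
    out["NEFF"] = neff
    out["INFO"] = 1.0
    out["QCHISQ"] = q
    out["QDF"] = q_df
    out["QP"] = q_p
    return (
        out[FACTOR_GWAS_COLUMNS]
        .sort_values(["CHR", "BP"], kind="mergesort")
        .reset_index(drop=True)
    )


def snp_factor_assoc(
    gcov: GeneticCov,
    fit: CfaFit,
    factor: str,
    snp_cov: np.ndarray,
    snp_se: np.ndarray,
    maf: float,
) -> tuple[float, float]:
    """Single-SNP common-pathway estimate (beta, se) in per-allele units.

    ``snp_cov``/``snp_se`` are the SNP-indicator covariances (standardized
    genotype, observed trait scale) and their SEs, aligned to ``gcov.traits``.
    """
    var_snp = 2.0 * maf * (1.0 - maf)
    if var_snp <= 0:
        raise ValueError("SNP variance must be positive")
    traits = list(gcov.traits)
    inds, lam = _factor_measurement(fit, factor)
    idx = [traits.index(t) for t in inds]
    d = _scaling_d(gcov, idx)
    icorr = gcov.estimation_error_corr()[np.ix_(idx, idx)]
    s = np.asarray(snp_cov, dtype=float)[idx] / d
    se = np.asarray(snp_se, dtype=float)[idx] / d
    W = np.linalg.inv(_error_cov(se, icorr))
    aWa = float(lam @ W @ lam)
    beta_std = float(lam @ W @ s) / aWa
    se_std = 1.0 / np.sqrt(aWa)
    return beta_std / np.sqrt(var_snp), se_std / np.sqrt(var_snp)


def qsnp(
    gcov: GeneticCov,
    fit: CfaFit,
    factor: str,
    snp_cov: np.ndarray,
    snp_se: np.ndarray,
) -> tuple[float, int, float]:
    """Single-SNP heterogeneity: fit decrement between the common-pathway
    (SNP -> factor) and saturated independent-pathways (SNP -> indicators)
    models, on the chi^2 metric with df = m - 1."""
    traits = list(gcov.traits)
    inds, lam = _factor_measurement(fit, factor)
    idx = [traits.index(t) for t in inds]
    d = _scaling_d(gcov, idx)
    icorr = gcov.estimation_error_corr()[np.ix_(idx, idx)]
    s = np.asarray(snp_cov, dtype=float)[idx] / d
    se = np.asarray(snp_se, dtype=float)[idx] / d
    W = np.linalg.inv(_error_cov(se, icorr))
    aWa = float(lam @ W @ lam)
    aWs = float(lam @ W @ s)
    q = max(float(s @ W @ s) - aWs**2 / aWa, 0.0)
    q_df = len(inds) - 1
    return q, q_df, float(chi2_dist.sf(q, q_df))


def qsnp_from_scan(rows: pd.DataFrame) -> tuple[np.ndarray, int, np.ndarray]:
    """(q_chisq, q_df, q_p) arrays from a factor GWAS table."""
    return (
        rows["QCHISQ"].to_numpy(dtype=float),
        int(rows["QDF"].iloc[0]),
        rows["QP"].to_numpy(dtype=float),
    )


def qtrait(
    gcov_aug: GeneticCov,
    fit: CfaFit,
    factor: str,
    trait: str,
) -> dict:
    """Heterogeneity of an external trait's genetic correlations.

    ``gcov_aug`` must include the external trait as one of its rows/columns.
    The common-pathway model routes the trait's association through the
    factor (gamma * lambda_i); the independent-pathways model fits the m
    trait-indicator covariances exactly, so the decrement is the GLS
    residual with m - 1 degrees of freedom. The trait-indicator sampling
    covariance block comes from the jackknife V.
    """
    traits = list(gcov_aug.traits)
    if trait not in traits:
        raise ValueError(f"external trait {trait!r} not in the covariance matrix")
    t_idx = traits.index(trait)
    inds, lam = _factor_measurement(fit, factor)
    idx = [traits.index(t) for t in inds]

    R, V_std = standardized_cov(gcov_aug)
    k = len(traits)
    hv = [(i, j) for i in range(k) for j in range(i + 1)]
    hv_pos = {pr: e for e, pr in enumerate(hv)}

    def el(i, j):
        return hv_pos[(max(i, j), min(i, j))]

    sel = [el(t_idx, i) for i in idx]
    s = np.array([R[t_idx, i] for i in idx])
    Sig = V_std[np.ix_(sel, sel)]
    # guard nearly singular sampling covariance
    w, Q = np.linalg.eigh(0.5 * (Sig + Sig.T))
    floor = max(w.max() * 1e-10, 1e-14)
    W = (Q / np.clip(w, floor, None)) @ Q.T
    aWa = float(lam @ W @ lam)
    aWs = float(lam @ W @ s)
    gamma = aWs / aWa
    q = float(s @ W @ s) - aWs**2 / aWa
    q = max(q, 0.0)
    q_df = len(inds) - 1
    converged = bool(abs(gamma) < 5.0)
    return {
        "factor": factor,
        "trait": trait,
        "gamma": gamma,
        "gamma_se": 1.0 / np.sqrt(aWa),
        "q_chisq": q,
        "q_df": q_df,
        "q_p": float(chi2_dist.sf(q, q_df)),
        "converged": converged,
    }


def qtrait_significant_share(n_significant_q: int, n_significant_rg: int) -> float:
    """Share (percent) of factor-correlated traits flagged heterogeneous."""
    if n_significant_rg <= 0:
        raise ValueError("need at least one significantly correlated trait")
    if n_significant_q > n_significant_rg:
        raise ValueError("heterogeneous count cannot exceed the correlated count")
    return 100.0 * n_significant_q / n_significant_rg


def factor_neff(
    rows: pd.DataFrame, maf_window: tuple[float, float] = (0.10, 0.40)
) -> float:
    """Factor effective sample size: mean of 1 / (2 MAF (1 - MAF) SE^2) over
    SNPs with MAF inside the restriction window."""
    maf = rows["MAF"].to_numpy(dtype=float)
    se = rows["SE"].to_numpy(dtype=float)
    lo, hi = maf_window
    mask = (maf >= lo) & (maf <= hi) & np.isfinite(se) & (se > 0)
    if not np.any(mask):
        raise ValueError(f"no SNPs with MAF in [{lo}, {hi}]")
    return float(np.mean(1.0 / (2.0 * maf[mask] * (1.0 - maf[mask]) * se[mask] ** 2)))


def _count_loci(chrom, pos, significant, clump_kb: float) -> int:
    """Greedy merge of significant SNPs within clump_kb into loci."""
    loci = 0
    last_chr, last_pos = None, None
    order = np.lexsort((pos, chrom))
    for i in order:
        if not significant[i]:
            continue
        if last_chr != chrom[i] or pos[i] - last_pos > clump_kb * 1000:
            loci += 1
        last_chr, last_pos = chrom[i], pos[i]
    return loci


def gwas_summary(
    rows: pd.DataFrame, p_threshold: float = 5e-8, clump_kb: float = 250.0
) -> FactorGwasSummary:
    """Scan-level summaries: mean chi^2 for the factor and Q statistics,
    genomic inflation, factor N-hat, and distance-clumped locus counts."""
    z = rows["Z"].to_numpy(dtype=float)
    chi2 = z**2
    p = chi2_dist.sf(chi2, 1)
    chrom = rows["CHR"].to_numpy()
    pos = rows["BP"].to_numpy(dtype=float)
    qp = rows["QP"].to_numpy(dtype=float)
    return FactorGwasSummary(
        mean_chisq=float(np.mean(chi2)),
        q_mean_chisq=float(np.mean(rows["QCHISQ"].to_numpy(dtype=float))),
        lambda_gc=lambda_gc(chi2),
        n_hat=factor_neff(rows),
        loci_count=_count_loci(chrom, pos, p < p_threshold, clump_kb),
        q_loci_count=_count_loci(chrom, pos, qp < p_threshold, clump_kb),
    )


def write_factor_gwas(rows: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        rows[FACTOR_GWAS_COLUMNS].to_csv(fh, sep="\t", index=False)
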