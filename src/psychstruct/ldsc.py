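"""LD scores and LD-score regression.

Implements the univariate heritability regression (chi^2 on LD score),
cross-trait genetic covariance/correlation, the liability-scale conversion,
and the multivariable genetic covariance matrix S with its block-jackknife
sampling covariance V. LD scores are computed from the simulated cohort
itself (it plays the role of the reference panel).

Regression weights follow the standard two-component scheme: the product of
the heteroskedasticity weight 1/(1 + N h2 l/M)^2 (or its cross-trait
analogue) and the overcounting weight 1/l, with a first-pass unweighted fit
supplying the plug-in estimates. Standard errors come from a
delete-a-block jackknife over contiguous SNP blocks (200 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from ._utils import half_vec_index
from .synth import Cohort

__all__ = [
    "LdScores",
    "LdscFit",
    "RgFit",
    "GeneticCov",
    "ld_scores",
    "estimate_h2",
    "observed_to_liability",
    "attenuation_ratio",
    "lambda_gc",
    "estimate_rg",
    "genetic_cov_matrix",
    "standardized_cov",
    "write_genetic_cov",
    "read_genetic_cov",
]

MEDIAN_CHI2_1 = float(chi2_dist.ppf(0.5, df=1))  # 0.4549...


@dataclass
class LdScores:
    table: pd.DataFrame  # columns SNP, CHR, BP, L2
    window_snps: int
    n_ref: int

    @property
    def ell(self) -> np.ndarray:
        return np.asarray(self.table["L2"], dtype=float)


@dataclass
class LdscFit:
    h2_obs: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chisq: float
    lambda_gc: float
    attenuation_ratio: float  # NaN when mean_chisq <= 1 ("Ratio < 0" convention)
    n_blocks: int
    m_snps: int
    n_bar: float
    h2_liab: float | None = None
    delete_values: np.ndarray | None = None  # n_blocks x 2 (slope=h2, intercept)
    w_slope0: float = 0.0  # clipped step-1 plug-ins behind the weights
    w_icpt0: float = 1.0


@dataclass
class RgFit:
    rg: float
    rg_se: float
    gencov: float
    gencov_se: float
    cross_trait_intercept: float
    cross_trait_intercept_se: float
    h2_1: float
    h2_2: float
    out_of_bounds: bool = False
    undefined: bool = False
    n_blocks: int = 0


@dataclass
class GeneticCov:
    S: np.ndarray  # k x k genetic covariance (observed scale)
    V: np.ndarray  # m(m+1)/2 square sampling covariance, half-vec order
    traits: list[str]
    intercepts: np.ndarray  # k x k LDSC intercept matrix (cross-trait off-diag)
    smoothed: bool
    n_blocks: int
    m_snps: int
    n_bar: np.ndarray  # per-trait mean regression N
    # correlation of the per-SNP estimation errors across traits. Defaults to
    # the normalized cross-trait intercepts; under complete sample overlap the
    # sample phenotypic correlation of the outcomes is a far more precise
    # estimator of the same quantity and can be supplied here.
    error_corr: np.ndarray | None = None

    def half_vec_order(self):
        return half_vec_index(len(self.traits))

    def estimation_error_corr(self) -> np.ndarray:
        if self.error_corr is not None:
            return self.error_corr
        d = np.sqrt(np.clip(np.diag(self.intercepts), 1e-6, None))
        icorr = self.intercepts / np.outer(d, d)
        out = np.clip(0.5 * (icorr + icorr.T), -0.99, 0.99)
        np.fill_diagonal(out, 1.0)
        return out


def ld_scores(cohort: Cohort, window_snps: int = 60) -> LdScores:
    """Per-SNP LD score: sum of bias-adjusted squared correlations with SNPs
    within ``window_snps`` positions on the same chromosome.

    r2_adj = r^2 - (1 - r^2) / (n - 2); the self-term contributes exactly 1.
    """
    if window_snps < 1:
        raise ValueError("window must be >= 1 SNP")
    n = cohort.n_individuals
    if n <= 2:
        raise ValueError("need more than 2 individuals to adjust r^2")
    M = cohort.n_snps
    ell = np.zeros(M)
    for c in np.unique(cohort.chromosomes):
        idx = np.where(cohort.chromosomes == c)[0]
        order = idx[np.argsort(cohort.positions[idx], kind="mergesort")]
        Xi = cohort.dosages[:, order].astype(np.float64)
        Xi -= Xi.mean(axis=0)
        sd = Xi.std(axis=0)
        Xi /= np.where(sd > 0, sd, 1.0)
        R = (Xi.T @ Xi) / n
        r2 = R**2
        r2adj = r2 - (1.0 - r2) / (n - 2)
        m_c = len(order)
        pos_in_order = np.arange(m_c)
        band = np.abs(pos_in_order[:, None] - pos_in_order[None, :]) <= window_snps
        ell[order] = np.sum(np.where(band, r2adj, 0.0), axis=1)
    table = pd.DataFrame(
        {"SNP": cohort.snp_ids, "CHR": cohort.chromosomes, "BP": cohort.positions, "L2": ell}
    )
    return LdScores(table=table, window_snps=window_snps, n_ref=n)


def lambda_gc(chi2: np.ndarray) -> float:
    """Genomic inflation factor: median chi^2 over the null median (0.4549)."""
    return float(np.median(chi2) / MEDIAN_CHI2_1)


def attenuation_ratio(intercept: float, mean_chisq: float) -> float:
    """(intercept - 1) / (mean chi^2 - 1); NaN when mean chi^2 <= 1, mirroring
    the 'Ratio < 0' reporting convention for unattenuated traits."""
    if mean_chisq <= 1.0:
        return float("nan")
    return (intercept - 1.0) / (mean_chisq - 1.0)


def _blocks(m: int, n_blocks: int):
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(edges[b], edges[b + 1]) for b in range(n_blocks)]


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Weighted regression of y on [1, x]; returns full (slope, intercept) and
    the n_blocks delete-one-block coefficient pairs."""
    m = len(x)
    X = np.column_stack([x, np.ones(m)])
    Xw = X * w[:, None]
    A_full = X.T @ Xw
    c_full = Xw.T @ y
    blocks = _blocks(m, n_blocks)
    A_b = np.empty((n_blocks, 2, 2))
    c_b = np.empty((n_blocks, 2))
    for b, (lo, hi) in enumerate(blocks):
        Xb = X[lo:hi]
        Xwb = Xw[lo:hi]
        A_b[b] = Xb.T @ Xwb
        c_b[b] = Xwb.T @ y[lo:hi]
    coef_full = np.linalg.solve(A_full, c_full)
    coef_del = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        coef_del[b] = np.linalg.solve(A_full - A_b[b], c_full - c_b[b])
    return coef_full, coef_del


def _jackknife_se(delete_values: np.ndarray) -> np.ndarray:
    B = delete_values.shape[0]
    mean = delete_values.mean(axis=0)
    return np.sqrt((B - 1) / B * np.sum((delete_values - mean) ** 2, axis=0))


def _align(ss: pd.DataFrame, ld: LdScores):
    if "L2" in ss.columns:
        return ss
    merged = ss.merge(ld.table[["SNP", "L2"]], on="SNP", how="inner", sort=False)
    if merged.empty:
        raise ValueError("no SNPs shared between sumstats and LD scores")
    return merged


def estimate_h2(
    ss: pd.DataFrame,
    ld: LdScores,
    n_blocks: int = 200,
    sample_prev: float | None = None,
    pop_prev: float | None = None,
) -> LdscFit:
    """Univariate LD-score regression of chi^2 on LD score.

    The regressor is N * l / M so the slope is h2 on the observed scale; the
    intercept is free. If both prevalences are supplied the liability-scale
    heritability is populated as well.
    """
    merged = _align(ss, ld)
    m = len(merged)
    if m < 200:
        raise ValueError(f"need >= 200 SNPs for LD-score regression, got {m}")
    if m < n_blocks:
        raise ValueError(f"fewer SNPs ({m}) than jackknife blocks ({n_blocks})")
    z = np.asarray(merged["Z"], dtype=float)
    ok = np.isfinite(z)
    merged, z = merged[ok], z[ok]
    m = len(merged)
    chi2 = z**2
    ell = np.clip(np.asarray(merged["L2"], dtype=float), 1.0, None)
    N = np.asarray(merged["N"], dtype=float)
    x = N * ell / m

    coef0 = np.linalg.lstsq(np.column_stack([x, np.ones(m)]), chi2, rcond=None)[0]
    h2_0 = float(np.clip(coef0[0], 0.0, 1.0))
    icpt0 = float(np.clip(coef0[1], 0.1, 2.0))
    het = icpt0 + h2_0 * N * ell / m
    w = 1.0 / (ell * het**2)
    coef, coef_del = _wls_jackknife(x, chi2, w, n_blocks)
    se = _jackknife_se(coef_del)
    h2_obs, intercept = float(coef[0]), float(coef[1])
    mean_chisq = float(chi2.mean())
    fit = LdscFit(
        h2_obs=h2_obs,
        h2_se=float(se[0]),
        intercept=intercept,
        intercept_se=float(se[1]),
        mean_chisq=mean_chisq,
        lambda_gc=lambda_gc(chi2),
        attenuation_ratio=attenuation_ratio(intercept, mean_chisq),
        n_blocks=n_blocks,
        m_snps=m,
        n_bar=float(N.mean()),
        delete_values=coef_del,
        w_slope0=h2_0,
        w_icpt0=icpt0,
    )
    if sample_prev is not None and pop_prev is not None:
        fit.h2_liab = observed_to_liability(h2_obs, sample_prev, pop_prev)
    return fit


def observed_to_liability(h2_obs: float, sample_prev: float, pop_prev: float) -> float:
    """Observed-scale to liability-scale heritability.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) * phi(Phi^-1(1-K))^2), where P
    is the sample and K the population prevalence.
    """
    P, K = float(sample_prev), float(pop_prev)
    if not (0.0 < P < 1.0 and 0.0 < K < 1.0):
        raise ValueError("prevalences must lie in (0, 1)")
    z = norm.isf(K)
    mult = K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * norm.pdf(z) ** 2)
    return h2_obs * mult


def _cross_regression(merged1, merged2, ell, m, fit1: LdscFit, fit2: LdscFit, n_blocks):
    """Weights use the same clipped step-1 plug-ins as the univariate fits,
    so rg of a study with itself is exactly 1 (the cross weights reduce to
    twice the univariate weights)."""
    z1 = np.asarray(merged1["Z"], dtype=float)
    z2 = np.asarray(merged2["Z"], dtype=float)
    N1 = np.asarray(merged1["N"], dtype=float)
    N2 = np.asarray(merged2["N"], dtype=float)
    y = z1 * z2
    x = np.sqrt(N1 * N2) * ell / m

    coef0 = np.linalg.lstsq(np.column_stack([x, np.ones(m)]), y, rcond=None)[0]
    gencov0 = float(np.clip(coef0[0], -1.0, 1.0))
    icept0 = float(np.clip(coef0[1], -2.0, 2.0))
    a1 = fit1.w_icpt0 + fit1.w_slope0 * N1 * ell / m
    a2 = fit2.w_icpt0 + fit2.w_slope0 * N2 * ell / m
    c = gencov0 * x + icept0
    w = 1.0 / (ell * (a1 * a2 + c**2))
    return _wls_jackknife(x, y, w, n_blocks)


def estimate_rg(
    ss1: pd.DataFrame, ss2: pd.DataFrame, ld: LdScores, n_blocks: int = 200
) -> RgFit:
    """Cross-trait LD-score regression: rg = gencov / sqrt(h2_1 h2_2).

    Estimates beyond +-1 are reported as-is with ``out_of_bounds`` set; an
    undefined rg (either h2 <= 0) is flagged, not raised. The cross-trait
    intercept reflects phenotypic correlation under sample overlap.
    """
    m1 = _align(ss1, ld)
    m2 = _align(ss2, ld)
    common = m1.merge(m2[["SNP"]], on="SNP", how="inner", sort=False)["SNP"]
    if len(common) < 200:
        raise ValueError(f"need >= 200 shared SNPs, got {len(common)}")
    m1 = m1.set_index("SNP").loc[common].reset_index()
    m2 = m2.set_index("SNP").loc[common].reset_index()
    m = len(common)
    ell = np.clip(np.asarray(m1["L2"], dtype=float), 1.0, None)

    f1 = estimate_h2(m1, ld, n_blocks=n_blocks)
    f2 = estimate_h2(m2, ld, n_blocks=n_blocks)
    coef, coef_del = _cross_regression(m1, m2, ell, m, f1, f2, n_blocks)
    gencov, icept = float(coef[0]), float(coef[1])
    se = _jackknife_se(coef_del)

    undefined = f1.h2_obs <= 0 or f2.h2_obs <= 0
    if undefined:
        rg = float("nan")
        rg_se = float("nan")
    else:
        rg = gencov / np.sqrt(f1.h2_obs * f2.h2_obs)
        h2_del_1 = f1.delete_values[:, 0]
        h2_del_2 = f2.delete_values[:, 0]
        with np.errstate(invalid="ignore"):
            rg_del = coef_del[:, 0] / np.sqrt(np.clip(h2_del_1 * h2_del_2, 1e-12, None))
        rg_se = float(_jackknife_se(rg_del[:, None])[0])
    return RgFit(
        rg=float(rg),
        rg_se=rg_se,
        gencov=gencov,
        gencov_se=float(se[0]),
        cross_trait_intercept=icept,
        cross_trait_intercept_se=float(se[1]),
        h2_1=f1.h2_obs,
        h2_2=f2.h2_obs,
        out_of_bounds=bool(np.isfinite(rg) and abs(rg) > 1.0),
        undefined=undefined,
        n_blocks=n_blocks,
    )


def genetic_cov_matrix(
    studies: list[pd.DataFrame],
    ld: LdScores,
    traits: list[str] | None = None,
    n_blocks: int = 200,
) -> GeneticCov:
    """Multivariable LDSC: genetic covariance matrix S with block-jackknife
    sampling covariance V of its half-vectorization.

    All traits are aligned to the shared SNP set and a single block partition
    so the jackknife captures the cross-element sampling covariance. The
    half-vec order is the row-major lower triangle including the diagonal:
    (0,0), (1,0), (1,1), (2,0), ...
    """
    k = len(studies)
    if k < 2:
        raise ValueError("need at least 2 traits")
    names = list(traits) if traits else [f"T{i+1}" for i in range(k)]
    aligned = [_align(s, ld) for s in studies]
    shared = aligned[0]["SNP"]
    for a in aligned[1:]:
        shared = shared[shared.isin(set(a["SNP"]))]
    shared = list(shared)
    if len(shared) < 200:
        raise ValueError(f"need >= 200 shared SNPs across all traits, got {len(shared)}")
    aligned = [a.set_index("SNP").loc[shared].reset_index() for a in aligned]
    m = len(shared)
    ell = np.clip(np.asarray(aligned[0]["L2"], dtype=float), 1.0, None)

    uni = [estimate_h2(a, ld, n_blocks=n_blocks) for a in aligned]
    pairs = half_vec_index(k)
    n_el = len(pairs)
    S = np.zeros((k, k))
    intercepts = np.eye(k)
    delete_mat = np.empty((n_blocks, n_el))
    for e, (i, j) in enumerate(pairs):
        if i == j:
            S[i, i] = uni[i].h2_obs
            intercepts[i, i] = uni[i].intercept
            delete_mat[:, e] = uni[i].delete_values[:, 0]
        else:
            coef, coef_del = _cross_regression(
                aligned[i], aligned[j], ell, m, uni[i], uni[j], n_blocks
            )
            S[i, j] = S[j, i] = float(coef[0])
            intercepts[i, j] = intercepts[j, i] = float(coef[1])
            delete_mat[:, e] = coef_del[:, 0]

    B = n_blocks
    centered = delete_mat - delete_mat.mean(axis=0)
    V = (B - 1) / B * (centered.T @ centered)

    smoothed = False
    w = np.linalg.eigvalsh(0.5 * (V + V.T))
    if w.min() < 0:
        ww, Q = np.linalg.eigh(0.5 * (V + V.T))
        V = (Q * np.clip(ww, 0.0, None)) @ Q.T
        smoothed = True
    sw = np.linalg.eigvalsh(0.5 * (S + S.T))
    if sw.min() < 1e-8:
        smoothed = True  # rank-deficient S flagged; left untouched for the user
    return GeneticCov(
        S=S,
        V=V,
        traits=names,
        intercepts=intercepts,
        smoothed=smoothed,
        n_blocks=n_blocks,
        m_snps=m,
        n_bar=np.array([f.n_bar for f in uni]),
    )


def standardized_cov(gcov: GeneticCov, diag_floor: float = 1e-4):
    """Standardize S to a genetic correlation matrix and rescale V to match.

    Off-diagonal sampling variances are rescaled by 1/(S_ii S_jj) (delta
    method ignoring the sampling error of the diagonal — documented
    approximation). A non-positive heritability estimate on the diagonal is
    floored at ``diag_floor`` with a warning: the trait then contributes
    essentially nothing downstream (its standardized rows blow up in
    variance) instead of poisoning the matrix with NaNs. Returns
    (R_g, V_std).
    """
    import warnings

    diag = np.diag(gcov.S).copy()
    if np.any(diag < diag_floor):
        bad = [gcov.traits[i] for i in np.where(diag < diag_floor)[0]]
        warnings.warn(
            f"non-positive h2 estimate for {bad}; diagonal floored at {diag_floor}"
        )
        diag = np.clip(diag, diag_floor, None)
    d = np.sqrt(diag)
    R = gcov.S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    pairs = half_vec_index(len(gcov.traits))
    scale = np.array([1.0 / (d[i] * d[j]) for i, j in pairs])
    V_std = gcov.V * np.outer(scale, scale)
    return R, V_std


def write_genetic_cov(gcov: GeneticCov, s_path, v_path) -> None:
    pd.DataFrame(gcov.S, index=gcov.traits, columns=gcov.traits).to_csv(s_path)
    pairs = half_vec_index(len(gcov.traits))
    labels = [f"{gcov.traits[i]}:{gcov.traits[j]}" for i, j in pairs]
    pd.DataFrame(gcov.V, index=labels, columns=labels).to_csv(v_path)


def read_genetic_cov(s_path, v_path, n_blocks: int = 0) -> GeneticCov:
    Sdf = pd.read_csv(s_path, index_col=0)
    Vdf = pd.read_csv(v_path, index_col=0)
    traits = list(Sdf.columns)
    k = len(traits)
    return GeneticCov(
        S=Sdf.to_numpy(),
        V=Vdf.to_numpy(),
        traits=traits,
        intercepts=np.eye(k),
        smoothed=False,
        n_blocks=n_blocks,
        m_snps=0,
        n_bar=np.full(k, np.nan),
    )
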