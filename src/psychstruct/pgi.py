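"""Polygenic indices: shrinkage weighting, scoring, residualization, and
latent-factor prediction.

Weights are blockwise-ridge shrunk marginal effects: within each LD block,
w = (R + lambda I)^-1 b with R the block LD correlation matrix and b the
standardized marginal effects (Z / sqrt(N)). This is a deterministic
stand-in filling the role of Bayesian shrinkage estimators in summary-
statistic PGI pipelines. Scores are allele-dosage weighted sums, with an
optional exclusion of the major histocompatibility complex region.

Latent-factor prediction fixes the measurement loadings at a previously
fitted solution and regresses each latent factor on the (residualized)
PGIs through the moment structure: the polyserial correlations between a
PGI and the binary indicators identify the PGI -> factor paths by
generalized least squares, and R^2 per factor is the explained latent
variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .factor_models import CfaFit
from .synth import Cohort

__all__ = [
    "PgiWeights",
    "PgiPrediction",
    "MhcRegion",
    "align_blocks",
    "shrink_weights",
    "score",
    "residualize",
    "polyserial_corr",
    "predict_latent",
    "incremental_r2",
    "outcome_assoc",
    "ld_block_matrices",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MhcRegion:
    """Coordinate interval excluded from scoring when flagged (simulated
    coordinate system)."""

    chromosome: int = 6
    start: int = 26_000_000
    end: int = 34_000_000


@dataclass
class PgiWeights:
    table: pd.DataFrame  # SNP, A1, WEIGHT
    source_factor: str
    lambda_shrink: float
    mhc_excluded: bool = False


@dataclass
class PgiPrediction:
    r2_per_factor: dict
    gamma: pd.DataFrame  # PGI x factor paths
    factor_names: list[str]


def ld_block_matrices(cohort: Cohort):
    """Block LD correlation matrices of the cohort, as (index array, R) pairs."""
    B = cohort.ld_block_size
    X = cohort.dosages.astype(np.float64)
    out = []
    for start in range(0, cohort.n_snps, B):
        idx = np.arange(start, min(start + B, cohort.n_snps))
        Xb = X[:, idx]
        Xb = Xb - Xb.mean(axis=0)
        sd = Xb.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xb = Xb / sd
        out.append((idx, (Xb.T @ Xb) / len(Xb)))
    return out


def write_weights(weights: PgiWeights, path) -> None:
    weights.table.to_csv(path, sep="\t", index=False)


def read_weights(path, source_factor: str = "", lambda_shrink: float = 0.0) -> PgiWeights:
    return PgiWeights(
        table=pd.read_csv(path, sep="\t"),
        source_factor=source_factor,
        lambda_shrink=lambda_shrink,
    )


def write_scores(scores: np.ndarray, ids, path) -> None:
    pd.DataFrame({"IID": ids, "SCORE": scores}).to_csv(path, sep="\t", index=False)


def align_blocks(ss: pd.DataFrame, cohort: Cohort, blocks=None):
    """Restrict cohort LD blocks to the SNPs present in a sumstats table,
    re-indexed to the table's row order (the alignment shrink_weights
    expects)."""
    if blocks is None:
        blocks = ld_block_matrices(cohort)
    snp_order = {s: i for i, s in enumerate(cohort.snp_ids)}
    present = {snp_order[s]: r for r, s in enumerate(ss["SNP"]) if s in snp_order}
    out = []
    for idx, R in blocks:
        keep = [j for j, g in enumerate(idx) if g in present]
        if not keep:
            continue
        rows = np.array([present[idx[j]] for j in keep])
        out.append((rows, R[np.ix_(keep, keep)]))
    return out


def shrink_weights(
    ss: pd.DataFrame,
    ld_blocks,
    lambda_shrink: float = 0.1,
    source_factor: str = "",
) -> PgiWeights:
    """Blockwise ridge: w = (R_block + lambda I)^-1 b, b = Z / sqrt(N).

    ``ld_blocks`` is a list of (snp index array, correlation matrix) pairs
    aligned to the row order of ``ss``. A numerically singular block is
    re-solved with an inflated ridge and a warning.
    """
    z = ss["Z"].to_numpy(dtype=float)
    n = ss["N"].to_numpy(dtype=float)
    b = z / np.sqrt(n)
    w = np.zeros_like(b)
    for idx, R in ld_blocks:
        lam = lambda_shrink
        A = R + lam * np.eye(len(idx))
        for _ in range(6):
            try:
                sol = np.linalg.solve(A, b[idx])
                if np.all(np.isfinite(sol)):
                    break
            except np.linalg.LinAlgError:
                pass
            lam = max(lam * 10.0, 1e-4)
            warnings.warn(
                f"singular LD block; ridge increased to lambda={lam:g}"
            )
            A = R + lam * np.eye(len(idx))
        w[idx] = sol
    table = pd.DataFrame({"SNP": ss["SNP"].to_numpy(), "A1": ss["A1"].to_numpy(), "WEIGHT": w})
    return PgiWeights(table=table, source_factor=source_factor, lambda_shrink=lambda_shrink)


def score(
    cohort: Cohort,
    weights: PgiWeights,
    exclude_mhc: bool = False,
    mhc_region: MhcRegion = MhcRegion(),
) -> np.ndarray:
    """Per-individual score: sum of weight x allele dosage over matched SNPs."""
    pos = {s: j for j, s in enumerate(cohort.snp_ids)}
    matched = weights.table["SNP"].map(pos)
    ok = matched.notna()
    if ok.sum() < 0.5 * len(weights.table):
        raise ValueError(
            f"only {int(ok.sum())}/{len(weights.table)} weight SNPs matched the cohort"
        )
    idx = matched[ok].to_numpy(dtype=int)
    w = weights.table.loc[ok, "WEIGHT"].to_numpy(dtype=float)
    if exclude_mhc:
        in_mhc = (
            (cohort.chromosomes[idx] == mhc_region.chromosome)
            & (cohort.positions[idx] >= mhc_region.start)
            & (cohort.positions[idx] <= mhc_region.end)
        )
        w = np.where(in_mhc, 0.0, w)
        weights.mhc_excluded = True
    return cohort.dosages[:, idx].astype(np.float64) @ w


def residualize(scores: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of the scores on the covariates (with intercept),
    re-standardized to mean 0, SD 1."""
    y = np.asarray(scores, dtype=float)
    C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ beta
    sd = resid.std()
    if sd == 0:
        return resid
    return (resid - resid.mean()) / sd


def polyserial_corr(x: np.ndarray, y_binary: np.ndarray) -> float:
    """Two-step polyserial correlation between a continuous score and a
    binary indicator: r_ps = r_pearson * sqrt(p(1-p)) / phi(tau)."""
    y = np.asarray(y_binary, dtype=float)
    p = y.mean()
    if p <= 0 or p >= 1:
        raise ValueError("binary indicator must have both classes")
    tau = norm.isf(p)
    r_pb = np.corrcoef(np.asarray(x, dtype=float), y)[0, 1]
    r = r_pb * np.sqrt(p * (1 - p)) / norm.pdf(tau)
    return float(np.clip(r, -0.999, 0.999))


def _measurement(fit: CfaFit):
    L = fit.loadings.to_numpy()
    names = list(fit.loadings.index)
    factors = list(fit.loadings.columns)
    return L, names, factors


def predict_latent(
    scores: dict,
    diagnoses: np.ndarray,
    fit: CfaFit,
    condition_names: list[str],
) -> PgiPrediction:
    """Latent-factor prediction R^2 with fixed measurement loadings.

    ``scores`` maps PGI names to per-individual (residualized) score
    vectors. Each factor is regressed on all supplied PGIs jointly through
    the moment conditions cov(PGI_m, ind_i) = sum_f lambda_if (C gamma_f)_m
    with C the PGI correlation matrix; R^2 per factor is gamma_f' C gamma_f.
    """
    L, names, factors = _measurement(fit)
    order = [condition_names.index(nm) for nm in names]
    Y = np.asarray(diagnoses, dtype=float)[:, order]
    pgi_names = list(scores)
    S = np.column_stack([np.asarray(scores[p], dtype=float) for p in pgi_names])
    S = (S - S.mean(axis=0)) / S.std(axis=0)
    n_pgi = S.shape[1]
    k = len(names)
    nf = len(factors)
    C = np.corrcoef(S, rowvar=False) if n_pgi > 1 else np.ones((1, 1))

    # moment vector: polyserial corr of each PGI with each indicator
    s_mom = np.empty((n_pgi, k))
    for m in range(n_pgi):
        for i in range(k):
            s_mom[m, i] = polyserial_corr(S[:, m], Y[:, i])

    # design: s[m, i] = sum_f L[i, f] * (C @ gamma[:, f])[m]; solve for gamma
    # as a least-squares problem in the stacked (m, i) moments
    A = np.zeros((n_pgi * k, n_pgi * nf))
    for m in range(n_pgi):
        for i in range(k):
            row = m * k + i
            for f in range(nf):
                for m2 in range(n_pgi):
                    A[row, m2 * nf + f] += L[i, f] * C[m, m2]
    gamma_vec, *_ = np.linalg.lstsq(A, s_mom.reshape(-1), rcond=None)
    gamma = gamma_vec.reshape(n_pgi, nf)
    r2 = {}
    for f, fac in enumerate(factors):
        g = gamma[:, f]
        r2[fac] = float(np.clip(g @ C @ g, 0.0, 1.0))
    return PgiPrediction(
        r2_per_factor=r2,
        gamma=pd.DataFrame(gamma, index=pgi_names, columns=factors),
        factor_names=factors,
    )


def incremental_r2(
    domain_scores: dict,
    p_score: np.ndarray,
    diagnoses: np.ndarray,
    fit: CfaFit,
    condition_names: list[str],
    outcome_factor: str,
) -> float:
    """Delta R^2 for a factor: joint domain-PGI prediction minus the
    general-factor PGI prediction."""
    joint = predict_latent(domain_scores, diagnoses, fit, condition_names)
    solo = predict_latent({"p": p_score}, diagnoses, fit, condition_names)
    return joint.r2_per_factor[outcome_factor] - solo.r2_per_factor[outcome_factor]


def outcome_assoc(
    scores: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray | None = None,
    sex: np.ndarray | None = None,
) -> tuple[float, float]:
    """Standardized PGI effect on a continuous outcome, adjusting for the
    demographic template age, sex, age^2, sex x age, sex x age^2."""
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    y = (y - y.mean()) / y.std()
    x = np.asarray(scores, dtype=float)
    x = (x - x.mean()) / x.std()
    cols = [x]
    names = ["PGI"]
    if age is not None:
        a = np.asarray(age, dtype=float)
        a = (a - a.mean()) / a.std()
        cols += [a, a**2]
        names += ["age", "age2"]
        if sex is not None:
            s = np.asarray(sex, dtype=float)
            cols += [s, s * a, s * a**2]
            names += ["sex", "sex_age", "sex_age2"]
    elif sex is not None:
        cols += [np.asarray(sex, dtype=float)]
        names += ["sex"]
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("regression design is rank deficient")
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])
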