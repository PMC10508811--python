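"""Tetrachoric correlations and the phenotypic correlation matrix.

The tetrachoric correlation treats a 2x2 table of binary outcomes as a
dichotomization of a bivariate normal liability: thresholds are fixed at the
normal quantiles of the margins (two-step estimation) and the correlation is
the value maximizing the multinomial likelihood of the four cells. Standard
errors come from the observed information at the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._utils import bvn_cdf, nearest_pd_corr

__all__ = ["TetraFit", "PhenoCorrMatrix", "tetrachoric", "corr_matrix"]

R_CAP = 0.999


@dataclass
class TetraFit:
    r: float
    se: float
    tau1: float
    tau2: float
    n_pairs: int
    capped: bool = False
    continuity_corrected: bool = False


@dataclass
class PhenoCorrMatrix:
    R_p: np.ndarray
    se_matrix: np.ndarray
    n_matrix: np.ndarray
    condition_names: list[str]
    smoothed: bool = False


def _cell_probs(tau1: float, tau2: float, r) -> np.ndarray:
    """P of cells [[00, 01], [10, 11]] for X = 1[L1 > tau1], Y = 1[L2 > tau2]."""
    r = np.asarray(r, dtype=float)
    c = bvn_cdf(tau1, tau2, r)  # P(L1 <= tau1, L2 <= tau2) = P00
    p0x = norm.cdf(tau1)
    px0 = norm.cdf(tau2)
    p00 = np.asarray(c)
    p01 = p0x - p00
    p10 = px0 - p00
    p11 = 1.0 - p0x - px0 + p00
    out = np.stack([p00, p01, p10, p11], axis=-1)
    return np.clip(out, 1e-300, 1.0)


def tetrachoric(table) -> TetraFit:
    """ML tetrachoric correlation of a 2x2 count table.

    ``table[i][j]`` counts observations with X = i, Y = j (0 = below
    threshold). Zero cells get a 0.5 continuity correction (flagged); a zero
    margin is an error because the threshold is undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x2 count array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: tetrachoric correlation undefined")
    corrected = False
    if np.any(t == 0):
        t = t + 0.5
        corrected = True
    n = t.sum()
    p_x1 = t[1].sum() / n
    p_y1 = t[:, 1].sum() / n
    tau1 = norm.isf(p_x1)
    tau2 = norm.isf(p_y1)
    counts = t.reshape(-1)

    def nll(r):
        return -float(counts @ np.log(_cell_probs(tau1, tau2, r)))

    res = minimize_scalar(nll, bounds=(-R_CAP, R_CAP), method="bounded",
                          options={"xatol": 1e-7})
    r_hat = float(res.x)
    capped = abs(r_hat) >= R_CAP - 1e-6
    if capped:
        r_hat = float(np.sign(r_hat) * R_CAP)

    # observed information by central second difference of the nll
    h = 1e-4
    lo = max(-R_CAP, r_hat - h)
    hi = min(R_CAP, r_hat + h)
    d2 = (nll(hi) - 2.0 * nll(r_hat) + nll(lo)) / ((0.5 * (hi - lo)) ** 2)
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    return TetraFit(
        r=r_hat,
        se=se,
        tau1=float(tau1),
        tau2=float(tau2),
        n_pairs=int(round(n - (2.0 if corrected else 0.0))),
        capped=capped,
        continuity_corrected=corrected,
    )


def corr_matrix(diagnoses, condition_names: list[str] | None = None) -> PhenoCorrMatrix:
    """Pairwise-complete tetrachoric correlation matrix.

    ``diagnoses`` is an individuals x conditions array of {0, 1, NaN}. Each
    pair uses its complete observations (pairwise deletion). A pair whose
    complete subset leaves a condition with fewer than 2 cases (or controls)
    is set missing and completed by nearest-PD smoothing with a warning.
    Smoothing by eigenvalue clipping is also applied whenever the assembled
    matrix is not PD; the flag records whether anything changed.
    """
    X = np.asarray(diagnoses, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    names = list(condition_names) if condition_names else [f"C{i+1}" for i in range(k)]

    R = np.eye(k)
    SE = np.zeros((k, k))
    N = np.zeros((k, k), dtype=np.int64)
    np.fill_diagonal(N, np.sum(~np.isnan(X), axis=0))
    missing_pairs = []
    for i in range(k):
        for j in range(i):
            mask = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            xi = X[mask, i].astype(np.int64)
            xj = X[mask, j].astype(np.int64)
            N[i, j] = N[j, i] = mask.sum()
            counts = np.zeros((2, 2))
            np.add.at(counts, (xi, xj), 1.0)
            cases_ok = (
                counts[1].sum() >= 2 and counts[0].sum() >= 2
                and counts[:, 1].sum() >= 2 and counts[:, 0].sum() >= 2
            )
            if not cases_ok:
                missing_pairs.append((names[i], names[j]))
                R[i, j] = R[j, i] = np.nan
                SE[i, j] = SE[j, i] = np.nan
                continue
            fit = tetrachoric(counts)
            R[i, j] = R[j, i] = fit.r
            SE[i, j] = SE[j, i] = fit.se

    smoothed = False
    if missing_pairs:
        warnings.warn(
            f"{len(missing_pairs)} pair(s) had too few cases for a tetrachoric "
            f"estimate and were completed by smoothing: {missing_pairs}"
        )
        R = np.where(np.isnan(R), 0.0, R)
        smoothed = True
    R_s, changed = nearest_pd_corr(R)
    smoothed = smoothed or changed
    return PhenoCorrMatrix(
        R_p=R_s, se_matrix=SE, n_matrix=N, condition_names=names, smoothed=smoothed
    )
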