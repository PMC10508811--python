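"""Cross-level disparity between phenotypic and genetic correlations.

The disparity D = r_p - r_g quantifies, pair by pair, how much the
phenotypic correlation of two conditions departs from their genetic
correlation (positive when the phenotypic relationship is the stronger
one). Per-condition permutation tests ask whether a condition's disparities
track a technical covariate (e.g. GWAS effective N) beyond chance: the
covariate vector is shuffled in each permutation and the observed Pearson
correlation is referred to the resulting null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import lower_tri_pairs

__all__ = [
    "DisparityResult",
    "PermTestResult",
    "disparity",
    "perm_test",
    "tech_correlations",
    "matrix_correlation",
]


@dataclass
class DisparityResult:
    D: np.ndarray
    condition_names: list[str]
    per_condition_mean: np.ndarray
    overall_mean_abs: float
    range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.condition_names, columns=self.condition_names)


@dataclass
class PermTestResult:
    observed_r: np.ndarray  # per condition
    empirical_p: np.ndarray
    condition_names: list[str]
    n_perm: int
    seed: int
    statistic: str  # "signed" or "absolute"


def disparity(Rp: np.ndarray, Rg: np.ndarray, condition_names: list[str] | None = None,
              names_p: list[str] | None = None, names_g: list[str] | None = None) -> DisparityResult:
    """Elementwise D = r_p - r_g with per-condition and overall summaries."""
    Rp = np.asarray(Rp, dtype=float)
    Rg = np.asarray(Rg, dtype=float)
    if Rp.shape != Rg.shape:
        raise ValueError("matrices must have the same dimension")
    if names_p is not None and names_g is not None and list(names_p) != list(names_g):
        mismatches = [
            (a, b) for a, b in zip(names_p, names_g) if a != b
        ] + [(a, None) for a in names_p[len(names_g):]] + [(None, b) for b in names_g[len(names_p):]]
        raise ValueError(f"condition label mismatch between levels: {mismatches}")
    k = Rp.shape[0]
    names = list(condition_names or names_p or [f"C{i+1}" for i in range(k)])
    D = Rp - Rg
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    off = ~np.eye(k, dtype=bool)
    per_cond = np.array([D[i, off[i]].mean() for i in range(k)])
    return DisparityResult(
        D=D,
        condition_names=names,
        per_condition_mean=per_cond,
        overall_mean_abs=float(np.abs(D[off]).mean()),
        range=(float(D[off].min()), float(D[off].max())),
    )


def perm_test(
    D: DisparityResult,
    covariate: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "signed",
) -> PermTestResult:
    """Per-condition permutation test of D rows against a per-condition
    covariate.

    For condition i the observed statistic is the Pearson correlation
    between its off-diagonal D row (signed by default, |D| optionally) and
    the covariate values of its partner conditions. Each permutation
    shuffles the covariate vector; the two-sided empirical p-value is
    (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1).
    """
    cov = np.asarray(covariate, dtype=float)
    k = len(D.condition_names)
    if cov.shape != (k,):
        raise ValueError("covariate must align with the conditions")
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate: correlation undefined")
    if statistic not in ("signed", "absolute"):
        raise ValueError("statistic must be 'signed' or 'absolute'")
    rng = np.random.default_rng(seed)
    # one set of covariate shuffles shared across conditions, mirroring a
    # single pass of "shuffle the vector, correlate with each row"
    perms = np.stack([rng.permutation(cov) for _ in range(n_perm)])
    obs_r = np.empty(k)
    emp_p = np.empty(k)
    for i in range(k):
        partners = [j for j in range(k) if j != i]
        d_row = D.D[i, partners]
        if statistic == "absolute":
            d_row = np.abs(d_row)
        if np.ptp(d_row) == 0:
            obs_r[i] = np.nan
            emp_p[i] = np.nan
            continue
        d_c = d_row - d_row.mean()
        d_norm = np.sqrt(np.sum(d_c**2))

        def _corr_with(xs):
            xc = xs - xs.mean(axis=-1, keepdims=True)
            denom = d_norm * np.sqrt(np.sum(xc**2, axis=-1))
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(denom > 0, (xc @ d_c) / denom, 1.0)

        r_obs = float(_corr_with(cov[partners][None, :])[0])
        r_null = _corr_with(perms[:, partners])
        count = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-15))
        obs_r[i] = r_obs
        emp_p[i] = (1 + count) / (n_perm + 1)
    return PermTestResult(
        observed_r=obs_r,
        empirical_p=emp_p,
        condition_names=list(D.condition_names),
        n_perm=n_perm,
        seed=seed,
        statistic=statistic,
    )


def tech_correlations(D: DisparityResult, rg_se_matrix: np.ndarray) -> float:
    """Pearson correlation between |D| and the genetic-correlation SEs over
    the unique off-diagonal pairs."""
    SE = np.asarray(rg_se_matrix, dtype=float)
    if SE.shape != D.D.shape:
        raise ValueError("SE matrix must match the disparity matrix dimension")
    pairs = lower_tri_pairs(D.D.shape[0])
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    d = np.array([abs(D.D[i, j]) for i, j in pairs])
    s = np.array([SE[i, j] for i, j in pairs])
    return float(np.corrcoef(d, s)[0, 1])


def matrix_correlation(Rp: np.ndarray, Rg: np.ndarray) -> float:
    """Pearson correlation between the two matrices over unique off-diagonal
    pairs (the matrix-level similarity of the two levels)."""
    Rp = np.asarray(Rp, dtype=float)
    Rg = np.asarray(Rg, dtype=float)
    pairs = lower_tri_pairs(Rp.shape[0])
    a = np.array([Rp[i, j] for i, j in pairs])
    b = np.array([Rg[i, j] for i, j in pairs])
    return float(np.corrcoef(a, b)[0, 1])
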