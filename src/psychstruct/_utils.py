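"""Shared numerical utilities: seed derivation, bivariate-normal CDF, matrix helpers."""

from __future__ import annotations

import hashlib

import numpy as np
from scipy.special import ndtr, owens_t


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stable per-stage seed from a master seed and a stage label.

    Uses blake2b so that stages are independently reproducible and the
    derived seed never exceeds 2**31 - 1.
    """
    h = hashlib.blake2b(f"{int(master_seed)}:{label}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Owen's-T based (Owen 1956), vectorized over any broadcastable arguments.
    Accurate to ~1e-14 away from |rho| = 1; the |rho| -> 1 limits are handled
    explicitly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    hi = np.clip(rho, -1.0, 1.0)
    near_one = hi >= 1.0 - 1e-12
    near_mone = hi <= -1.0 + 1e-12
    regular = ~(near_one | near_mone)

    if np.any(near_one):
        out[near_one] = ndtr(np.minimum(h[near_one], k[near_one]))
    if np.any(near_mone):
        out[near_mone] = np.maximum(
            0.0, ndtr(h[near_mone]) + ndtr(k[near_mone]) - 1.0
        )
    if np.any(regular):
        hh, kk, rr = h[regular], k[regular], rho[regular]
        out[regular] = _bvn_cdf_owen(hh, kk, rr)
    if out.ndim == 0:
        return float(out)
    return out


def _bvn_cdf_owen(h, k, rho):
    # snap sub-epsilon arguments to exactly zero so the h == 0 / k == 0
    # special cases catch denormals instead of overflowing (k - rho h)/(h s)
    h = np.where(np.abs(h) < 1e-12, 0.0, h)
    k = np.where(np.abs(k) < 1e-12, 0.0, k)
    s = np.sqrt(1.0 - rho * rho)
    # a_h = (k - rho h) / (h s); guard h == 0 (and k == 0) separately.
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (k - rho * h) / (h * s)
        ak = (h - rho * k) / (k * s)
    t_h = np.where(h != 0.0, owens_t(h, np.where(h != 0.0, ah, 0.0)), 0.0)
    t_k = np.where(k != 0.0, owens_t(k, np.where(k != 0.0, ak, 0.0)), 0.0)

    # h == 0 (k != 0): a = (k - rho h)/(h s) -> sign(k) * inf, and
    # T(0, +-inf) = +-1/4 via arctan
    zh = (h == 0.0) & (k != 0.0)
    if np.any(zh):
        a = np.sign(k[zh]) * np.inf
        t_h = t_h.copy()
        t_h[zh] = np.arctan(a) / (2.0 * np.pi)
    zk = (k == 0.0) & (h != 0.0)
    if np.any(zk):
        a = np.sign(h[zk]) * np.inf
        t_k = t_k.copy()
        t_k[zk] = np.arctan(a) / (2.0 * np.pi)

    hk = h * k
    delta = np.where(
        (hk > 0.0) | ((hk == 0.0) & (h + k >= 0.0)), 0.0, 0.5
    )
    out = 0.5 * (ndtr(h) + ndtr(k)) - t_h - t_k - delta

    # h == k == 0: closed form 1/4 + arcsin(rho) / (2 pi)
    zz = (h == 0.0) & (k == 0.0)
    if np.any(zz):
        out = np.where(zz, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    return np.clip(out, 0.0, 1.0)


def cov2corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def nearest_pd_corr(R: np.ndarray, eig_floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped nearest positive-definite correlation matrix.

    Returns (smoothed matrix, changed flag). Entries are renormalized to a
    unit diagonal after clipping.
    """
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() >= eig_floor:
        out = R.copy()
        np.fill_diagonal(out, 1.0)
        return out, False
    w_clipped = np.clip(w, eig_floor, None)
    S = (V * w_clipped) @ V.T
    out = cov2corr(S)
    return out, True


def is_pd(M: np.ndarray, tol: float = 0.0) -> bool:
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    return bool(w.min() > tol)


def lower_tri_pairs(k: int):
    """(i, j) with i > j, row-major: (1,0), (2,0), (2,1), ..."""
    return [(i, j) for i in range(k) for j in range(i)]


def half_vec_index(k: int):
    """Row-major lower triangle *including* diagonal: (0,0),(1,0),(1,1),..."""
    return [(i, j) for i in range(k) for j in range(i + 1)]
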