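"""Exploratory and confirmatory factor models on correlation matrices.

EFA is principal-axis factoring with iterated communalities, followed by an
oblique rotation (oblimin via gradient-projection, or promax). Factor
retention combines parallel analysis with the joint dRMSEA < 0.015 /
dR^2 < 0.05 rule. CFA minimizes a diagonally weighted least squares (DWLS)
discrepancy over the unique off-diagonal correlations, with residual
variances derived from the loadings (1 - communality), so the implied
diagonal is exactly 1. Supported shapes: correlated first-order factors, a
single first-order factor, a second-order general factor over the
first-order factors, and a bifactor model (orthogonal general + specifics).

Estimation is always on (co)variance/correlation matrices, never raw binary
data; the genetic and phenotypic levels differ only in where the element
sampling variances come from (block-jackknife V versus tetrachoric
standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from ._utils import lower_tri_pairs, nearest_pd_corr
from .ldsc import GeneticCov, standardized_cov
from .phenocorr import PhenoCorrMatrix

__all__ = [
    "EfaSolution",
    "ModelSpec",
    "CfaFit",
    "parallel_analysis",
    "efa",
    "retain_factors",
    "fit_cfa",
    "cross_level_fit",
    "loading_correlation",
    "efa_to_spec",
]


# ---------------------------------------------------------------------------
# EFA


@dataclass
class EfaSolution:
    loadings: pd.DataFrame  # conditions x factors (pattern matrix)
    factor_corr: np.ndarray
    communalities: np.ndarray
    rmsea: float
    r2_total: float
    rotation: str
    n_factors: int
    chi2: float
    df: int
    converged: bool = True


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations as starting communalities."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def _paf(R: np.ndarray, m: int, tol: float = 1e-6, max_iter: int = 5000):
    """Principal-axis factoring with iterated communalities."""
    k = R.shape[0]
    h = np.clip(_smc(R), 0.0, 0.995)
    last_delta = np.inf
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        w, V = np.linalg.eigh(Rh)
        idx = np.argsort(w)[::-1][:m]
        lam = np.clip(w[idx], 0.0, None)
        L = V[:, idx] * np.sqrt(lam)
        h_new = np.clip(np.sum(L**2, axis=1), 0.0, 0.9999)
        last_delta = float(np.max(np.abs(h_new - h)))
        h = h_new
        if last_delta < tol:
            return L, h
    raise RuntimeError(
        f"principal-axis factoring failed to converge in {max_iter} iterations "
        f"(last communality change {last_delta:.2e})"
    )


def _varimax(L: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    k, m = L.shape
    T = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / k)
        )
        T = u @ vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return T


def _oblimin_criterion(L: np.ndarray, gamma: float):
    k, m = L.shape
    L2 = L**2
    Nm = np.ones((m, m)) - np.eye(m)
    C = np.eye(k) - (gamma / k) * np.ones((k, k))
    inner = C @ L2 @ Nm
    f = np.sum(L2 * inner) / 4.0
    G = L * inner
    return f, G


def _gpf_oblique(A: np.ndarray, gamma: float = 0.0, tol: float = 1e-6, max_iter: int = 1000):
    """Gradient-projection oblique rotation (Jennrich 2002) for the oblimin
    family; gamma = 0 is quartimin. Started from the varimax orientation —
    the identity start can sit on a saddle for symmetric block structures."""
    m = A.shape[1]
    T = _varimax(A)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ls in range(20):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X**2, axis=0))
            Ti_n = np.linalg.inv(X)
            L_n = A @ Ti_n.T
            f_n, Gq_n = _oblimin_criterion(L_n, gamma)
            if f_n < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Ti_n, L_n, f_n, Gq_n
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi


def _promax(A: np.ndarray, kappa: int = 4):
    T_v = _varimax(A)
    X = A @ T_v
    P = X * np.abs(X) ** (kappa - 1)
    U = np.linalg.solve(X.T @ X, X.T @ P)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    L = X @ U
    U_full = T_v @ U
    Phi = np.linalg.inv(U_full.T @ U_full)
    return L, Phi


def _sign_fix(L: np.ndarray, Phi: np.ndarray):
    """Each factor scaled so its largest-|loading| indicator is positive."""
    signs = np.ones(L.shape[1])
    for f in range(L.shape[1]):
        j = int(np.argmax(np.abs(L[:, f])))
        if L[j, f] < 0:
            signs[f] = -1.0
    D = np.diag(signs)
    return L @ D, D @ Phi @ D


def _efa_fit_stats(R: np.ndarray, L: np.ndarray, h: np.ndarray, n: int):
    """ML discrepancy based chi2 / df / RMSEA for an m-factor solution."""
    k, m = L.shape
    Sigma = L @ L.T
    np.fill_diagonal(Sigma, 1.0)
    Sigma, _ = nearest_pd_corr(Sigma, eig_floor=1e-8)
    sign_S, logdet_S = np.linalg.slogdet(Sigma)
    sign_R, logdet_R = np.linalg.slogdet(R)
    F = logdet_S - logdet_R + np.trace(R @ np.linalg.inv(Sigma)) - k
    F = max(F, 0.0)
    df = ((k - m) ** 2 - (k + m)) // 2
    chi2 = (n - 1) * F
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        rmsea = 0.0
    return float(chi2), int(df), rmsea


def parallel_analysis(
    R: np.ndarray,
    n: int,
    reps: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Number of eigenvalues of R exceeding the chosen quantile of
    eigenvalues from uncorrelated normal data of the same dimension."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if n <= k:
        raise ValueError("need n > number of variables")
    rng = np.random.default_rng(seed)
    sim = np.empty((reps, k))
    for r in range(reps):
        X = rng.standard_normal((n, k))
        sim[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    thresh = np.quantile(sim, quantile, axis=0)
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    # leading run: stop at the first eigenvalue that fails its threshold
    count = 0
    for o, t in zip(obs, thresh):
        if o > t:
            count += 1
        else:
            break
    return count


def efa(
    R: np.ndarray,
    n_factors: int,
    rotation: str = "oblimin",
    n: int = 1000,
    names: list[str] | None = None,
) -> EfaSolution:
    """Principal-axis EFA with an oblique rotation.

    ``n`` only enters the RMSEA; loadings depend on R alone. Rotation is
    skipped for a single factor.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if not 1 <= n_factors < k:
        raise ValueError("need 1 <= n_factors < k")
    R_pd, _ = nearest_pd_corr(R)
    names = list(names) if names else [f"C{i+1}" for i in range(k)]
    A, h = _paf(R_pd, n_factors)
    if n_factors == 1:
        L, Phi = A, np.eye(1)
    elif rotation == "oblimin":
        L, Phi = _gpf_oblique(A, gamma=0.0)
    elif rotation == "promax":
        L, Phi = _promax(A, kappa=4)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    L, Phi = _sign_fix(L, Phi)
    # order factors by explained variance for stable output
    order = np.argsort(-np.sum(L**2, axis=0), kind="mergesort")
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    chi2, df, rmsea = _efa_fit_stats(R_pd, A, h, n)
    return EfaSolution(
        loadings=pd.DataFrame(L, index=names, columns=[f"F{j+1}" for j in range(n_factors)]),
        factor_corr=Phi,
        communalities=h,
        rmsea=rmsea,
        r2_total=float(np.sum(h) / k),
        rotation=rotation if n_factors > 1 else "none",
        n_factors=n_factors,
        chi2=chi2,
        df=df,
    )


def retain_factors(R: np.ndarray, n: int, max_k: int, rotation: str = "oblimin") -> int:
    """Smallest m such that the (m+1)-factor solution improves RMSEA by less
    than 0.015 and total R^2 by less than 0.05."""
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    if max_k >= k:
        raise ValueError("max_k must be below the number of conditions")
    sols: list[EfaSolution | None] = []
    for m in range(1, max_k + 2):
        try:
            sols.append(efa(R, m, rotation=rotation, n=n))
        except RuntimeError:
            # a richer model that cannot even be extracted is no improvement
            sols.append(None)
    for m in range(1, max_k + 1):
        cur, nxt = sols[m - 1], sols[m]
        if cur is None:
            return max(m - 1, 1)
        if nxt is None:
            return m
        d_rmsea = cur.rmsea - nxt.rmsea
        d_r2 = nxt.r2_total - cur.r2_total
        if d_rmsea < 0.015 and d_r2 < 0.05:
            return m
    return max_k


def efa_to_spec(sol: EfaSolution, factor_names: list[str] | None = None) -> "ModelSpec":
    """Simple-structure spec: each indicator assigned to its max-|loading|
    factor. A factor left with a single indicator is not identified, so its
    indicator is reassigned to the next-best factor (and the empty factor
    dropped), as an analyst would do before confirmation."""
    L = np.abs(sol.loadings.to_numpy())
    inds = list(sol.loadings.index)
    m = L.shape[1]
    fnames = list(factor_names) if factor_names else [f"F{j+1}" for j in range(m)]
    assign = {i: int(np.argmax(L[i])) for i in range(len(inds))}
    L_rank = np.argsort(-L, axis=1)
    for _ in range(m):
        counts = {f: sum(1 for a in assign.values() if a == f) for f in set(assign.values())}
        singles = [f for f, c in counts.items() if c == 1]
        if not singles or len(counts) == 1:
            break
        f_bad = singles[0]
        i_bad = next(i for i, a in assign.items() if a == f_bad)
        for cand in L_rank[i_bad]:
            if cand != f_bad and counts.get(cand, 0) >= 1:
                assign[i_bad] = int(cand)
                break
    factors: dict[str, list[str]] = {}
    for i, ind in enumerate(inds):
        factors.setdefault(fnames[assign[i]], []).append(ind)
    return ModelSpec(factors=factors)


# ---------------------------------------------------------------------------
# CFA


@dataclass
class ModelSpec:
    """Confirmatory model shape.

    ``factors`` maps factor names to indicator lists (a single factor over
    all indicators is the first-order general-factor model). ``second_order``
    adds a higher-order factor regressed on by every first-order factor;
    ``bifactor`` adds an orthogonal general factor loading on all indicators
    and makes the named factors orthogonal specifics. ``equality_constraints``
    lists groups of (factor, indicator) loading slots held equal; 2-indicator
    specific factors in a bifactor model get this constraint automatically
    (the standard Heywood-case remedy).
    """

    factors: dict[str, list[str]]
    factor_corr_free: bool = True
    second_order: str | None = None
    bifactor: bool = False
    residual_corrs: list[tuple[str, str]] = field(default_factory=list)
    equality_constraints: list[list[tuple[str, str]]] = field(default_factory=list)

    def __post_init__(self):
        if not self.factors:
            raise ValueError("spec needs at least one factor")
        if self.second_order and self.bifactor:
            raise ValueError("choose either a second-order or a bifactor structure")
        if self.second_order and len(self.factors) < 3:
            raise ValueError("a second-order factor needs >= 3 first-order factors")
        constrained = {slot for grp in self.equality_constraints for slot in grp}
        for fac, inds in self.factors.items():
            if len(inds) < 2 and not any(s[0] == fac for s in constrained):
                if len(self.factors) == 1 or not self._indicator_shared(inds):
                    raise ValueError(
                        f"factor {fac!r} has < 2 indicators and no constraint; "
                        "the model is not identified"
                    )

    def _indicator_shared(self, inds):
        counts = {}
        for f, lst in self.factors.items():
            for i in lst:
                counts[i] = counts.get(i, 0) + 1
        return all(counts[i] > 1 for i in inds)

    @property
    def indicators(self) -> list[str]:
        seen: list[str] = []
        for inds in self.factors.values():
            for i in inds:
                if i not in seen:
                    seen.append(i)
        return seen

    def with_residual_corrs(self, extra: list[tuple[str, str]]) -> "ModelSpec":
        return ModelSpec(
            factors={f: list(v) for f, v in self.factors.items()},
            factor_corr_free=self.factor_corr_free,
            second_order=self.second_order,
            bifactor=self.bifactor,
            residual_corrs=list(self.residual_corrs) + list(extra),
            equality_constraints=[list(g) for g in self.equality_constraints],
        )

    def to_yaml(self, path) -> None:
        doc = {
            "factors": {f: list(v) for f, v in self.factors.items()},
            "factor_corr_free": self.factor_corr_free,
            "second_order": self.second_order,
            "bifactor": self.bifactor,
            "residual_corrs": [list(p) for p in self.residual_corrs],
            "equality_constraints": [
                [list(slot) for slot in grp] for grp in self.equality_constraints
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            factors=doc["factors"],
            factor_corr_free=doc.get("factor_corr_free", True),
            second_order=doc.get("second_order"),
            bifactor=doc.get("bifactor", False),
            residual_corrs=[tuple(p) for p in doc.get("residual_corrs", [])],
            equality_constraints=[
                [tuple(s) for s in grp] for grp in doc.get("equality_constraints", [])
            ],
        )


@dataclass
class CfaFit:
    loadings: pd.DataFrame  # indicators x factors (incl. general for bifactor)
    factor_corr: pd.DataFrame
    residuals: np.ndarray  # derived residual variances (may be < 0: Heywood)
    residual_corr_estimates: dict
    second_order_loadings: dict
    chi2: float
    df: int
    cfi: float
    rmsea: float
    srmr: float
    param_se: np.ndarray
    converged: bool
    heywood_flags: list[str]
    objective: float
    n_eff: float
    theta: np.ndarray
    spec: ModelSpec
    gradient_norm: float


class _CfaProblem:
    """Maps a parameter vector to an implied correlation matrix."""

    def __init__(self, spec: ModelSpec, indicator_names: list[str]):
        self.spec = spec
        self.ind = list(indicator_names)
        self.k = len(self.ind)
        self.ind_idx = {n: i for i, n in enumerate(self.ind)}
        self.fac_names = list(spec.factors)
        self.nf = len(self.fac_names)
        self.fac_idx = {n: j for j, n in enumerate(self.fac_names)}

        # loading slots -> parameter ids with equality groups
        slot_list = []
        for f, inds in spec.factors.items():
            for i in inds:
                if i not in self.ind_idx:
                    raise ValueError(f"indicator {i!r} not present in the data")
                slot_list.append((f, i))
        if spec.bifactor:
            for i in self.ind:
                slot_list.append(("_general", i))
        group_of = {}
        for g, grp in enumerate(spec.equality_constraints):
            for slot in grp:
                group_of[tuple(slot)] = g
        self.slots = slot_list
        self.slot_param = []
        group_param: dict[int, int] = {}
        self.n_load_params = 0
        for slot in slot_list:
            g = group_of.get(slot)
            if g is None:
                self.slot_param.append(self.n_load_params)
                self.n_load_params += 1
            elif g in group_param:
                self.slot_param.append(group_param[g])
            else:
                group_param[g] = self.n_load_params
                self.slot_param.append(self.n_load_params)
                self.n_load_params += 1

        if spec.bifactor:
            self.n_phi = 0
            self.n_gamma = 0
        elif spec.second_order:
            self.n_phi = 0
            self.n_gamma = self.nf
        elif spec.factor_corr_free and self.nf > 1:
            self.n_phi = self.nf * (self.nf - 1) // 2
            self.n_gamma = 0
        else:
            self.n_phi = 0
            self.n_gamma = 0
        self.n_rescorr = len(spec.residual_corrs)
        self.n_params = self.n_load_params + self.n_phi + self.n_gamma + self.n_rescorr
        self.pairs = lower_tri_pairs(self.k)

    def start(self) -> np.ndarray:
        th = np.zeros(self.n_params)
        th[: self.n_load_params] = 0.7 if not self.spec.bifactor else 0.5
        off = self.n_load_params
        if self.n_phi:
            th[off : off + self.n_phi] = 0.3
            off += self.n_phi
        if self.n_gamma:
            th[off : off + self.n_gamma] = 0.7
            off += self.n_gamma
        return th

    def bounds(self):
        b = [(-2.0, 2.0)] * self.n_load_params
        b += [(-0.999, 0.999)] * (self.n_phi + self.n_gamma)
        b += [(-0.999, 0.999)] * self.n_rescorr
        return b

    def unpack(self, theta: np.ndarray):
        nf_total = self.nf + (1 if self.spec.bifactor else 0)
        L = np.zeros((self.k, nf_total))
        fac_col = dict(self.fac_idx)
        if self.spec.bifactor:
            fac_col["_general"] = self.nf
        for slot, p in zip(self.slots, self.slot_param):
            f, i = slot
            L[self.ind_idx[i], fac_col[f]] = theta[p]
        off = self.n_load_params
        if self.spec.bifactor:
            Phi = np.eye(nf_total)
            gamma = None
        elif self.spec.second_order:
            gamma = theta[off : off + self.n_gamma]
            off_d = np.clip(1.0 - gamma**2, 0.0, None)
            Phi = np.outer(gamma, gamma) + np.diag(off_d)
            np.fill_diagonal(Phi, 1.0)
        elif self.n_phi:
            Phi = np.eye(self.nf)
            vals = theta[off : off + self.n_phi]
            for v, (i, j) in zip(vals, lower_tri_pairs(self.nf)):
                Phi[i, j] = Phi[j, i] = v
            gamma = None
        else:
            Phi = np.eye(nf_total)
            gamma = None
        off = self.n_load_params + self.n_phi + self.n_gamma
        rescorr = theta[off : off + self.n_rescorr]
        return L, Phi, gamma, rescorr

    def implied(self, theta: np.ndarray) -> np.ndarray:
        L, Phi, _gamma, rescorr = self.unpack(theta)
        Sigma = L @ Phi @ L.T
        resid = 1.0 - np.diag(Sigma)
        R = Sigma + np.diag(resid)
        for v, (a, b) in zip(rescorr, self.spec.residual_corrs):
            i, j = self.ind_idx[a], self.ind_idx[b]
            R[i, j] += v
            R[j, i] += v
        return R


def _coerce_cfa_data(data, n_eff):
    """Returns (R, var_offdiag k x k, V_full or None, n_eff, names)."""
    if isinstance(data, PhenoCorrMatrix):
        R = data.R_p
        var = np.where(np.isfinite(data.se_matrix), data.se_matrix, 0.0) ** 2
        off = data.n_matrix[~np.eye(len(data.condition_names), dtype=bool)]
        n_eff = n_eff or (float(np.min(off)) if off.size else 1000.0)
        return R, var, None, n_eff, list(data.condition_names)
    if isinstance(data, GeneticCov):
        R, V_std = standardized_cov(data)
        k = len(data.traits)
        pairs_hv = [(i, j) for i in range(k) for j in range(i + 1)]
        var = np.zeros((k, k))
        for e, (i, j) in enumerate(pairs_hv):
            if i != j:
                var[i, j] = var[j, i] = V_std[e, e]
        # effective n for fit indices: smallest per-trait regression N
        n_eff = n_eff or float(np.nanmin(data.n_bar))
        return R, var, (V_std, pairs_hv), n_eff, list(data.traits)
    if isinstance(data, tuple) and len(data) == 2:
        R, names = np.asarray(data[0], dtype=float), list(data[1])
        n_eff = n_eff or 1000.0
        k = R.shape[0]
        var = (1.0 - R**2) ** 2 / max(n_eff - 1, 1.0)
        return R, var, None, n_eff, names
    raise TypeError("data must be PhenoCorrMatrix, GeneticCov, or (matrix, names)")


VAR_FLOOR = 1e-8


def fit_cfa(
    data,
    spec: ModelSpec,
    n_eff: float | None = None,
    start: np.ndarray | None = None,
) -> CfaFit:
    """DWLS confirmatory factor analysis.

    Minimizes sum_{i<j} (r_ij - sigma_ij(theta))^2 / Var(r_ij). The chi2 is
    the minimized discrepancy (weights are inverse sampling variances); CFI
    compares against the zero-correlation baseline on the same weights;
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); SRMR is the RMS
    correlation residual. Parameter SEs are sandwich estimates using the full
    sampling covariance V when available (genetic data), else the diagonal.
    Heywood cases (communality > 1) are flagged, never silently truncated.
    """
    R, var, V_info, n_eff, names = _coerce_cfa_data(data, n_eff)
    prob = _CfaProblem(spec, names)
    k = prob.k
    pairs = prob.pairs
    r_vec = np.array([R[i, j] for i, j in pairs])
    w_var = np.array([max(var[i, j], VAR_FLOOR) for i, j in pairs])
    # zero-SE entries (synthetic exact input) fall back to the median variance
    if np.all(var[np.triu_indices(k, 1)] <= VAR_FLOOR):
        w_var = np.full_like(w_var, 1.0 / max(n_eff, 2.0))
    w = 1.0 / w_var

    idx_i = np.array([i for i, j in pairs])
    idx_j = np.array([j for i, j in pairs])

    def objective(theta):
        Sig = prob.implied(theta)
        resid = r_vec - Sig[idx_i, idx_j]
        val = float(np.sum(w * resid**2))
        return val if np.isfinite(val) else 1e12

    bnds = prob.bounds()

    def _projected_grad(x, jac):
        # KKT: gradient components blocked by an active bound do not count
        g = np.asarray(jac, dtype=float).copy()
        for p, (lo, hi) in enumerate(bnds):
            if (x[p] <= lo + 1e-9 and g[p] > 0) or (x[p] >= hi - 1e-9 and g[p] < 0):
                g[p] = 0.0
        return float(np.max(np.abs(g)))

    starts = [np.asarray(start, dtype=float)] if start is not None else [prob.start()]
    starts.append(prob.start() * 0.6)
    res = None
    for th0 in starts:
        cand = minimize(
            objective, th0, method="L-BFGS-B", bounds=bnds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        cand = minimize(  # polish: restart from the solution
            objective, cand.x, method="L-BFGS-B", bounds=bnds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if res is None or cand.fun < res.fun:
            res = cand
        if _projected_grad(res.x, res.jac) <= 1e-4:
            break
    theta = res.x
    f_min = float(res.fun)
    grad_norm = _projected_grad(theta, res.jac) if res.jac is not None else np.nan
    if grad_norm > 1e-3:
        raise RuntimeError(
            f"CFA failed to converge (projected gradient max |g| = {grad_norm:.2e})"
        )

    # sign convention
    L, Phi, gamma, rescorr = prob.unpack(theta)
    nf_total = L.shape[1]
    signs = np.ones(nf_total)
    for f in range(nf_total):
        jmax = int(np.argmax(np.abs(L[:, f])))
        if L[jmax, f] < 0:
            signs[f] = -1.0
    L = L * signs
    Phi = np.diag(signs) @ Phi @ np.diag(signs)
    if gamma is not None:
        gamma = gamma * signs[: prob.nf]

    Sigma = prob.implied(theta)
    resid_var = 1.0 - np.diag(L @ Phi @ L.T)
    heywood = [names[i] for i in range(k) if resid_var[i] < 0]

    chi2 = f_min
    n_free = prob.n_params
    df = len(pairs) - n_free
    resid_vec = r_vec - Sigma[idx_i, idx_j]
    srmr = float(np.sqrt(np.mean(resid_vec**2)))
    f_base = float(np.sum(w * r_vec**2))
    df_base = len(pairs)
    num = max(chi2 - df, 0.0)
    den = max(f_base - df_base, num, 1e-12)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = (
        float(np.sqrt(max(chi2 - df, 0.0) / (df * max(n_eff - 1, 1.0))))
        if df > 0
        else 0.0
    )

    # sandwich SEs: (J'WJ)^-1 J'W V W J (J'WJ)^-1 over the off-diag moments
    J = np.empty((len(pairs), n_free))
    eps = 1e-6
    for p in range(n_free):
        tp = theta.copy()
        tm = theta.copy()
        tp[p] += eps
        tm[p] -= eps
        Sp = prob.implied(tp)
        Sm = prob.implied(tm)
        J[:, p] = (Sp[idx_i, idx_j] - Sm[idx_i, idx_j]) / (2 * eps)
    JW = J * w[:, None]
    try:
        bread = np.linalg.pinv(J.T @ JW)
        if V_info is not None:
            V_std, pairs_hv = V_info
            hv_pos = {pr: e for e, pr in enumerate(pairs_hv)}
            sel = [hv_pos[(i, j)] for i, j in pairs]
            V_full = V_std[np.ix_(sel, sel)]
        else:
            V_full = np.diag(w_var)
        meat = JW.T @ V_full @ JW
        cov_theta = bread @ meat @ bread
        param_se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))
    except np.linalg.LinAlgError:
        # degenerate Jacobian (e.g. a parameter pinned at its bound on very
        # noisy input): keep the point estimates, flag the SEs
        param_se = np.full(n_free, np.nan)

    fac_names = prob.fac_names + (["general"] if spec.bifactor else [])
    so_loadings = (
        {f: float(g) for f, g in zip(prob.fac_names, gamma)} if gamma is not None else {}
    )
    return CfaFit(
        loadings=pd.DataFrame(L, index=names, columns=fac_names),
        factor_corr=pd.DataFrame(Phi, index=fac_names, columns=fac_names),
        residuals=resid_var,
        residual_corr_estimates={
            pair: float(v) for pair, v in zip(spec.residual_corrs, rescorr)
        },
        second_order_loadings=so_loadings,
        chi2=chi2,
        df=df,
        cfi=float(min(cfi, 1.0)),
        rmsea=rmsea,
        srmr=srmr,
        param_se=param_se,
        converged=bool(grad_norm <= 1e-3),
        heywood_flags=heywood,
        objective=f_min,
        n_eff=float(n_eff),
        theta=theta,
        spec=spec,
        gradient_norm=grad_norm,
    )


def cross_level_fit(
    spec: ModelSpec,
    data,
    extra_residual_corrs: list[tuple[str, str]] | None = None,
    n_eff: float | None = None,
    start: np.ndarray | None = None,
) -> CfaFit:
    """Fit a model developed at one level to the other level's matrix,
    optionally freeing additional residual correlations."""
    new_spec = spec.with_residual_corrs(extra_residual_corrs or [])
    if extra_residual_corrs and start is not None:
        start = np.concatenate([start, np.zeros(len(extra_residual_corrs))])
    return fit_cfa(data, new_spec, n_eff=n_eff, start=start)


def loading_correlation(fit_a: CfaFit, fit_b: CfaFit, matched_factors) -> float:
    """Pearson correlation of loadings over matched factors, after aligning
    each factor pair's sign by its dominant indicator."""
    xs, ys = [], []
    for fa, fb in matched_factors:
        la = fit_a.loadings[fa]
        lb = fit_b.loadings[fb]
        common = [i for i in la.index if i in lb.index and (la[i] != 0 or lb[i] != 0)]
        va = la[common].to_numpy()
        vb = lb[common].to_numpy()
        if len(common) and np.dot(va, vb) < 0:
            vb = -vb
        xs.append(va)
        ys.append(vb)
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    if len(x) < 3:
        raise ValueError("matched factors share fewer than 3 loadings")
    return float(np.corrcoef(x, y)[0, 1])
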