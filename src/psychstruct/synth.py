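"""Liability-threshold factor-model simulator.

Generates cohorts of correlated binary conditions whose genetic and
environmental covariance structures are separately controllable, so that the
phenotypic (tetrachoric) and genetic (LD-score) correlation matrices implied
by the generating model can be deliberately decoupled. Every downstream
estimator in the package is validated against the closed-form quantities of
this model.

Model
-----
For condition ``i`` the liability is ``L_i = g_i + e_i`` with ``Var(L_i) = 1``
and ``Var(g_i) = h2_i`` (liability-scale SNP heritability). Both components
follow common-factor structures specified on the *standardized* scale::

    corr(g) = L_g Phi_g L_g' + diag(1 - communality_g)
    corr(e) = L_e Phi_e L_e' + diag(1 - communality_e)

so the implied genetic correlation matrix is ``corr(g)`` and the implied
phenotypic (liability) correlation matrix is::

    r_p[i, j] = sqrt(h2_i h2_j) r_g[i, j] + sqrt((1-h2_i)(1-h2_j)) r_e[i, j]

Diagnoses are thresholded at ``tau_i = Phi^-1(1 - K_i)`` where ``K_i`` is the
population lifetime prevalence, so the threshold comes from the *population*
prevalence and the sample prevalence is an output of the simulation.

Genotypes are Binomial(2, MAF) with blockwise AR(1) linkage disequilibrium:
each LD block is generated from two independent latent Gaussian AR(1)
haplotype chains thresholded at ``Phi^-1(1 - MAF)``, which preserves
Hardy-Weinberg margins and gives a closed-form expected dosage correlation
(see :func:`expected_dosage_corr`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._utils import bvn_cdf, cov2corr, derive_seed, is_pd

__all__ = [
    "SimConfig",
    "TrueModel",
    "Cohort",
    "ConfigurationError",
    "ModelConstructionError",
    "InfeasibleTargetError",
    "simulate_true_model",
    "implied_correlations",
    "simulate_cohort",
    "decouple_levels",
    "expected_dosage_corr",
    "write_cohort",
]

N_AUTOSOMES = 22


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g. infeasible h2 allocation)."""


class ModelConstructionError(ValueError):
    """The specified structure does not imply a valid correlation matrix."""


class InfeasibleTargetError(ValueError):
    """A requested phenotypic-genetic decoupling has no PD environmental
    structure; carries the offending eigenvalue."""

    def __init__(self, msg: str, eigenvalue: float):
        super().__init__(msg)
        self.eigenvalue = float(eigenvalue)


@dataclass(frozen=True)
class SimConfig:
    """Scale and rates of a simulated study.

    ``prevalences`` are *population* lifetime prevalences K per condition;
    ``h2_targets`` are liability-scale SNP heritabilities. ``ld_block_size``
    SNPs form one AR(1) LD block with latent decay ``ld_decay`` per adjacent
    SNP; ``n_snps`` must divide into whole blocks.
    """

    n_individuals: int
    n_snps: int
    n_conditions: int
    prevalences: tuple[float, ...]
    h2_targets: tuple[float, ...]
    ld_block_size: int = 40
    ld_decay: float = 0.9
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self):
        object.__setattr__(self, "prevalences", tuple(float(p) for p in self.prevalences))
        object.__setattr__(self, "h2_targets", tuple(float(h) for h in self.h2_targets))
        if len(self.prevalences) != self.n_conditions:
            raise ConfigurationError("prevalences must have length n_conditions")
        if len(self.h2_targets) != self.n_conditions:
            raise ConfigurationError("h2_targets must have length n_conditions")
        if not all(0.0 < p < 1.0 for p in self.prevalences):
            raise ConfigurationError("all prevalences must lie in (0, 1)")
        if not all(0.0 <= h <= 1.0 for h in self.h2_targets):
            raise ConfigurationError("all h2 targets must lie in [0, 1]")
        if self.n_snps % self.ld_block_size != 0:
            raise ConfigurationError(
                f"n_snps={self.n_snps} not divisible into blocks of {self.ld_block_size}"
            )
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must lie in [0, 1)")

    @property
    def n_blocks(self) -> int:
        return self.n_snps // self.ld_block_size

    def block_decays(self) -> np.ndarray:
        """Per-block latent AR(1) decay, cycling over {0, 1/4, 1/2, 3/4, 1} x
        ld_decay so the genome mixes unlinked and strongly linked regions —
        the LD-score heterogeneity that identifies the LDSC intercept."""
        steps = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * self.ld_decay
        return steps[np.arange(self.n_blocks) % len(steps)]


@dataclass
class TrueModel:
    """Ground-truth generating model.

    Loading matrices are on the liability scale (they already include the
    sqrt(h2) / sqrt(1-h2) scaling); ``loadings_std_*`` expose the standardized
    patterns. ``snp_effects`` holds per-SNP standardized effects for the
    common genetic factors (first ``n_factors_genetic`` columns) followed by
    the per-condition specific genetic components (next ``n_conditions``
    columns).
    """

    config: SimConfig
    condition_names: list[str]
    factor_names_genetic: list[str]
    factor_names_env: list[str]
    loadings_genetic: np.ndarray  # k x f_g, liability scale
    loadings_env: np.ndarray  # k x f_e, liability scale
    phi_genetic: np.ndarray
    phi_env: np.ndarray
    residual_genetic: np.ndarray  # per-condition variances, liability scale
    residual_env: np.ndarray
    thresholds: np.ndarray
    snp_effects: np.ndarray  # M x (f_g + k)
    mafs: np.ndarray

    @property
    def h2(self) -> np.ndarray:
        return np.asarray(self.config.h2_targets)

    @property
    def n_factors_genetic(self) -> int:
        return self.loadings_genetic.shape[1]

    @property
    def loadings_std_genetic(self) -> np.ndarray:
        h = np.sqrt(np.where(self.h2 > 0, self.h2, 1.0))
        return self.loadings_genetic / h[:, None]

    @property
    def loadings_std_env(self) -> np.ndarray:
        e = np.sqrt(1.0 - self.h2)
        return self.loadings_env / e[:, None]

    def genetic_corr(self) -> np.ndarray:
        Ls = self.loadings_std_genetic
        res = np.where(self.h2 > 0, self.residual_genetic / np.where(self.h2 > 0, self.h2, 1.0), 1.0)
        R = Ls @ self.phi_genetic @ Ls.T + np.diag(res)
        np.fill_diagonal(R, 1.0)
        return R

    def env_corr(self) -> np.ndarray:
        Ls = self.loadings_std_env
        res = self.residual_env / (1.0 - self.h2)
        R = Ls @ self.phi_env @ Ls.T + np.diag(res)
        np.fill_diagonal(R, 1.0)
        return R


@dataclass
class Cohort:
    """One simulated sample: dosages, liabilities, diagnoses, covariates."""

    dosages: np.ndarray  # n x M, float32 in [0, 2]
    liabilities_genetic: np.ndarray  # n x k
    liabilities_env: np.ndarray  # n x k
    diagnoses: np.ndarray  # n x k int8
    covariates: pd.DataFrame  # sex, birth_year, PC1..PC4
    snp_ids: list[str]
    chromosomes: np.ndarray  # per-SNP, 1..22
    positions: np.ndarray  # per-SNP 1-based bp
    mafs: np.ndarray
    condition_names: list[str]
    ld_block_size: int

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "CHR": self.chromosomes,
                "BP": self.positions,
                "MAF": self.mafs,
            }
        )


def _pattern_to_matrix(pattern, condition_names):
    """dict {factor: {condition: loading}} -> (k x f standardized matrix, factor names)."""
    factor_names = list(pattern)
    k = len(condition_names)
    name_to_idx = {n: i for i, n in enumerate(condition_names)}
    L = np.zeros((k, len(factor_names)))
    for f, fac in enumerate(factor_names):
        for cond, lam in pattern[fac].items():
            idx = cond if isinstance(cond, (int, np.integer)) else name_to_idx[cond]
            if not 0 <= idx < k:
                raise ConfigurationError(
                    f"pattern references condition {cond!r} outside the {k} conditions"
                )
            L[idx, f] = float(lam)
    return L, factor_names


def _default_phi(m: int) -> np.ndarray:
    return np.eye(m)


def simulate_true_model(
    config: SimConfig,
    spec_genetic,
    spec_env,
    phi_genetic: np.ndarray | None = None,
    phi_env: np.ndarray | None = None,
    condition_names: list[str] | None = None,
) -> TrueModel:
    """Build the ground-truth model from standardized factor patterns.

    ``spec_genetic`` / ``spec_env`` map factor names to ``{condition:
    standardized loading}``. Communalities above 1 mean the pattern claims
    more variance than the h2 (resp. environmental) share allows and raise
    :class:`ConfigurationError`.
    """
    k = config.n_conditions
    names = list(condition_names) if condition_names else [f"C{i+1}" for i in range(k)]
    if len(names) != k:
        raise ConfigurationError("condition_names length mismatch")
    h2 = np.asarray(config.h2_targets)
    K = np.asarray(config.prevalences)

    Lg_std, gnames = _pattern_to_matrix(spec_genetic, names)
    Le_std, enames = _pattern_to_matrix(spec_env, names)
    Pg = np.asarray(phi_genetic, dtype=float) if phi_genetic is not None else _default_phi(Lg_std.shape[1])
    Pe = np.asarray(phi_env, dtype=float) if phi_env is not None else _default_phi(Le_std.shape[1])
    for P, nm in ((Pg, "phi_genetic"), (Pe, "phi_env")):
        if not np.allclose(P, P.T) or not np.allclose(np.diag(P), 1.0):
            raise ConfigurationError(f"{nm} must be a correlation matrix")

    comm_g = np.einsum("if,fg,ig->i", Lg_std, Pg, Lg_std)
    comm_e = np.einsum("if,fg,ig->i", Le_std, Pe, Le_std)
    if np.any(comm_g > 1.0 + 1e-12):
        bad = names[int(np.argmax(comm_g))]
        raise ConfigurationError(
            f"genetic loading variance exceeds the h2 share for {bad} "
            f"(communality {comm_g.max():.4f} > 1)"
        )
    if np.any(comm_e > 1.0 + 1e-12):
        bad = names[int(np.argmax(comm_e))]
        raise ConfigurationError(
            f"environmental loading variance exceeds its share for {bad} "
            f"(communality {comm_e.max():.4f} > 1)"
        )

    # zero-h2 conditions carry no genetic loadings at all
    Lg_std = np.where(h2[:, None] > 0, Lg_std, 0.0)
    comm_g = np.where(h2 > 0, comm_g, 0.0)

    Lg = Lg_std * np.sqrt(h2)[:, None]
    Le = Le_std * np.sqrt(1.0 - h2)[:, None]
    res_g = h2 * (1.0 - comm_g)
    res_e = (1.0 - h2) * (1.0 - comm_e)
    thresholds = norm.isf(K)

    rng = np.random.default_rng(derive_seed(config.seed, "true-model"))
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    f_g = Lg_std.shape[1]
    M = config.n_snps
    # common-factor effects correlated across factors so the realized genetic
    # factor scores have correlation ~ Phi_g; specific effects independent
    chol_pg = np.linalg.cholesky(Pg + 1e-12 * np.eye(f_g))
    common = rng.standard_normal((M, f_g)) @ chol_pg.T / np.sqrt(M)
    specific = rng.standard_normal((M, k)) / np.sqrt(M)
    snp_effects = np.hstack([common, specific])

    model = TrueModel(
        config=config,
        condition_names=names,
        factor_names_genetic=gnames,
        factor_names_env=enames,
        loadings_genetic=Lg,
        loadings_env=Le,
        phi_genetic=Pg,
        phi_env=Pe,
        residual_genetic=res_g,
        residual_env=res_e,
        thresholds=thresholds,
        snp_effects=snp_effects,
        mafs=mafs,
    )
    # r_p must be strictly PD (the environmental structure is factorized);
    # r_g may be singular (e.g. a pure common-pathway model with unit
    # standardized loadings has a rank-1 genetic correlation matrix)
    r_p, r_g = implied_correlations(model)
    if np.linalg.eigvalsh(r_g).min() < -1e-8:
        raise ModelConstructionError("implied genetic correlation matrix is indefinite")
    return model


def implied_correlations(model: TrueModel) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form liability-scale phenotypic and genetic correlation matrices."""
    h2 = model.h2
    r_g = model.genetic_corr()
    r_e = model.env_corr()
    a = np.sqrt(h2)
    b = np.sqrt(1.0 - h2)
    r_p = np.outer(a, a) * r_g + np.outer(b, b) * r_e
    np.fill_diagonal(r_p, 1.0)
    r_p = 0.5 * (r_p + r_p.T)
    r_g = 0.5 * (r_g + r_g.T)
    if not is_pd(r_p):
        raise ModelConstructionError("implied phenotypic correlation matrix is not PD")
    return r_p, r_g


def decouple_levels(model: TrueModel, target_D: np.ndarray) -> TrueModel:
    """Return a model whose implied r_p - r_g equals ``target_D``.

    The genetic side is untouched; the environmental correlation structure is
    re-solved so that the phenotypic matrix lands exactly on r_g + D. The new
    environmental structure is stored through its Cholesky factor (one
    'factor' per condition, Phi_e = I, zero residuals).
    """
    D = np.asarray(target_D, dtype=float)
    k = len(model.condition_names)
    if D.shape != (k, k) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ConfigurationError("target_D must be symmetric with a zero diagonal")
    h2 = model.h2
    if np.any(h2 >= 1.0):
        raise ConfigurationError("decoupling requires h2 < 1 for every condition")
    r_g = model.genetic_corr()
    r_p_target = r_g + D
    a = np.sqrt(h2)
    b = np.sqrt(1.0 - h2)
    R_e = (r_p_target - np.outer(a, a) * r_g) / np.outer(b, b)
    np.fill_diagonal(R_e, 1.0)
    if np.any(np.abs(R_e[~np.eye(k, dtype=bool)]) > 1.0):
        worst = np.abs(R_e[~np.eye(k, dtype=bool)]).max()
        raise InfeasibleTargetError(
            f"required environmental correlation {worst:.3f} exceeds |1|", np.nan
        )
    w = np.linalg.eigvalsh(0.5 * (R_e + R_e.T))
    if w.min() <= 1e-10:
        raise InfeasibleTargetError(
            f"environmental structure not PD (min eigenvalue {w.min():.3e})", w.min()
        )
    L = np.linalg.cholesky(R_e)
    Le = L * b[:, None]
    return replace(
        model,
        loadings_env=Le,
        phi_env=np.eye(k),
        residual_env=np.zeros(k),
        factor_names_env=[f"E{i+1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# cohort simulation


def expected_dosage_corr(maf_j: float, maf_k: float, rho_latent: float) -> float:
    """Closed-form dosage correlation induced by the latent-Gaussian coupling.

    Each haplotype allele is ``1[Z > Phi^-1(1 - p)]`` with latent correlation
    ``rho_latent`` between loci; the dosage is the sum of two independent
    haplotypes, so ``corr(d_j, d_k) = cov(H_j, H_k) / sqrt(p_j q_j p_k q_k)``
    with ``cov(H_j, H_k) = P11 - p_j p_k`` from the bivariate normal CDF.
    """
    tj = norm.isf(maf_j)
    tk = norm.isf(maf_k)
    # P(Z_j > tj, Z_k > tk) via survival copula
    p11 = 1.0 - norm.cdf(tj) - norm.cdf(tk) + bvn_cdf(tj, tk, rho_latent)
    cov_h = p11 - maf_j * maf_k
    return cov_h / np.sqrt(maf_j * (1 - maf_j) * maf_k * (1 - maf_k))


def _simulate_dosage_block(rng, n, mafs_block, rho):
    """Two thresholded latent AR(1) haplotype chains -> Binomial(2, p) dosages."""
    B = len(mafs_block)
    thr = norm.isf(mafs_block).astype(np.float32)
    d = np.zeros((n, B), dtype=np.int8)
    for _ in range(2):
        z = rng.standard_normal((n, B), dtype=np.float32)
        if rho > 0:
            fac = np.float32(np.sqrt(1.0 - rho * rho))
            rho32 = np.float32(rho)
            for j in range(1, B):
                z[:, j] = rho32 * z[:, j - 1] + fac * z[:, j]
        d += z > thr
    return d


def _snp_metadata(config: SimConfig):
    """Round-robin chromosome per LD block; positions spaced 100 kb within a
    chromosome so blocks never span chromosome boundaries."""
    n_b = config.n_blocks
    B = config.ld_block_size
    chroms = np.empty(config.n_snps, dtype=np.int64)
    positions = np.empty(config.n_snps, dtype=np.int64)
    counter = {c: 0 for c in range(1, N_AUTOSOMES + 1)}
    for b in range(n_b):
        c = (b % N_AUTOSOMES) + 1
        sl = slice(b * B, (b + 1) * B)
        chroms[sl] = c
        start = counter[c]
        positions[sl] = (np.arange(start, start + B) + 1) * 100_000
        counter[c] = start + B
    return chroms, positions


def simulate_cohort(model: TrueModel, config: SimConfig | None = None) -> Cohort:
    """Draw one cohort (dosages, liabilities, diagnoses, covariates).

    Genetic factor scores are the SNP-effect weighted sums of standardized
    dosages, empirically standardized so that the total liability variance is
    1 and the thresholds reproduce the population prevalences.
    """
    cfg = config or model.config
    rng = np.random.default_rng(derive_seed(cfg.seed, "cohort"))
    n, M, k = cfg.n_individuals, cfg.n_snps, cfg.n_conditions
    B = cfg.ld_block_size

    dosages = np.empty((n, M), dtype=np.float32)
    decays = cfg.block_decays()
    for b in range(cfg.n_blocks):
        sl = slice(b * B, (b + 1) * B)
        dosages[:, sl] = _simulate_dosage_block(rng, n, model.mafs[sl], decays[b])

    # standardized dosages -> factor scores, without materializing a second
    # n x M matrix: accumulate X @ W with X centered/scaled on the fly
    mu = dosages.mean(axis=0, dtype=np.float64)
    sumsq = np.einsum("ij,ij->j", dosages, dosages, dtype=np.float64)
    sd = np.sqrt(np.clip(sumsq / n - mu**2, 0.0, None))
    sd_safe = np.where(sd > 0, sd, 1.0)
    W = (model.snp_effects / sd_safe[:, None]).astype(np.float32)
    scores = dosages @ W
    scores -= mu[None, :].astype(np.float32) @ W
    scores = scores.astype(np.float64)
    # empirical standardization keeps prevalence calibration exact-in-mean
    s_sd = scores.std(axis=0)
    scores /= np.where(s_sd > 0, s_sd, 1.0)

    f_g = model.n_factors_genetic
    F = scores[:, :f_g]
    U = scores[:, f_g:]
    h2 = model.h2
    Ls = model.loadings_std_genetic
    res_std = np.where(h2 > 0, model.residual_genetic / np.where(h2 > 0, h2, 1.0), 0.0)
    g = (F @ Ls.T + U * np.sqrt(res_std)) * np.sqrt(h2)

    R_e = model.env_corr()
    chol_e = np.linalg.cholesky(R_e + 1e-12 * np.eye(k))
    eps = rng.standard_normal((n, k)) @ chol_e.T
    e = eps * np.sqrt(1.0 - h2)

    liab = g + e
    diagnoses = (liab > model.thresholds).astype(np.int8)

    covariates = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n),
            "birth_year": rng.integers(1940, 1971, size=n),
            **{f"PC{j+1}": rng.standard_normal(n) for j in range(4)},
        }
    )
    chroms, positions = _snp_metadata(cfg)
    snp_ids = [f"rs{c}_{p}" for c, p in zip(chroms, positions)]
    return Cohort(
        dosages=dosages,
        liabilities_genetic=g,
        liabilities_env=e,
        diagnoses=diagnoses,
        covariates=covariates,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        mafs=model.mafs.copy(),
        condition_names=list(model.condition_names),
        ld_block_size=B,
    )


def write_cohort(cohort: Cohort, outdir, header_comment: str | None = None) -> None:
    """Write diagnoses/covariates as TSV and dosages as a dense matrix with a
    SNP metadata sidecar."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, path):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)

    diag = pd.DataFrame(cohort.diagnoses, columns=cohort.condition_names)
    diag.insert(0, "IID", [f"I{i+1}" for i in range(cohort.n_individuals)])
    _write(diag, out / "diagnoses.tsv")
    cov = cohort.covariates.copy()
    cov.insert(0, "IID", diag["IID"])
    _write(cov, out / "covariates.tsv")
    _write(cohort.snp_table(), out / "snps.tsv")
    np.savetxt(out / "dosages.tsv", cohort.dosages, fmt="%.0f", delimiter="\t")


def read_cohort(indir, ld_block_size: int = 40) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Liabilities are not serialized and come back as zeros; the LD block size
    is layout metadata the caller must supply if it differs from the
    default.
    """
    import pathlib

    ind = pathlib.Path(indir)
    diag = pd.read_csv(ind / "diagnoses.tsv", sep="\t", comment="#")
    cov = pd.read_csv(ind / "covariates.tsv", sep="\t", comment="#")
    snps = pd.read_csv(ind / "snps.tsv", sep="\t", comment="#")
    dosages = np.loadtxt(ind / "dosages.tsv", delimiter="\t").astype(np.float32)
    if dosages.ndim == 1:
        dosages = dosages[:, None]
    names = [c for c in diag.columns if c != "IID"]
    n, k = len(diag), len(names)
    return Cohort(
        dosages=dosages,
        liabilities_genetic=np.zeros((n, k)),
        liabilities_env=np.zeros((n, k)),
        diagnoses=diag[names].to_numpy(dtype=np.int8),
        covariates=cov.drop(columns=["IID"]),
        snp_ids=list(snps["SNP"]),
        chromosomes=snps["CHR"].to_numpy(),
        positions=snps["BP"].to_numpy(),
        mafs=snps["MAF"].to_numpy(dtype=float),
        condition_names=names,
        ld_block_size=ld_block_size,
    )


def write_vcf(cohort: Cohort, path) -> None:
    """Hard-called genotypes as a minimal uncompressed VCF (GT only)."""
    n = cohort.n_individuals
    samples = [f"I{i+1}" for i in range(n)]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=psychstruct-simulated\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(cohort.n_snps):
            gts = "\t".join(
                gt_codes[int(round(float(d)))] for d in cohort.dosages[:, j]
            )
            fh.write(
                f"{cohort.chromosomes[j]}\t{cohort.positions[j]}\t"
                f"{cohort.snp_ids[j]}\tG\tA\t.\tPASS\t.\tGT\t{gts}\n"
            )
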