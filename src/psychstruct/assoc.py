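"""Per-SNP association scans, effective N, munging filters and sample-size
weighted meta-analysis.

Summary statistics live in a pandas DataFrame with the fixed column set
``SNP CHR BP A1 A2 MAF BETA SE Z N NEFF INFO`` (tab-separated on disk, gzip
accepted). Association on the simulated cohorts is ordinary least squares of
the 0/1 diagnosis on allele dosage plus covariates — the linear-probability
scale that LD-score regression expects for binary traits.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import Cohort

__all__ = [
    "SUMSTATS_COLUMNS",
    "run_gwas",
    "run_gwas_multi",
    "effective_n",
    "munge",
    "meta_analyze",
    "read_sumstats",
    "write_sumstats",
    "validate_sumstats",
]

log = logging.getLogger(__name__)

SUMSTATS_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "MAF", "BETA", "SE", "Z", "N", "NEFF", "INFO",
]


def effective_n(sample_prevalence: float, n_total: int) -> float:
    """Effective sample size of a case-control study: 4 p (1 - p) N."""
    p = float(sample_prevalence)
    if not 0.0 < p < 1.0:
        raise ValueError("sample prevalence must lie in (0, 1)")
    return 4.0 * p * (1.0 - p) * float(n_total)


def run_gwas(
    cohort: Cohort,
    condition_index: int,
    covariates: Sequence[str] = (),
    min_cases: int = 50,
) -> pd.DataFrame:
    """Per-SNP OLS of the 0/1 outcome on dosage plus covariates.

    Uses Frisch-Waugh residualization: outcome and dosages are projected off
    the covariate design (with intercept) once, then each SNP is a simple
    regression with residual degrees of freedom n - q - 1 (q = number of
    covariate columns including the intercept) — algebraically identical to
    the full joint OLS per SNP. Monomorphic SNPs are emitted with beta = 0
    and an undefined (NaN) SE.
    """
    return run_gwas_multi(cohort, [condition_index], covariates, min_cases)[0]


def run_gwas_multi(
    cohort: Cohort,
    condition_indices: Sequence[int],
    covariates: Sequence[str] = (),
    min_cases: int = 50,
) -> list[pd.DataFrame]:
    """Association scans for several conditions in one pass over the dosages
    (the covariate design, and hence the per-SNP residual variance of the
    dosage, is shared across outcomes)."""
    n = cohort.n_individuals
    Y = cohort.diagnoses[:, list(condition_indices)].astype(np.float64)
    for t, ci in enumerate(condition_indices):
        n_cases = int(Y[:, t].sum())
        if n_cases < min_cases or n - n_cases < min_cases:
            raise ValueError(
                f"condition {cohort.condition_names[ci]} has "
                f"{n_cases} cases / {n - n_cases} controls; need >= {min_cases} of each"
            )
    C = np.ones((n, 1))
    names = ["intercept"]
    for c in covariates:
        C = np.hstack([C, np.asarray(cohort.covariates[c], dtype=float)[:, None]])
        names.append(c)
    q = C.shape[1]
    if np.linalg.matrix_rank(C) < q:
        bad = []
        for j in range(1, q):
            if np.linalg.matrix_rank(C[:, : j + 1]) == np.linalg.matrix_rank(C[:, :j]):
                bad.append(names[j])
        raise ValueError(f"degenerate covariate matrix; collinear columns: {bad}")

    Q, _ = np.linalg.qr(C)
    Y_r = Y - Q @ (Q.T @ Y)
    yty = np.einsum("it,it->t", Y_r, Y_r)

    # chunked so the float64 dosage copy stays small; X_r'y_r = X'y_r and
    # ||x_r||^2 = ||x||^2 - ||Q'x||^2, so the residualized dosage matrix is
    # never materialized
    M = cohort.n_snps
    xtx = np.empty(M)
    xty = np.empty((M, Y.shape[1]))
    chunk = max(1, int(4e7) // max(n, 1))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        Xc = cohort.dosages[:, lo:hi].astype(np.float64)
        G = Q.T @ Xc
        xtx[lo:hi] = np.einsum("ij,ij->j", Xc, Xc) - np.einsum("ij,ij->j", G, G)
        xty[lo:hi] = Xc.T @ Y_r
    mono = xtx <= 1e-12
    xtx_safe = np.where(mono, 1.0, xtx)
    df_resid = n - q - 1
    freq = cohort.dosages.mean(axis=0, dtype=np.float64) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    out = []
    for t, ci in enumerate(condition_indices):
        beta = np.where(mono, 0.0, xty[:, t] / xtx_safe)
        rss = yty[t] - beta * xty[:, t]
        sigma2 = np.clip(rss, 0.0, None) / df_resid
        se = np.where(mono, np.nan, np.sqrt(sigma2 / xtx_safe))
        with np.errstate(invalid="ignore"):
            z = np.where(mono, np.nan, beta / se)
        n_cases = int(Y[:, t].sum())
        ss = pd.DataFrame(
            {
                "SNP": cohort.snp_ids,
                "CHR": cohort.chromosomes,
                "BP": cohort.positions,
                "A1": "A",
                "A2": "G",
                "MAF": maf,
                "BETA": beta,
                "SE": se,
                "Z": z,
                "N": n,
                "NEFF": effective_n(n_cases / n, n),
                "INFO": 1.0,
            }
        )
        out.append(ss.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True))
    return out


def munge(
    ss: pd.DataFrame,
    info_min: float = 0.9,
    maf_min: float = 0.01,
    drop_ambiguous: bool = False,
) -> pd.DataFrame:
    """Drop SNPs failing INFO >= info_min or MAF >= maf_min (inclusive
    bounds). ``drop_ambiguous`` additionally removes strand-ambiguous (A/T,
    C/G) SNPs; simulated data carry no strand uncertainty, so they are
    retained by default."""
    keep_info = ss["INFO"] >= info_min
    keep_maf = ss["MAF"] >= maf_min
    keep = keep_info & keep_maf
    dropped_info = int((~keep_info).sum())
    dropped_maf = int((keep_info & ~keep_maf).sum())
    dropped_amb = 0
    if drop_ambiguous:
        ambiguous = ss.apply(
            lambda r: _COMPLEMENT.get(r["A1"]) == r["A2"], axis=1
        )
        dropped_amb = int((keep & ambiguous).sum())
        keep &= ~ambiguous
    out = ss[keep].reset_index(drop=True)
    log.info(
        "munge: removed %d SNPs on INFO < %.2f, %d on MAF < %.3f, "
        "%d strand-ambiguous (%d remain)",
        dropped_info, info_min, dropped_maf, maf_min, dropped_amb, len(out),
    )
    if out.empty:
        raise ValueError(
            f"munging removed every SNP; consider relaxing info_min={info_min} "
            f"or maf_min={maf_min}"
        )
    return out


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _aligned_sign(a1, a2, ref1, ref2):
    """+1 if alleles match, -1 if swapped (with or without strand flip), 0 if
    irreconcilable."""
    if (a1, a2) == (ref1, ref2):
        return 1
    if (a1, a2) == (ref2, ref1):
        return -1
    f1, f2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (f1, f2) == (ref1, ref2):
        return 1
    if (f1, f2) == (ref2, ref1):
        return -1
    return 0


def meta_analyze(studies: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Sample-size weighted meta-analysis over the shared SNP set.

    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)) with w_i = sqrt(Neff_i); the
    meta effective N is the sum of the per-cohort effective Ns. Effect alleles
    are aligned to the first study, flipping z when A1/A2 are swapped; SNPs
    with irreconcilable alleles are dropped with a log entry. BETA/SE are
    back-filled on the standardized scale so that Z = BETA / SE holds.
    """
    studies = [s for s in studies]
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    base = studies[0].set_index("SNP")
    shared = base.index
    for s in studies[1:]:
        shared = shared.intersection(s.set_index("SNP").index)
    shared = list(shared)

    zs, ws, neffs, ns, mafs = [], [], [], [], []
    dropped = set()
    for s_idx, s in enumerate(studies):
        s = s.set_index("SNP").loc[shared]
        if s_idx == 0:
            sign = np.ones(len(shared))
        else:
            sign = np.array(
                [
                    _aligned_sign(a1, a2, r1, r2)
                    for a1, a2, r1, r2 in zip(
                        s["A1"], s["A2"],
                        base.loc[shared, "A1"], base.loc[shared, "A2"],
                    )
                ],
                dtype=float,
            )
            for snp, sg in zip(shared, sign):
                if sg == 0:
                    dropped.add(snp)
        zs.append(np.asarray(s["Z"], dtype=float) * np.where(sign == 0, np.nan, sign))
        neffs.append(np.asarray(s["NEFF"], dtype=float))
        ws.append(np.sqrt(np.asarray(s["NEFF"], dtype=float)))
        ns.append(np.asarray(s["N"], dtype=float))
        mafs.append(np.asarray(s["MAF"], dtype=float))
    if dropped:
        log.info("meta_analyze: dropped %d SNPs with irreconcilable alleles", len(dropped))

    Zm = np.vstack(zs)
    Wm = np.vstack(ws)
    z_meta = np.nansum(Wm * Zm, axis=0) / np.sqrt(np.sum(Wm**2, axis=0))
    neff_meta = np.sum(np.vstack(neffs), axis=0)
    n_meta = np.sum(np.vstack(ns), axis=0)
    maf_meta = np.sum(np.vstack(mafs) * np.vstack(neffs), axis=0) / neff_meta

    out = base.loc[shared].reset_index()
    out["Z"] = z_meta
    out["NEFF"] = neff_meta
    out["N"] = n_meta
    out["MAF"] = maf_meta
    # standardized-scale effect implied by the meta Z and the effective N
    var_snp = 2.0 * maf_meta * (1.0 - maf_meta)
    out["SE"] = 1.0 / np.sqrt(neff_meta * var_snp)
    out["BETA"] = out["Z"] * out["SE"]
    out["INFO"] = 1.0
    keep = ~out["SNP"].isin(dropped)
    out = out[keep]
    return (
        out[SUMSTATS_COLUMNS]
        .sort_values(["CHR", "BP"], kind="mergesort")
        .reset_index(drop=True)
    )


def validate_sumstats(ss: pd.DataFrame) -> None:
    missing = [c for c in SUMSTATS_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"sumstats missing columns: {missing}")
    finite = ss["SE"].notna()
    ratio = np.abs(ss.loc[finite, "BETA"] / ss.loc[finite, "SE"] - ss.loc[finite, "Z"])
    if len(ratio) and np.nanmax(ratio) > 1e-6:
        raise ValueError("Z != BETA/SE in sumstats")


def write_sumstats(ss: pd.DataFrame, path, header_comment: str | None = None) -> None:
    import gzip
    import pathlib

    path = pathlib.Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ss[SUMSTATS_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", comment="#")
    validate_sumstats(ss)
    return ss
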