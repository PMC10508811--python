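"""End-to-end pipeline: simulate -> GWAS -> LDSC / tetrachoric -> EFA ->
CFA -> cross-level comparison -> disparity -> factor GWAS + Q -> PGI.

The stage order mirrors the analysis flow of a cross-level psychopathology
study: phenotypic structure is learned on a training half of the sample and
confirmed on the test half; genetic structure is learned on odd-chromosome
SNPs and confirmed on even chromosomes; polygenic indices built from the
factor GWAS are evaluated in a holdout subsample disjoint from the GWAS
individuals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assoc, disparity, factor_models, gsem, ldsc, pgi, phenocorr, synth
from ._utils import derive_seed

__all__ = [
    "PipelineConfig",
    "default_study",
    "split_train_test",
    "run_pipeline",
]

log = logging.getLogger(__name__)

# Ten-condition study template: population prevalences and liability-scale
# heritabilities spanning the ranges typical of lifetime psychiatric
# conditions in a population biobank (rare conditions ~0.3%, common ~20%;
# h2 ~0.05-0.25).
DEFAULT_CONDITIONS = {
    "ANX": (0.1001, 0.071),
    "AUD": (0.0316, 0.114),
    "BIP": (0.0104, 0.185),
    "DEP": (0.1957, 0.069),
    "EAT": (0.0042, 0.131),
    "OCD": (0.0026, 0.187),
    "PTSD": (0.0193, 0.097),
    "SCZ": (0.0037, 0.246),
    "SUI": (0.0986, 0.048),
    "SUD": (0.0079, 0.109),
}

# Genetic-level structure: thought disorder, internalizing (incl. substance
# use), compulsive. Phenotypic (environmental) structure: thought disorder,
# internalizing (incl. compulsive conditions), externalizing.
DEFAULT_GENETIC_PATTERN = {
    "TD": {"BIP": 0.75, "SCZ": 0.75},
    "INT": {"ANX": 0.7, "AUD": 0.55, "DEP": 0.75, "PTSD": 0.65, "SUD": 0.55, "SUI": 0.65},
    "COMP": {"EAT": 0.65, "OCD": 0.65},
}
DEFAULT_GENETIC_PHI = np.array(
    [[1.0, 0.45, 0.30], [0.45, 1.0, 0.45], [0.30, 0.45, 1.0]]
)
DEFAULT_ENV_PATTERN = {
    "TD": {"BIP": 0.70, "SCZ": 0.70},
    "INT": {"ANX": 0.70, "DEP": 0.75, "EAT": 0.55, "OCD": 0.55, "PTSD": 0.65, "SUI": 0.65},
    "EXT": {"AUD": 0.70, "SUD": 0.70},
}
DEFAULT_ENV_PHI = np.array(
    [[1.0, 0.45, 0.35], [0.45, 1.0, 0.50], [0.35, 0.50, 1.0]]
)

# Six-condition demo configuration: common-enough conditions with equal
# moderate heritability, so every stage (including LDSC on a
# thousands-of-SNPs genome) operates in an estimable regime. Genetically the
# compulsive conditions form their own factor; phenotypically they are
# absorbed into internalizing — the cross-level decoupling under study.
DEMO_CONDITIONS = {
    "DEP": (0.20, 0.35),
    "ANX": (0.15, 0.35),
    "SUI": (0.10, 0.35),
    "PTSD": (0.08, 0.35),
    "EAT": (0.06, 0.35),
    "OCD": (0.05, 0.35),
}


def _patterns_for(names):
    """Subset the template factor patterns to the present conditions,
    dropping factors left without indicators (with matching Phi rows)."""
    def filt(pattern, phi):
        kept, keep_idx = {}, []
        for j, (f, p) in enumerate(pattern.items()):
            sub = {c: v for c, v in p.items() if c in names}
            if sub:
                kept[f] = sub
                keep_idx.append(j)
        return kept, phi[np.ix_(keep_idx, keep_idx)]

    pat_g, phi_g = filt(DEFAULT_GENETIC_PATTERN, DEFAULT_GENETIC_PHI)
    pat_e, phi_e = filt(DEFAULT_ENV_PATTERN, DEFAULT_ENV_PHI)
    return pat_g, phi_g, pat_e, phi_e


def default_study(
    n_individuals: int = 20_000,
    n_snps: int = 2_000,
    seed: int = 0,
    conditions: dict | None = None,
):
    """Study-template SimConfig + TrueModel: ten conditions, three genetic
    factors, a deliberately different three-factor phenotypic structure."""
    conds = conditions or DEFAULT_CONDITIONS
    names = list(conds)
    cfg = synth.SimConfig(
        n_individuals=n_individuals,
        n_snps=n_snps,
        n_conditions=len(names),
        prevalences=tuple(conds[c][0] for c in names),
        h2_targets=tuple(conds[c][1] for c in names),
        seed=seed,
    )
    pattern_g = {f: {c: v for c, v in p.items() if c in names}
                 for f, p in DEFAULT_GENETIC_PATTERN.items()}
    pattern_e = {f: {c: v for c, v in p.items() if c in names}
                 for f, p in DEFAULT_ENV_PATTERN.items()}
    model = synth.simulate_true_model(
        cfg, pattern_g, pattern_e,
        phi_genetic=DEFAULT_GENETIC_PHI, phi_env=DEFAULT_ENV_PHI,
        condition_names=names,
    )
    return cfg, model


@dataclass
class PipelineConfig:
    """Serializable pipeline configuration; every stochastic stage draws its
    seed from the master seed via stable hashing."""

    outdir: str = "runs/demo"
    seed: int = 0
    n_individuals: int = 20_000
    n_snps: int = 2_000
    conditions: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEMO_CONDITIONS.items()
    })
    holdout_frac: float = 0.2
    info_min: float = 0.9
    maf_min: float = 0.01
    p_threshold: float = 5e-8
    clump_kb: float = 250.0
    n_perm: int = 1000
    ldsc_blocks: int = 200
    lambda_shrink: float = 0.1
    gwas_covariates: list = field(default_factory=lambda: ["sex", "birth_year", "PC1", "PC2", "PC3", "PC4"])
    stages: dict = field(default_factory=lambda: {
        "gwas": True, "ldsc": True, "phenocorr": True, "factors": True,
        "disparity": True, "gsem": True, "pgi": True,
    })

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("outdir", None)  # identical analyses hash equal wherever written
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.blake2b(blob.encode(), digest_size=6).hexdigest()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def split_train_test(obj, mode: str, seed: int = 0):
    """Disjoint exhaustive split: 50/50 by individuals (cohorts) or odd/even
    chromosomes (sumstats tables; odd chromosomes form the training half)."""
    if mode == "individuals":
        cohort: synth.Cohort = obj
        n = cohort.n_individuals
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        half = n // 2
        return _subset_cohort(cohort, perm[:half]), _subset_cohort(cohort, perm[half:])
    if mode == "chromosomes":
        ss: pd.DataFrame = obj
        odd = ss[ss["CHR"] % 2 == 1].reset_index(drop=True)
        even = ss[ss["CHR"] % 2 == 0].reset_index(drop=True)
        return odd, even
    raise ValueError("mode must be 'individuals' or 'chromosomes'")


def _subset_cohort(cohort: synth.Cohort, rows: np.ndarray) -> synth.Cohort:
    return synth.Cohort(
        dosages=cohort.dosages[rows],
        liabilities_genetic=cohort.liabilities_genetic[rows],
        liabilities_env=cohort.liabilities_env[rows],
        diagnoses=cohort.diagnoses[rows],
        covariates=cohort.covariates.iloc[rows].reset_index(drop=True),
        snp_ids=cohort.snp_ids,
        chromosomes=cohort.chromosomes,
        positions=cohort.positions,
        mafs=cohort.mafs,
        condition_names=cohort.condition_names,
        ld_block_size=cohort.ld_block_size,
    )


def run_pipeline(config: PipelineConfig) -> pathlib.Path:
    """Execute all enabled stages; returns the run directory.

    Every output table carries a header comment with the config hash and
    seed; ``summary.json`` aggregates fit indices, disparity summaries, Q
    summaries, and PGI R^2 values.
    """
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"psychstruct config={config.config_hash()} seed={config.seed}"
    logging.basicConfig(level=logging.INFO)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    stage = "simulate"
    try:
        names = list(config.conditions)
        cfg = synth.SimConfig(
            n_individuals=config.n_individuals,
            n_snps=config.n_snps,
            n_conditions=len(names),
            prevalences=tuple(config.conditions[c][0] for c in names),
            h2_targets=tuple(config.conditions[c][1] for c in names),
            seed=config.stage_seed("simulate"),
        )
        pattern_g, phi_g, pattern_e, phi_e = _patterns_for(names)
        model = synth.simulate_true_model(
            cfg, pattern_g, pattern_e,
            phi_genetic=phi_g, phi_env=phi_e,
            condition_names=names,
        )
        cohort = synth.simulate_cohort(model)
        r_p_true, r_g_true = synth.implied_correlations(model)
        summary["implied_mean_abs_D"] = float(
            np.abs(r_p_true - r_g_true)[~np.eye(len(names), dtype=bool)].mean()
        )

        n_hold = int(config.holdout_frac * cohort.n_individuals)
        rng = np.random.default_rng(config.stage_seed("holdout"))
        perm = rng.permutation(cohort.n_individuals)
        holdout = _subset_cohort(cohort, perm[:n_hold])
        discovery = _subset_cohort(cohort, perm[n_hold:])

        sumstats = {}
        if config.stages.get("gwas", True):
            stage = "gwas"
            for i, cname in enumerate(names):
                ss = assoc.run_gwas(discovery, i, config.gwas_covariates)
                ss = assoc.munge(ss, config.info_min, config.maf_min)
                sumstats[cname] = ss
                assoc.write_sumstats(ss, out / f"gwas_{cname}.tsv", tag)

        gcov = None
        ld = None
        if config.stages.get("ldsc", True) and sumstats:
            stage = "ldsc"
            ld = ldsc.ld_scores(discovery)
            studies = [sumstats[c] for c in names]
            gcov = ldsc.genetic_cov_matrix(
                studies, ld, traits=names, n_blocks=config.ldsc_blocks
            )
            # complete sample overlap: the observed phenotypic correlation is
            # the precise estimate of the cross-trait estimation-error
            # correlation (what the cross-trait intercept measures)
            gcov.error_corr = np.corrcoef(
                discovery.diagnoses.astype(float), rowvar=False
            )
            ldsc.write_genetic_cov(gcov, out / "genetic_S.csv", out / "genetic_V.csv")
            summary["h2_obs"] = {c: float(gcov.S[i, i]) for i, c in enumerate(names)}

        pheno = None
        pheno_train = pheno_test = None
        if config.stages.get("phenocorr", True):
            stage = "phenocorr"
            train, test = split_train_test(
                discovery, "individuals", config.stage_seed("pheno-split")
            )
            pheno_train = phenocorr.corr_matrix(train.diagnoses, names)
            pheno_test = phenocorr.corr_matrix(test.diagnoses, names)
            pheno = pheno_test
            with open(out / "R_p.csv", "w") as fh:
                fh.write(f"# {tag}\n")
                pd.DataFrame(pheno_test.R_p, index=names, columns=names).to_csv(fh)

        fits = {}
        if config.stages.get("factors", True) and pheno_train is not None and gcov is not None:
            stage = "factors"
            n_train = int(np.min(pheno_train.n_matrix))
            n_pa = factor_models.parallel_analysis(
                pheno_train.R_p, n_train, seed=config.stage_seed("parallel")
            )
            n_keep = factor_models.retain_factors(
                pheno_train.R_p, n_train, max_k=min(5, len(names) - 2)
            )
            summary["parallel_analysis_factors"] = n_pa
            summary["retained_factors_phenotypic"] = n_keep
            efa_p = factor_models.efa(
                pheno_train.R_p, n_keep, rotation="oblimin", n=n_train, names=names
            )
            spec_p = factor_models.efa_to_spec(efa_p)

            odd_even = {
                c: split_train_test(sumstats[c], "chromosomes") for c in names
            }
            ld_odd = ldsc.LdScores(
                table=ld.table[ld.table["CHR"] % 2 == 1].reset_index(drop=True),
                window_snps=ld.window_snps, n_ref=ld.n_ref,
            )
            ld_even = ldsc.LdScores(
                table=ld.table[ld.table["CHR"] % 2 == 0].reset_index(drop=True),
                window_snps=ld.window_snps, n_ref=ld.n_ref,
            )
            n_blocks_half = max(30, config.ldsc_blocks // 2)
            gcov_odd = ldsc.genetic_cov_matrix(
                [odd_even[c][0] for c in names], ld_odd, traits=names,
                n_blocks=n_blocks_half,
            )
            gcov_even = ldsc.genetic_cov_matrix(
                [odd_even[c][1] for c in names], ld_even, traits=names,
                n_blocks=n_blocks_half,
            )
            R_g_odd, _ = ldsc.standardized_cov(gcov_odd)
            efa_g = factor_models.efa(
                R_g_odd, min(n_keep, len(names) - 2), rotation="promax",
                n=int(np.nanmin(gcov_odd.n_bar)), names=names,
            )
            spec_g = factor_models.efa_to_spec(efa_g)

            fits["pheno_on_pheno"] = factor_models.fit_cfa(pheno_test, spec_p)
            fits["genetic_on_even"] = factor_models.fit_cfa(gcov_even, spec_g)
            fits["genetic_on_all"] = factor_models.fit_cfa(gcov, spec_g)
            stage = "crosslevel"
            fits["pheno_spec_on_genetic"] = factor_models.cross_level_fit(spec_p, gcov)
            fits["genetic_spec_on_pheno"] = factor_models.cross_level_fit(spec_g, pheno_test)
            summary["fit_indices"] = {
                k: {"cfi": f.cfi, "srmr": f.srmr, "rmsea": f.rmsea, "chi2": f.chi2, "df": f.df}
                for k, f in fits.items()
            }
            match = [(a, a) for a in fits["pheno_on_pheno"].loadings.columns
                     if a in fits["genetic_spec_on_pheno"].loadings.columns]
            if match and sum(
                (fits["pheno_on_pheno"].loadings[a] != 0).sum() for a, _ in match
            ) >= 3:
                summary["loading_correlation_pheno_data"] = factor_models.loading_correlation(
                    fits["pheno_on_pheno"], fits["genetic_spec_on_pheno"], match
                )

        if config.stages.get("disparity", True) and pheno is not None and gcov is not None:
            stage = "disparity"
            R_g, V_std = ldsc.standardized_cov(gcov)
            disp = disparity.disparity(pheno.R_p, R_g, condition_names=names)
            with open(out / "disparity_D.csv", "w") as fh:
                fh.write(f"# {tag}\n")
                disp.to_frame().to_csv(fh)
            neff_vec = np.array([float(sumstats[c]["NEFF"].iloc[0]) for c in names])
            perm = disparity.perm_test(
                disp, neff_vec, n_perm=config.n_perm,
                seed=config.stage_seed("permutation"),
            )
            with open(out / "disparity_permutation.csv", "w") as fh:
                fh.write(f"# {tag} n_perm={config.n_perm} "
                         f"perm_seed={config.stage_seed('permutation')}\n")
                pd.DataFrame({
                    "condition": names,
                    "observed_r": perm.observed_r,
                    "empirical_p": perm.empirical_p,
                }).to_csv(fh, index=False)
            summary["disparity"] = {
                "overall_mean_abs": disp.overall_mean_abs,
                "range": list(disp.range),
                "matrix_correlation": disparity.matrix_correlation(pheno.R_p, R_g),
                "n_perm": config.n_perm,
            }

        factor_scan = {}
        if config.stages.get("gsem", True) and gcov is not None and "genetic_on_all" in fits:
            stage = "gsem"
            g_fit = fits["genetic_on_all"]
            studies = [sumstats[c] for c in names]
            for fac in g_fit.loadings.columns:
                if (g_fit.loadings[fac] != 0).sum() < 2:
                    continue
                scan = gsem.factor_gwas(gcov, g_fit, studies, g_fit.spec, fac)
                gsem.write_factor_gwas(scan, out / f"factor_gwas_{fac}.tsv", tag)
                factor_scan[fac] = scan
                summ = gsem.gwas_summary(scan, config.p_threshold, config.clump_kb)
                summary.setdefault("factor_gwas", {})[fac] = dataclasses.asdict(summ)

        if config.stages.get("pgi", True) and factor_scan:
            stage = "pgi"
            blocks = pgi.ld_block_matrices(discovery)
            covs = holdout.covariates[["birth_year", "sex", "PC1", "PC2", "PC3", "PC4"]]
            scores = {}
            for fac, scan in factor_scan.items():
                blocks_f = pgi.align_blocks(scan, discovery, blocks)
                w = pgi.shrink_weights(scan, blocks_f, config.lambda_shrink, fac)
                raw = pgi.score(holdout, w)
                scores[fac] = pgi.residualize(raw, covs)
            g_fit = fits["genetic_on_all"]
            pred = pgi.predict_latent(scores, holdout.diagnoses, g_fit, names)
            summary["pgi_r2"] = {
                p: {f: float(v) for f, v in
                    pgi.predict_latent({p: s}, holdout.diagnoses, g_fit, names).r2_per_factor.items()}
                for p, s in scores.items()
            }
            summary["pgi_r2_joint"] = {f: float(v) for f, v in pred.r2_per_factor.items()}

        stage = "finalize"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        with open(out / "run.log", "w") as fh:
            fh.write(f"{tag}\nstages={config.stages}\n")
        config.to_yaml(out / "config.yaml")
        return out
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (outputs so far in {out})"
        ) from err
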