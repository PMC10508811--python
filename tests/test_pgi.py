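"""Polygenic indices: shrinkage weights, scoring (with MHC exclusion),
residualization, latent-factor prediction, and covariate-adjusted outcome
regressions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from psychstruct import assoc, factor_models as fm, gsem, ldsc, pgi
from psychstruct.synth import implied_correlations, simulate_cohort
from psychstruct.pipeline import split_train_test

from conftest import make_model


def _toy_ss(weights_z, n=10_000):
    m = len(weights_z)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i}" for i in range(m)],
            "A1": "A",
            "Z": np.asarray(weights_z, dtype=float),
            "N": np.full(m, float(n)),
        }
    )


class TestShrinkWeights:
    def test_identity_ld_no_shrinkage(self):
        ss = _toy_ss([2.0, -1.0, 0.5])
        blocks = [(np.arange(3), np.eye(3))]
        w = pgi.shrink_weights(ss, blocks, lambda_shrink=0.0)
        np.testing.assert_allclose(
            w.table["WEIGHT"], ss["Z"] / np.sqrt(ss["N"]), atol=1e-12
        )

    def test_infinite_shrinkage_kills_weights(self):
        ss = _toy_ss([2.0, -1.0, 0.5])
        blocks = [(np.arange(3), np.eye(3))]
        w = pgi.shrink_weights(ss, blocks, lambda_shrink=1e9)
        assert np.max(np.abs(w.table["WEIGHT"])) < 1e-9

    def test_duplicated_snp_shares_weight(self):
        """Two perfect copies: each receives half the single-SNP weight as
        the ridge penalty vanishes (2x2 closed form)."""
        z = 3.0
        ss2 = _toy_ss([z, z])
        eps = 1e-8
        R = np.array([[1.0, 1.0 - eps], [1.0 - eps, 1.0]])
        blocks = [(np.arange(2), R)]
        w2 = pgi.shrink_weights(ss2, blocks, lambda_shrink=1e-6)
        single = z / np.sqrt(10_000)
        np.testing.assert_allclose(w2.table["WEIGHT"], single / 2, rtol=1e-3)

    def test_singular_block_warns_and_recovers(self):
        ss = _toy_ss([1.0, 1.0])
        R = np.array([[1.0, 1.0], [1.0, 1.0]])  # exactly singular
        blocks = [(np.arange(2), R)]
        with pytest.warns(UserWarning, match="ridge"):
            w = pgi.shrink_weights(ss, blocks, lambda_shrink=0.0)
        assert np.all(np.isfinite(w.table["WEIGHT"]))


class TestScore:
    def test_zero_weights_zero_scores(self, small_cohort):
        table = pd.DataFrame(
            {"SNP": small_cohort.snp_ids, "A1": "A", "WEIGHT": 0.0}
        )
        w = pgi.PgiWeights(table, "F", 0.1)
        s = pgi.score(small_cohort, w)
        assert np.all(s == 0)

    def test_single_snp_weight_is_dosage(self, small_cohort):
        table = pd.DataFrame(
            {"SNP": [small_cohort.snp_ids[5]], "A1": ["A"], "WEIGHT": [1.0]}
        )
        s = pgi.score(small_cohort, pgi.PgiWeights(table, "F", 0.1))
        np.testing.assert_allclose(s, small_cohort.dosages[:, 5])

    def test_linearity(self, small_cohort):
        rng = np.random.default_rng(3)
        w1 = rng.normal(size=small_cohort.n_snps)
        w2 = rng.normal(size=small_cohort.n_snps)

        def mk(w):
            return pgi.PgiWeights(
                pd.DataFrame({"SNP": small_cohort.snp_ids, "A1": "A", "WEIGHT": w}),
                "F", 0.1,
            )

        s1 = pgi.score(small_cohort, mk(w1))
        s2 = pgi.score(small_cohort, mk(w2))
        s12 = pgi.score(small_cohort, mk(w1 + w2))
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-10)

    def test_mhc_exclusion_zeroes_region(self, small_cohort):
        c = small_cohort
        region = pgi.MhcRegion(chromosome=6, start=0, end=10**9)
        w_all = pgi.PgiWeights(
            pd.DataFrame({"SNP": c.snp_ids, "A1": "A", "WEIGHT": 1.0}), "F", 0.1
        )
        s_all = pgi.score(c, w_all)
        s_mhc = pgi.score(c, w_all, exclude_mhc=True, mhc_region=region)
        keep = c.chromosomes != 6
        expect = c.dosages[:, keep].sum(axis=1)
        np.testing.assert_allclose(s_mhc, expect, rtol=1e-6)
        assert not np.allclose(s_all, s_mhc)

    def test_unmatched_weights_error(self, small_cohort):
        table = pd.DataFrame(
            {"SNP": [f"zz{i}" for i in range(100)], "A1": "A", "WEIGHT": 1.0}
        )
        with pytest.raises(ValueError, match="matched"):
            pgi.score(small_cohort, pgi.PgiWeights(table, "F", 0.1))

    def test_true_effect_scores_track_genetic_liability(self, medium_cohort, medium_model):
        """Scoring with the generating SNP effects reproduces the genetic
        liability up to LD/standardization noise."""
        m = medium_model
        c = medium_cohort
        # condition 0's generating per-SNP standardized effects
        lam = m.loadings_std_genetic[0]
        res = np.sqrt(max(m.residual_genetic[0] / m.h2[0], 0.0))
        beta = m.snp_effects[:, : m.n_factors_genetic] @ lam
        beta = beta + m.snp_effects[:, m.n_factors_genetic + 0] * res
        sd = c.dosages.std(axis=0)
        table = pd.DataFrame(
            {"SNP": c.snp_ids, "A1": "A", "WEIGHT": beta / np.where(sd > 0, sd, 1)}
        )
        s = pgi.score(c, pgi.PgiWeights(table, "C1", 0.0))
        r = np.corrcoef(s, c.liabilities_genetic[:, 0])[0, 1]
        assert r > 0.9


class TestResidualize:
    def test_orthogonal_covariates_no_change(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=2_000)
        cov = pd.DataFrame({"a": rng.normal(size=2_000)})
        out = pgi.residualize(s, cov)
        z = (s - s.mean()) / s.std()
        assert np.corrcoef(out, z)[0, 1] > 0.999

    def test_pure_covariate_function_gives_zero(self):
        rng = np.random.default_rng(6)
        cov = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        s = 2 * cov["a"] - cov["b"] + 3
        out = pgi.residualize(s.to_numpy(), cov)
        assert np.std(s.to_numpy() - s.mean()) > 0
        assert np.allclose(out, 0.0) or np.std(out) == pytest.approx(1.0)
        # residuals themselves are numerically zero before standardization
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(500), cov]), s, rcond=None
        )[0]
        assert np.allclose(s - np.column_stack([np.ones(500), cov]) @ beta, 0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(7)
        cov = pd.DataFrame({c: rng.normal(size=1_000) for c in "abc"})
        s = rng.normal(size=1_000) + cov["a"].to_numpy()
        out = pgi.residualize(s, cov)
        for c in "abc":
            assert abs(np.dot(out, cov[c] - cov[c].mean())) < 1e-8 * 1_000

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank"):
            pgi.residualize(rng.normal(size=100), cov)


@pytest.fixture(scope="module")
def holdout_bundle():
    model = make_model(n=20_000, m=800, seed=81, decoupled=False)
    cohort = simulate_cohort(model)
    names = model.condition_names
    spec = fm.ModelSpec(factors={
        "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
    })
    _, r_g = implied_correlations(model)
    fit = fm.fit_cfa((r_g, names), spec, n_eff=20_000)
    return model, cohort, fit


class TestPredictLatent:
    def test_null_weights_predict_nothing(self, holdout_bundle):
        model, cohort, fit = holdout_bundle
        rng = np.random.default_rng(9)
        noise = rng.normal(size=cohort.n_individuals)
        pred = pgi.predict_latent(
            {"null": noise}, cohort.diagnoses, fit, cohort.condition_names
        )
        assert all(v < 0.01 for v in pred.r2_per_factor.values())

    def test_cognate_factor_specificity(self, holdout_bundle):
        """A score built from the first factor's generating SNP effects
        explains more of its cognate factor than of the others."""
        model, cohort, fit = holdout_bundle
        sd = cohort.dosages.std(axis=0)
        beta = model.snp_effects[:, 0]  # TD factor effects
        table = pd.DataFrame(
            {"SNP": cohort.snp_ids, "A1": "A",
             "WEIGHT": beta / np.where(sd > 0, sd, 1)}
        )
        s = pgi.score(cohort, pgi.PgiWeights(table, "TD", 0.0))
        pred = pgi.predict_latent(
            {"TD_pgi": s}, cohort.diagnoses, fit, cohort.condition_names
        )
        r2 = pred.r2_per_factor
        assert r2["TD"] > r2["INT"]
        assert r2["TD"] > r2["COMP"]
        assert r2["TD"] > 0.05

    def test_r2_invariant_to_other_factor_relabeling(self, holdout_bundle):
        model, cohort, fit = holdout_bundle
        rng = np.random.default_rng(10)
        s = rng.normal(size=cohort.n_individuals) + cohort.liabilities_genetic[:, 0]
        pred_a = pgi.predict_latent(
            {"s": s}, cohort.diagnoses, fit, cohort.condition_names
        )
        # swap the INT and COMP labels (and their indicator blocks)
        names = cohort.condition_names
        spec_sw = fm.ModelSpec(factors={
            "TD": names[0:2], "COMP": names[4:6], "INT": names[2:4],
        })
        _, r_g = implied_correlations(model)
        fit_sw = fm.fit_cfa((r_g, names), spec_sw, n_eff=20_000)
        pred_b = pgi.predict_latent(
            {"s": s}, cohort.diagnoses, fit_sw, cohort.condition_names
        )
        assert pred_a.r2_per_factor["TD"] == pytest.approx(
            pred_b.r2_per_factor["TD"], abs=1e-6
        )


def _pgi_chain(model_pat, phi, n, m, seed, outcome_factor="INT", spec_factors=None):
    """simulate -> GWAS (train half) -> factor scan -> shrink -> score the
    holdout; returns (domain scores dict, p score, holdout, 3-factor fit)."""
    from psychstruct import assoc, gsem, ldsc
    from psychstruct.pipeline import split_train_test
    from psychstruct.synth import SimConfig, simulate_true_model

    cfg = SimConfig(
        n_individuals=n, n_snps=m, n_conditions=6,
        prevalences=(0.25, 0.20, 0.25, 0.20, 0.25, 0.20),
        h2_targets=(0.45, 0.40, 0.45, 0.40, 0.45, 0.40), seed=seed,
    )
    model = simulate_true_model(cfg, model_pat, model_pat,
                                phi_genetic=phi, phi_env=phi)
    cohort = simulate_cohort(model)
    train, hold = split_train_test(cohort, "individuals", seed=seed)
    studies = assoc.run_gwas_multi(train, range(6))
    ld = ldsc.ld_scores(train)
    gcov = ldsc.genetic_cov_matrix(
        studies, ld, traits=train.condition_names, n_blocks=40
    )
    gcov.error_corr = np.corrcoef(train.diagnoses.astype(float), rowvar=False)
    names = gcov.traits
    factors = spec_factors or {
        "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
    }
    fit3 = fm.fit_cfa(gcov, fm.ModelSpec(factors=factors))
    fit1 = fm.fit_cfa(gcov, fm.ModelSpec(factors={"p": list(names)}))
    blocks = pgi.ld_block_matrices(train)

    def build(scan):
        w = pgi.shrink_weights(scan, pgi.align_blocks(scan, train, blocks), 0.2)
        return pgi.score(hold, w)

    domain = {
        f: build(gsem.factor_gwas(gcov, fit3, studies, fit3.spec, f))
        for f in factors
    }
    p_score = build(gsem.factor_gwas(gcov, fit1, studies, fit1.spec, "p"))
    return domain, p_score, hold, fit3


PAT_DISTINCT = {
    "TD": {0: 0.9, 1: 0.85}, "INT": {2: 0.9, 3: 0.85}, "COMP": {4: 0.9, 5: 0.85},
}
PHI_WEAK = np.array([[1.0, 0.2, 0.15], [0.2, 1.0, 0.2], [0.15, 0.2, 1.0]])


class TestTrainingSizeAndReversal:
    def test_r2_nondecreasing_in_training_n(self):
        """Mean cognate R2 grows with GWAS training sample size (3-point
        sweep, averaged over seeds)."""
        means = []
        for n in (2_000, 8_000, 20_000):
            r2s = []
            for seed in range(4):
                domain, _, hold, fit3 = _pgi_chain(
                    PAT_DISTINCT, PHI_WEAK, n, 800, 9000 + seed
                )
                pred = pgi.predict_latent(
                    {"INT": domain["INT"]}, hold.diagnoses, fit3,
                    hold.condition_names,
                )
                r2s.append(pred.r2_per_factor["INT"])
            means.append(np.mean(r2s))
        assert means[0] <= means[1] <= means[2]

    def test_pure_general_factor_gives_no_increment(self):
        """When generation is a single general factor, domain PGIs carry no
        information beyond the p-factor PGI."""
        # joint R2 over three correlated PGIs carries an O(1/n_holdout)
        # upward fit bias, so the check runs at a holdout large enough for
        # that bias to sit inside the 0.05 band
        pat_general = {"p": {i: 0.85 for i in range(6)}}
        phi1 = np.eye(1)
        deltas = []
        for seed in range(3):
            domain, p_score, hold, fit3 = _pgi_chain(
                pat_general, phi1, 30_000, 800, 9500 + seed
            )
            delta = pgi.incremental_r2(
                domain, p_score, hold.diagnoses, fit3,
                hold.condition_names, "INT",
            )
            deltas.append(delta)
        assert abs(np.mean(deltas)) < 0.05


class TestOutcomeAssoc:
    def test_outcome_equals_score_beta_one(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=1_000)
        beta, se = pgi.outcome_assoc(s, s.copy())
        assert beta == pytest.approx(1.0, abs=1e-10)

    def test_independent_outcome_beta_near_zero(self):
        rng = np.random.default_rng(12)
        s = rng.normal(size=5_000)
        y = rng.normal(size=5_000)
        age = rng.uniform(40, 70, size=5_000)
        sex = rng.integers(0, 2, size=5_000)
        beta, se = pgi.outcome_assoc(s, y, age, sex)
        assert abs(beta) < 3 * se + 0.01

    def test_orthogonal_covariates_leave_beta(self):
        rng = np.random.default_rng(13)
        s = rng.normal(size=20_000)
        y = 0.3 * s + rng.normal(size=20_000)
        b0, _ = pgi.outcome_assoc(s, y)
        age = rng.uniform(40, 70, size=20_000)
        sex = rng.integers(0, 2, size=20_000)
        b1, _ = pgi.outcome_assoc(s, y, age, sex)
        # covariates independent of both variables barely move the estimate
        assert b1 == pytest.approx(b0, abs=0.02)
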