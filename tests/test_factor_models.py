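"""EFA (parallel analysis, principal-axis factoring, rotations, retention)
and DWLS CFA (fit indices, cross-level transfer, loading correlations)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from psychstruct import factor_models as fm
from psychstruct.synth import implied_correlations

from conftest import make_model


def _single_factor_R(loadings):
    lam = np.asarray(loadings)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


def _three_block_R(lam=0.7, between=0.3, k_per=3):
    """Three-factor simple structure: blocks of k_per indicators."""
    k = 3 * k_per
    L = np.zeros((k, 3))
    for f in range(3):
        L[f * k_per : (f + 1) * k_per, f] = lam
    Phi = np.full((3, 3), between)
    np.fill_diagonal(Phi, 1.0)
    R = L @ Phi @ L.T
    np.fill_diagonal(R, 1.0)
    return R


class TestParallelAnalysis:
    def test_identity_retains_zero(self):
        assert fm.parallel_analysis(np.eye(8), n=5_000, seed=1) == 0

    def test_single_factor_retains_one(self):
        R = _single_factor_R([0.8] * 6)
        assert fm.parallel_analysis(R, n=10_000, seed=2) == 1

    def test_three_block_structure_retains_three(self):
        R = _three_block_R()
        assert fm.parallel_analysis(R, n=10_000, seed=3) == 3


class TestEfa:
    def test_single_factor_loadings_recovered(self):
        R = _single_factor_R([0.7] * 5)
        sol = fm.efa(R, 1, n=5_000)
        np.testing.assert_allclose(sol.loadings.to_numpy().ravel(), 0.7, atol=1e-3)
        assert sol.rmsea < 0.005

    def test_rotations_agree_on_assignment(self):
        R = _three_block_R(lam=0.75, between=0.35)
        obl = fm.efa(R, 3, rotation="oblimin", n=10_000)
        pro = fm.efa(R, 3, rotation="promax", n=10_000)
        a_obl = np.argmax(np.abs(obl.loadings.to_numpy()), axis=1)
        a_pro = np.argmax(np.abs(pro.loadings.to_numpy()), axis=1)
        # same partition of indicators into factors
        for a in (a_obl, a_pro):
            groups = [tuple(np.where(a == f)[0]) for f in sorted(set(a))]
            assert sorted(groups) == [(0, 1, 2), (3, 4, 5), (6, 7, 8)]

    def test_communalities_invariant_under_rotation(self):
        R = _three_block_R()
        for rot in ("oblimin", "promax"):
            sol = fm.efa(R, 3, rotation=rot, n=10_000)
            L = sol.loadings.to_numpy()
            comm_rot = np.diag(L @ sol.factor_corr @ L.T)
            np.testing.assert_allclose(comm_rot, sol.communalities, atol=1e-6)

    def test_recovers_generating_genetic_structure(self):
        """EFA on the implied genetic correlation matrix assigns indicators
        to their generating factors (congruence via max loading)."""
        model = make_model(n=1000, m=400, seed=9)
        _, r_g = implied_correlations(model)
        sol = fm.efa(r_g, 3, rotation="promax", n=50_000)
        a = np.argmax(np.abs(sol.loadings.to_numpy()), axis=1)
        # generating blocks: (0,1), (2,3), (4,5)
        assert a[0] == a[1] and a[2] == a[3] and a[4] == a[5]
        assert len({a[0], a[2], a[4]}) == 3
        # per-factor congruence with the generating standardized loadings
        Lg = model.loadings_std_genetic
        L = sol.loadings.to_numpy()
        for gen_f, inds in enumerate([(0, 1), (2, 3), (4, 5)]):
            est_f = a[inds[0]]
            x = Lg[list(inds), gen_f]
            y = L[list(inds), est_f]
            congruence = abs(x @ y) / np.sqrt((x @ x) * (y @ y))
            assert congruence > 0.95

    def test_sign_convention(self):
        R = _single_factor_R([0.7, 0.7, -0.7, 0.7])
        sol = fm.efa(R, 1, n=5_000)
        L = sol.loadings.to_numpy().ravel()
        assert np.max(np.abs(L)) == pytest.approx(abs(L).max())
        assert L[np.argmax(np.abs(L))] > 0


class TestRetainFactors:
    def test_identity_like_retains_one(self):
        rng = np.random.default_rng(4)
        R = np.eye(6) + 0.01 * rng.standard_normal((6, 6))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 1.0)
        assert fm.retain_factors(R, n=5_000, max_k=4) == 1

    def test_three_block_retains_three(self):
        R = _three_block_R(lam=0.75, between=0.25)
        assert fm.retain_factors(R, n=10_000, max_k=4) == 3

    def test_never_far_above_parallel_analysis(self):
        """Retention by dRMSEA/dR2 stays within one factor of parallel
        analysis on random low-rank constructions."""
        rng = np.random.default_rng(5)
        for trial in range(20):
            m_true = int(rng.integers(1, 4))
            k = 9
            L = np.zeros((k, m_true))
            for i in range(k):
                L[i, rng.integers(0, m_true)] = rng.uniform(0.6, 0.85)
            R = L @ L.T
            np.fill_diagonal(R, 1.0)
            pa = fm.parallel_analysis(R, n=10_000, seed=100 + trial)
            kept = fm.retain_factors(R, n=10_000, max_k=5)
            assert kept <= pa + 1


class TestFitCfa:
    def test_saturated_single_factor_recovery(self):
        R = _single_factor_R([0.7] * 4)
        spec = fm.ModelSpec(factors={"F": ["C1", "C2", "C3", "C4"]})
        fit = fm.fit_cfa((R, ["C1", "C2", "C3", "C4"]), spec, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings["F"], 0.7, atol=1e-4)
        assert fit.chi2 < 1e-6
        assert fit.srmr < 1e-6
        assert fit.cfi == pytest.approx(1.0)
        assert not fit.heywood_flags

    def test_matches_brute_force_dwls_minimum(self):
        """Solution equals an independent numeric minimization of the same
        weighted least squares objective on a 4-indicator toy."""
        rng = np.random.default_rng(11)
        lam_true = np.array([0.8, 0.7, 0.6, 0.5])
        R = _single_factor_R(lam_true)
        noise = rng.uniform(-0.03, 0.03, size=(4, 4))
        R = R + (noise + noise.T) / 2
        np.fill_diagonal(R, 1.0)
        names = ["A", "B", "C", "D"]
        n_eff = 5_000
        fit = fm.fit_cfa((R, names), fm.ModelSpec(factors={"F": names}), n_eff=n_eff)

        pairs = [(i, j) for i in range(4) for j in range(i)]
        w = (n_eff - 1) / (1.0 - np.array([R[i, j] for i, j in pairs]) ** 2) ** 2

        def objective(lam):
            resid = [R[i, j] - lam[i] * lam[j] for i, j in pairs]
            return np.sum(w * np.asarray(resid) ** 2)

        best = None
        for start in ([0.5] * 4, [0.9] * 4, [0.3, 0.9, 0.5, 0.7]):
            res = minimize(objective, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20_000})
            if best is None or res.fun < best.fun:
                best = res
        np.testing.assert_allclose(
            np.abs(fit.loadings["F"].to_numpy()), np.abs(best.x), atol=1e-4
        )
        assert fit.objective == pytest.approx(best.fun, abs=1e-6)

    def test_recovers_generating_loadings_three_factor(self):
        model = make_model(n=1000, m=400, seed=13)
        _, r_g = implied_correlations(model)
        names = model.condition_names
        spec = fm.ModelSpec(factors={
            "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
        })
        fit = fm.fit_cfa((r_g, names), spec, n_eff=50_000)
        Lg = model.loadings_std_genetic
        got = np.array([
            fit.loadings.loc[names[i], f]
            for f, idxs in zip(["TD", "INT", "COMP"], [(0, 1), (2, 3), (4, 5)])
            for i in idxs
        ])
        want = np.array([Lg[i, f] for f, idxs in enumerate([(0, 1), (2, 3), (4, 5)]) for i in idxs])
        np.testing.assert_allclose(got, want, atol=0.01)
        # factor correlations recovered too
        np.testing.assert_allclose(
            fit.factor_corr.to_numpy(), model.phi_genetic, atol=0.01
        )

    def test_indicator_reordering_invariance(self):
        R = _three_block_R(lam=0.7, between=0.3, k_per=2)
        names = [f"C{i}" for i in range(6)]
        spec = fm.ModelSpec(factors={"A": names[0:2], "B": names[2:4], "C": names[4:6]})
        fit1 = fm.fit_cfa((R, names), spec, n_eff=10_000)
        perm = [3, 1, 5, 0, 4, 2]
        R2 = R[np.ix_(perm, perm)]
        names2 = [names[i] for i in perm]
        fit2 = fm.fit_cfa((R2, names2), spec, n_eff=10_000)
        assert fit1.chi2 == pytest.approx(fit2.chi2, abs=1e-8)
        assert fit1.cfi == pytest.approx(fit2.cfi, abs=1e-8)
        assert fit1.srmr == pytest.approx(fit2.srmr, abs=1e-8)

    def test_second_order_model(self):
        # strong general factor over three correlated domains
        gamma = np.array([0.8, 0.7, 0.75])
        Phi = np.outer(gamma, gamma)
        np.fill_diagonal(Phi, 1.0)
        k_per = 2
        L = np.zeros((6, 3))
        for f in range(3):
            L[f * k_per : (f + 1) * k_per, f] = 0.7
        R = L @ Phi @ L.T
        np.fill_diagonal(R, 1.0)
        names = [f"C{i}" for i in range(6)]
        spec = fm.ModelSpec(
            factors={"A": names[0:2], "B": names[2:4], "C": names[4:6]},
            second_order="p",
        )
        fit = fm.fit_cfa((R, names), spec, n_eff=10_000)
        got = np.sort(np.abs(list(fit.second_order_loadings.values())))
        np.testing.assert_allclose(got, np.sort(gamma), atol=0.01)

    def test_bifactor_with_equality_constraints(self):
        L_gen = np.full(6, 0.6)
        L_spec = np.zeros((6, 3))
        L_spec[0:2, 0] = 0.5
        L_spec[2:4, 1] = 0.5
        L_spec[4:6, 2] = 0.5
        R = np.outer(L_gen, L_gen) + L_spec @ L_spec.T
        np.fill_diagonal(R, 1.0)
        names = [f"C{i}" for i in range(6)]
        spec = fm.ModelSpec(
            factors={"A": names[0:2], "B": names[2:4], "C": names[4:6]},
            bifactor=True,
            equality_constraints=[
                [("A", "C0"), ("A", "C1")],
                [("B", "C2"), ("B", "C3")],
                [("C", "C4"), ("C", "C5")],
            ],
        )
        fit = fm.fit_cfa((R, names), spec, n_eff=10_000)
        np.testing.assert_allclose(fit.loadings["general"], 0.6, atol=0.02)
        assert fit.loadings.loc["C0", "A"] == pytest.approx(
            fit.loadings.loc["C1", "A"], abs=1e-10
        )
        np.testing.assert_allclose(abs(fit.loadings.loc["C0", "A"]), 0.5, atol=0.02)

    def test_heywood_case_flagged(self):
        # a wildly inconsistent matrix forces communality > 1 for C0
        R = np.array([
            [1.0, 0.95, 0.9, 0.2],
            [0.95, 1.0, 0.5, 0.1],
            [0.9, 0.5, 1.0, 0.1],
            [0.2, 0.1, 0.1, 1.0],
        ])
        names = ["C0", "C1", "C2", "C3"]
        fit = fm.fit_cfa((R, names), fm.ModelSpec(factors={"F": names}), n_eff=2_000)
        if fit.heywood_flags:  # flagged, never silently truncated
            assert np.min(fit.residuals) < 0


class TestCrossLevel:
    def test_self_fit_passes_cutoffs(self):
        model = make_model(n=1000, m=400, seed=17)
        _, r_g = implied_correlations(model)
        names = model.condition_names
        spec = fm.ModelSpec(factors={
            "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
        })
        fit = fm.cross_level_fit(spec, (r_g, names), n_eff=50_000)
        assert fit.cfi > 0.95
        assert fit.srmr < 0.08

    def test_merged_factor_correlation_inflates_on_decoupled_data(self):
        """Fitting the genetic-level model to strongly decoupled phenotypic
        data drives the merged factors' correlation above its generating
        genetic value."""
        model = make_model(n=1000, m=400, seed=19, decoupled=True)
        r_p, r_g = implied_correlations(model)
        names = model.condition_names
        spec_g = fm.ModelSpec(factors={
            "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
        })
        fit_p = fm.cross_level_fit(spec_g, (r_p, names), n_eff=50_000)
        phi_fit = abs(fit_p.factor_corr.loc["INT", "COMP"])
        phi_gen = model.phi_genetic[1, 2]
        assert phi_fit > phi_gen + 0.1

    def test_extra_residual_corr_never_hurts_fit(self):
        """Nesting: freeing a residual correlation never increases the DWLS
        discrepancy (chi2); CFI may dip by at most its one-df penalty."""
        rng = np.random.default_rng(23)
        for trial in range(10):
            model = make_model(n=1000, m=400, seed=400 + trial)
            r_p, _ = implied_correlations(model)
            noise = rng.uniform(-0.02, 0.02, size=r_p.shape)
            R = r_p + (noise + noise.T) / 2
            np.fill_diagonal(R, 1.0)
            names = model.condition_names
            spec = fm.ModelSpec(factors={
                "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
            })
            base = fm.fit_cfa((R, names), spec, n_eff=20_000)
            extra = fm.cross_level_fit(
                spec, (R, names), extra_residual_corrs=[(names[4], names[5])],
                n_eff=20_000, start=base.theta,
            )
            assert extra.chi2 <= base.chi2 + 1e-6
            assert extra.cfi >= base.cfi - 1e-3


class TestLoadingCorrelation:
    def _fit(self, R, names, seed=0):
        spec = fm.ModelSpec(factors={
            "TD": names[0:2], "INT": names[2:4], "COMP": names[4:6],
        })
        return fm.fit_cfa((R, names), spec, n_eff=20_000)

    def test_identical_fits_correlate_one(self):
        model = make_model(n=1000, m=400, seed=29)
        _, r_g = implied_correlations(model)
        fit = self._fit(r_g, model.condition_names)
        r = fm.loading_correlation(fit, fit, [("TD", "TD"), ("INT", "INT"), ("COMP", "COMP")])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_aligned_by_default(self):
        model = make_model(n=1000, m=400, seed=29)
        _, r_g = implied_correlations(model)
        fit_a = self._fit(r_g, model.condition_names)
        import copy

        fit_b = copy.deepcopy(fit_a)
        fit_b.loadings["TD"] = -fit_b.loadings["TD"]
        r = fm.loading_correlation(fit_a, fit_b, [("TD", "TD"), ("INT", "INT")])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_two_seeds_same_model_highly_consistent(self):
        """Two cohorts from one generating model yield near-identical
        loading patterns. The generating loadings are spread out so the
        correlation reflects pattern recovery, not estimation noise on a
        constant vector."""
        from psychstruct import phenocorr, synth
        from conftest import PHI_E3, PHI_G3

        # ten conditions; the internalizing-style factor carries six
        # indicators with spread loadings, as in biobank-scale models
        pattern = {
            "TD": {0: 0.85, 1: 0.65},
            "INT": {2: 0.80, 3: 0.45, 4: 0.70, 5: 0.55, 6: 0.65, 7: 0.35},
            "COMP": {8: 0.75, 9: 0.50},
        }
        fits = []
        for seed in (31, 37):
            cfg = synth.SimConfig(
                n_individuals=50_000, n_snps=400, n_conditions=10,
                prevalences=(0.20, 0.10, 0.15, 0.12, 0.08, 0.05, 0.10, 0.03, 0.06, 0.04),
                h2_targets=(0.40, 0.30, 0.30, 0.25, 0.35, 0.30, 0.25, 0.20, 0.35, 0.30),
                seed=seed,
            )
            model = synth.simulate_true_model(
                cfg, pattern, pattern, phi_genetic=PHI_G3, phi_env=PHI_E3
            )
            cohort = synth.simulate_cohort(model)
            pm = phenocorr.corr_matrix(cohort.diagnoses, cohort.condition_names)
            names = model.condition_names
            spec = fm.ModelSpec(factors={
                "TD": names[0:2], "INT": names[2:8], "COMP": names[8:10],
            })
            fits.append(fm.fit_cfa(pm, spec))
        r = fm.loading_correlation(
            fits[0], fits[1], [("TD", "TD"), ("INT", "INT"), ("COMP", "COMP")]
        )
        assert r > 0.95

    def test_too_few_loadings_error(self):
        model = make_model(n=1000, m=400, seed=29)
        _, r_g = implied_correlations(model)
        fit = self._fit(r_g, model.condition_names)
        with pytest.raises(ValueError, match="fewer than 3"):
            fm.loading_correlation(fit, fit, [("TD", "TD")])


class TestModelSpecIO:
    def test_yaml_round_trip(self, tmp_path):
        spec = fm.ModelSpec(
            factors={"A": ["C1", "C2"], "B": ["C3", "C4", "C5"]},
            residual_corrs=[("C1", "C3")],
            equality_constraints=[[("A", "C1"), ("A", "C2")]],
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = fm.ModelSpec.from_yaml(path)
        assert back.factors == spec.factors
        assert back.residual_corrs == spec.residual_corrs
        assert back.equality_constraints == spec.equality_constraints

    def test_unidentified_spec_rejected(self):
        with pytest.raises(ValueError, match="identified"):
            fm.ModelSpec(factors={"A": ["C1"]})

    def test_efa_to_spec_partitions_indicators(self):
        R = _three_block_R(lam=0.75, between=0.3)
        sol = fm.efa(R, 3, n=10_000, names=[f"C{i}" for i in range(9)])
        spec = fm.efa_to_spec(sol)
        all_inds = sorted(i for v in spec.factors.values() for i in v)
        assert all_inds == sorted(f"C{i}" for i in range(9))
        assert all(len(v) == 3 for v in spec.factors.values())
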