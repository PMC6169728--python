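import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from genfactor.polycor import PolychoricMatrix, mixed_correlation_matrix
from genfactor.sem import (
    _rmsea,
    build_model,
    count_free_parameters,
    fit_dwls,
    nested_difference_test,
    regress_latents,
    sandwich_se,
)
from genfactor.simulate import SimulationConfig, simulate_cohort
from tests.conftest import factor_map


def synthetic_moments(labels, matrix, n_ordinal, n=1000):
    return PolychoricMatrix.from_correlations(labels, matrix, n_ordinal, n)


def atac_design():
    sizes = {"IA": 9, "HI": 10, "ASD": 17, "LD": 3, "ODD": 5, "CD": 5,
             "DEP": 5, "ANX": 8}
    return {f: [f"{f}_{k}" for k in range(m)] for f, m in sizes.items()}


class TestModelBuilding:
    def test_two_factor_parameter_count(self):
        spec = build_model({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]},
                           general=False)
        assert spec.n_free == 7  # 6 loadings + 1 disturbance correlation

    def test_general_factor_adds_item_loadings(self):
        spec = build_model({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]},
                           general=True)
        assert spec.n_free == 13

    def test_questionnaire_configuration_df_difference(self):
        """62 items, 8 factors, 9 covariates: the general-factor model has
        62 + 9 = 71 more free parameters, hence 71 fewer df."""
        covs = ["prs", "sex", "age"] + [f"pc{i+1}" for i in range(6)]
        cf = build_model(atac_design(), general=False, covariates=covs)
        gf = build_model(atac_design(), general=True, covariates=covs)
        nf_cf, df_cf = count_free_parameters(cf)
        nf_gf, df_gf = count_free_parameters(gf)
        assert nf_gf - nf_cf == 71
        assert df_cf - df_gf == 71
        assert df_cf == 2287
        assert df_gf == 2216

    def test_just_identified_one_factor(self):
        spec = build_model({"F": ["a", "b", "c"]}, general=False)
        _, df = count_free_parameters(spec)
        assert df == 0

    def test_double_assignment_rejected(self):
        with pytest.raises(ValueError, match="both"):
            build_model({"A": ["x", "y"], "B": ["x", "z"]}, general=False)

    def test_under_identified_rejected(self):
        with pytest.raises(ValueError, match="under-identified"):
            build_model({"A": ["a", "b"]}, general=True)


class TestExactRecovery:
    def test_one_factor_loadings(self):
        mat = np.full((3, 3), 0.36)
        np.fill_diagonal(mat, 1.0)
        mom = synthetic_moments(["a", "b", "c"], mat, 3)
        fit = fit_dwls(build_model({"F": ["a", "b", "c"]}, False), mom)
        assert fit.loadings["specific"].to_numpy() == pytest.approx(
            [0.6, 0.6, 0.6], abs=1e-5
        )
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-9)

    def test_two_factor_with_correlation(self):
        lam, r = 0.7, 0.5
        m = np.eye(6)
        for i in range(3):
            for j in range(3):
                if i != j:
                    m[i, j] = m[3 + i, 3 + j] = lam * lam
                m[i, 3 + j] = m[3 + j, i] = lam * lam * r
        labels = [f"x{i}" for i in range(6)]
        spec = build_model({"A": labels[:3], "B": labels[3:]}, False)
        fit = fit_dwls(spec, synthetic_moments(labels, m, 6))
        assert fit.loadings["specific"].to_numpy() == pytest.approx(
            [lam] * 6, abs=1e-5
        )
        assert fit.psi.loc["A", "B"] == pytest.approx(r, abs=1e-5)
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-9)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0

    def test_discrepancy_invariant_to_item_reordering(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items)
        spec = build_model({"IA": items[:3], "HI": items[3:]}, False)
        fit1 = fit_dwls(spec, mom)
        perm_items = ["HI1", "HI2", "HI3", "IA1", "IA2", "IA3"]
        mom2 = mixed_correlation_matrix(cohort, ordinal=perm_items)
        spec2 = build_model({"HI": perm_items[:3], "IA": perm_items[3:]}, False)
        fit2 = fit_dwls(spec2, mom2)
        assert fit1.discrepancy == pytest.approx(fit2.discrepancy, rel=1e-6)

    def test_sign_indeterminacy_resolved_positive(self):
        mat = np.full((3, 3), 0.36)
        np.fill_diagonal(mat, 1.0)
        mom = synthetic_moments(["a", "b", "c"], mat, 3)
        fit = fit_dwls(build_model({"F": ["a", "b", "c"]}, False), mom)
        assert (fit.loadings["specific"] > 0).all()


class TestNesting:
    def test_general_fixed_to_zero_reproduces_correlated_fit(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items)
        fmap = {"IA": items[:3], "HI": items[3:]}
        fit_cf = fit_dwls(build_model(fmap, False), mom)
        gf = build_model(fmap, True)
        fixed = {f"lambda_g[{it}]": 0.0 for it in items}
        fit_gf0 = fit_dwls(gf, mom, fixed=fixed)
        assert fit_gf0.discrepancy == pytest.approx(fit_cf.discrepancy, rel=1e-6)

    def test_identical_models_rejected(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items)
        fit = fit_dwls(build_model({"IA": items[:3], "HI": items[3:]}, False), mom)
        with pytest.raises(ValueError, match="nested"):
            nested_difference_test(fit, fit)

    def test_power_when_general_factor_present(self, small_cohort):
        """With generating general loadings ~0.3-0.85 the nested comparison
        must detect the general factor decisively."""
        cfg, cohort, *_ = small_cohort
        covs = ["prs_true", "sex", "age"]
        mom = mixed_correlation_matrix(cohort, ordinal=cfg.items, continuous=covs)
        fmap = factor_map(cfg)
        clu = cohort["family_id"].to_numpy()
        fit_c = fit_dwls(build_model(fmap, False, covs), mom, clusters=clu)
        fit_g = fit_dwls(build_model(fmap, True, covs), mom, clusters=clu)
        nt = nested_difference_test(fit_c, fit_g)
        assert nt.delta_df == len(cfg.items) + len(covs)
        assert nt.p_value < 0.05


class TestRegression:
    def test_standardized_beta_invariant_to_prs_scale(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        covs = ["prs_true", "sex"]
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        fmap = {"IA": items[:3], "HI": items[3:]}
        mom1 = mixed_correlation_matrix(cohort, ordinal=items, continuous=covs)
        doubled = cohort.assign(prs_true=2.0 * cohort["prs_true"])
        mom2 = mixed_correlation_matrix(doubled, ordinal=items, continuous=covs)
        b1 = regress_latents(build_model(fmap, False, covs), mom1)
        b2 = regress_latents(build_model(fmap, False, covs), mom2)
        assert b1["beta"].to_numpy() == pytest.approx(
            b2["beta"].to_numpy(), abs=1e-6
        )

    def test_collinear_covariates_rejected(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        cohort = cohort.assign(prs_copy=cohort["prs_true"] * 1.0000001)
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(
            cohort, ordinal=items, continuous=["prs_true", "prs_copy"]
        )
        spec = build_model({"IA": items[:3], "HI": items[3:]}, False,
                           ["prs_true", "prs_copy"])
        with pytest.raises(ValueError, match="collinear"):
            fit_dwls(spec, mom)


class TestSandwich:
    def test_singleton_clusters_match_naive(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items,
                                       continuous=["prs_true"])
        spec = build_model({"IA": items[:3], "HI": items[3:]}, False,
                           ["prs_true"])
        fit = fit_dwls(spec, mom)
        naive = sandwich_se(fit, None)
        singly = sandwich_se(fit, np.arange(len(cohort)))
        ratio = (singly / naive).to_numpy()
        assert np.all((0.9 < ratio) & (ratio < 1.1))

    def test_duplicating_families_shrinks_naive_not_clustered(self, small_cohort):
        """Duplicating every family doubles apparent information; the
        cluster sandwich must not be fooled while naive errors shrink."""
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        covs = ["prs_true"]
        spec = build_model({"IA": items[:3], "HI": items[3:]}, False, covs)

        mom = mixed_correlation_matrix(cohort, ordinal=items, continuous=covs)
        fit = fit_dwls(spec, mom)
        se_clu = sandwich_se(fit, cohort["family_id"].to_numpy())

        doubled = pd.concat([cohort, cohort], ignore_index=True)
        mom2 = mixed_correlation_matrix(doubled, ordinal=items, continuous=covs)
        fit2 = fit_dwls(spec, mom2)
        se_naive2 = sandwich_se(fit2, None)
        se_clu2 = sandwich_se(fit2, doubled["family_id"].to_numpy())

        name = "beta[IA,prs_true]"
        # clustered SE is stable under duplication; naive drops by ~sqrt(2)
        assert se_clu2[name] == pytest.approx(se_clu[name], rel=0.05)
        assert se_naive2[name] < 0.8 * se_clu2[name]

    def test_unknown_cluster_alignment_rejected(self, small_cohort):
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items)
        fit = fit_dwls(build_model({"IA": items[:3], "HI": items[3:]}, False), mom)
        with pytest.raises(ValueError, match="align"):
            sandwich_se(fit, np.arange(10))


class TestFitIndices:
    def test_rmsea_ci_matches_root_search(self):
        """CI from noncentral-chi2 inversion equals a brute-force root
        search of the noncentral CDF."""
        chi2, df, n = 180.0, 120, 2000
        rmsea, (lo, hi) = _rmsea(chi2, df, n)

        def search(prob):
            lam_grid = np.linspace(0, 400, 400_001)
            cdf = stats.ncx2.cdf(chi2, df, lam_grid)
            idx = np.argmin(np.abs(cdf - prob))
            return lam_grid[idx]

        lo_ref = np.sqrt(max(search(0.95), 0.0) / (df * n))
        hi_ref = np.sqrt(max(search(0.05), 0.0) / (df * n))
        assert lo == pytest.approx(lo_ref, abs=1e-4)
        assert hi == pytest.approx(hi_ref, abs=1e-4)

    def test_rmsea_undefined_for_zero_df(self):
        rmsea, ci = _rmsea(0.0, 0, 1000)
        assert np.isnan(rmsea) and np.isnan(ci[0])

    def test_baseline_fit_has_cfi_zero(self, small_cohort):
        """Fitting a deliberately wrong structure to strongly correlated
        items pushes CFI well below the perfect-fit value."""
        cfg, cohort, *_ = small_cohort
        items = ["IA1", "IA2", "IA3", "HI1", "HI2", "HI3"]
        mom = mixed_correlation_matrix(cohort, ordinal=items)
        good = fit_dwls(build_model({"IA": items[:3], "HI": items[3:]}, False), mom)
        assert good.cfi > 0.95
        assert good.chi2 >= 0.0
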