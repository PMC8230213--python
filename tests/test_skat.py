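"""Rare-variant machinery: null fits, weights, mixture tails, reductions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import oncopanel as op
from oncopanel.skat import (NullModelError, SkatGeneInput, _liu_sf, _project_weighted,
                            beta_weights, burden_test, chi2_mixture_sf, fit_null,
                            skat_o_screen, skat_o_test, skat_test)


class TestNullModel:
    def test_intercept_only_binary_fits_prevalence(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        null = fit_null(y, "binary")
        assert np.allclose(null.mu, 0.3, atol=1e-8)
        assert abs(null.residuals.sum()) < 1e-8

    def test_intercept_only_quantitative_residuals_are_centered(self, rng):
        y = rng.normal(5.0, 2.0, size=50)
        null = fit_null(y, "quantitative")
        assert np.allclose(null.residuals, y - y.mean())
        assert abs(null.residuals.sum()) < 1e-8

    def test_logistic_fit_matches_direct_likelihood_maximization(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        null = fit_null(y, "binary", covariates=x)

        def nll(beta):
            eta = beta[0] + beta[1] * x
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        res = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        mu_opt = 1 / (1 + np.exp(-(res.x[0] + res.x[1] * x)))
        assert np.allclose(null.mu, mu_opt, atol=1e-5)

    def test_single_class_trait_rejected(self):
        with pytest.raises(NullModelError, match="both classes"):
            fit_null(np.zeros(20), "binary")

    def test_too_few_individuals_rejected(self):
        with pytest.raises(NullModelError, match=">= 10"):
            fit_null(np.array([0, 1] * 4, dtype=float), "binary")


class TestBetaWeights:
    def test_rare_variants_upweighted(self):
        w = beta_weights([0.001, 0.05, 0.4])
        assert w[0] > w[1] > w[2]

    def test_flat_weights_when_a_b_one(self):
        assert np.allclose(beta_weights([0.01, 0.2, 0.5], a=1, b=1), 1.0)

    def test_matches_direct_density_evaluation(self):
        from math import gamma
        mafs = np.array([0.01, 0.1, 0.3])
        a, b = 1.5, 10.0
        direct = (gamma(a + b) / (gamma(a) * gamma(b))
                  * mafs ** (a - 1) * (1 - mafs) ** (b - 1))
        assert np.allclose(beta_weights(mafs, a, b), direct, rtol=1e-12)

    def test_out_of_range_maf_rejected(self):
        with pytest.raises(ValueError):
            beta_weights([0.2, 1.2])


class TestMixtureTail:
    def test_matches_monte_carlo_within_three_se(self, rng):
        spectra = [
            np.array([3.0, 1.0, 0.5, 0.2, 0.1]),
            np.array([1.0, 1.0, 1.0]),
            rng.uniform(0.05, 2.0, size=8),
        ]
        n_draws = 100_000
        for lam in spectra:
            draws = (lam * rng.chisquare(1, size=(n_draws, len(lam)))).sum(axis=1)
            for q in np.quantile(draws, [0.3, 0.7, 0.95, 0.995]):
                p, _ = chi2_mixture_sf(q, lam)
                mc = (draws > q).mean()
                se = np.sqrt(mc * (1 - mc) / n_draws)
                assert abs(p - mc) <= 3 * se + 1e-12, (lam, q, p, mc)

    def test_single_component_is_exact_chi_square(self):
        p, method = chi2_mixture_sf(6.0, [2.0])
        assert method == "exact"
        assert p == pytest.approx(stats.chi2.sf(3.0, df=1), rel=1e-12)

    def test_equal_weights_reduce_to_scaled_chi_square(self):
        p, _ = chi2_mixture_sf(5.0, [1.0, 1.0])
        assert p == pytest.approx(stats.chi2.sf(5.0, df=2), abs=1e-6)

    def test_moment_matching_fallback_is_sane(self):
        lam = np.array([1.0, 0.5])
        assert 0.0 < _liu_sf(3.0, lam) < 1.0


@pytest.fixture(scope="module")
def instance():
    G, y = op.generate_skat_null(150, 8, (0.01, 0.2), "binary", seed=3)
    null = fit_null(y, "binary")
    return SkatGeneInput.from_genotypes(G), null


class TestReductions:

    def test_rho_one_equals_independent_burden_score_test(self, instance):
        gi, null = instance
        Z = gi.genotypes * gi.weights
        s = Z.T @ null.residuals
        Z1 = _project_weighted(Z, null)
        ones = np.ones(Z.shape[1])
        var_burden = ones @ (Z1.T @ Z1) @ ones
        p_oracle = stats.chi2.sf(s.sum() ** 2 / var_burden, df=1)
        assert burden_test(gi, null).p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_rho_zero_equals_standalone_skat(self, instance):
        gi, null = instance
        Z = gi.genotypes * gi.weights
        s = Z.T @ null.residuals
        Z1 = _project_weighted(Z, null)
        lam = np.linalg.eigvalsh(Z1.T @ Z1)
        lam = lam[lam > lam.max() * 1e-10]
        p_oracle, _ = chi2_mixture_sf(float(s @ s), lam)
        assert skat_test(gi, null).p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_single_variant_collapses_all_rhos(self):
        G, y = op.generate_skat_null(100, 1, 0.2, "binary", seed=2)
        null = fit_null(y, "binary")
        res = skat_o_test(G, null)
        ps = list(res.per_rho_p.values())
        assert max(ps) - min(ps) < 1e-12
        assert res.p_value == pytest.approx(ps[0])

    def test_skat_o_bounded_by_min_p_and_bonferroni(self, instance):
        gi, null = instance
        res = skat_o_test(gi, null)
        p_min = min(res.per_rho_p.values())
        assert p_min <= res.p_value <= min(1.0, p_min * len(res.per_rho_p)) + 1e-12

    def test_permuting_individuals_consistently_leaves_p_unchanged(self, instance, rng):
        gi, null = instance
        perm = rng.permutation(null.n)
        null_perm = fit_null(null.y[perm], "binary")
        res_a = skat_o_test(gi, null)
        res_b = skat_o_test(SkatGeneInput.from_genotypes(gi.genotypes[perm]), null_perm)
        assert res_b.p_value == pytest.approx(res_a.p_value, rel=1e-8)

    def test_all_zero_genotypes_warn_and_return_one(self):
        y = np.array([0.0, 1.0] * 10)
        null = fit_null(y, "binary")
        with pytest.warns(UserWarning, match="all-zero"):
            res = skat_o_test(np.zeros((20, 3)), null)
        assert res.p_value == 1.0

    def test_dimension_mismatch_rejected(self, instance):
        gi, null = instance
        with pytest.raises(ValueError, match="individuals"):
            skat_o_test(gi.genotypes[:-5], null)

    def test_mac_and_carriers_reported(self, instance):
        gi, null = instance
        res = skat_o_test(gi, null)
        assert res.mac == int(gi.genotypes.sum())
        assert res.m_carriers == int((gi.genotypes.sum(axis=1) > 0).sum())
        assert res.n_marker_all == res.n_marker_test == gi.genotypes.shape[1]


class TestScreen:
    def test_injected_gene_ranks_at_top(self):
        """A strongly associated gene should dominate the screen ranking."""
        from tests.conftest import small_config

        top3 = 0
        n_rep = 12
        for rep in range(n_rep):
            cohort = op.generate_cohort(small_config(seed=300 + rep, n_patients=120))
            gene = cohort.annotations.loc[
                cohort.annotations["cosmic_pathogenic"], "gene"].iloc[0]
            injected = op.inject_gene_association(cohort, gene, "gender", 12.0,
                                                  seed=rep, baseline_rate=0.1)
            cls = op.classify(injected.calls, injected.annotations)
            # flat weights: the injected carrier variant is common, and the
            # default rare-variant weighting would deliberately downweight it
            result = skat_o_screen(cls, injected.calls, injected.patients, "gender",
                                   weights_beta=(1.0, 1.0), n_tests=25)
            top3 += gene in set(result["SetID"].head(3))
        assert top3 >= int(0.75 * n_rep)

    def test_constant_axis_rejected(self, demo_classified, demo_cohort):
        patients = demo_cohort.patients.assign(gender="male")
        with pytest.raises(NullModelError, match="single level"):
            skat_o_screen(demo_classified, demo_cohort.calls, patients, "gender")

    def test_marker_counts_mirror_input(self, demo_classified, demo_cohort):
        result = skat_o_screen(demo_classified, demo_cohort.calls,
                               demo_cohort.patients, "gender", n_tests=25)
        assert (result["n_marker_test"] <= result["n_marker_all"]).all()
        assert (result["m"] <= len(demo_cohort.patients)).all()
        assert result["p_value"].is_monotonic_increasing

    def test_permutation_p_close_to_asymptotic(self):
        G, y = op.generate_skat_null(100, 5, (0.05, 0.2), "binary", seed=9)
        null = fit_null(y, "binary")
        from oncopanel.skat import _permutation_p
        gi = SkatGeneInput.from_genotypes(G)
        p_perm, p_floor = _permutation_p(G, gi.weights, null,
                                         (0.0, 0.25, 1.0), 500, seed=4)
        p_asym = skat_o_test(gi, null, rho_grid=(0.0, 0.25, 1.0)).p_value
        assert p_floor == pytest.approx(1 / 501)
        assert abs(p_perm - p_asym) < 0.12
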