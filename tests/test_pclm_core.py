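import numpy as np
import pytest

from pclmhap import (
    PCLMHaplotypeEstimator,
    SimulationSpec,
    aggregate_genotypes,
    em_haplotype_freqs,
    fit_genotype_counts,
    fit_pclm,
    haplo_space,
    linkage_equilibrium_prior,
    select_lambda,
    simulate_population,
)
from pclmhap.variants import build_aggregated_problem

from conftest import le_prior_from_counts


class TestLinkageEquilibriumPrior:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([0.5, 0.5], [0.25, 0.25, 0.25, 0.25]),
            ([0.3], [0.7, 0.3]),
            ([0.5, 0.5, 0.5], [0.125] * 8),
        ],
    )
    def test_product_form(self, freqs, expected):
        assert np.allclose(np.exp(linkage_equilibrium_prior(freqs)), expected)

    def test_prior_normalized_for_any_freqs(self):
        beta0 = linkage_equilibrium_prior([0.17, 0.62, 0.048])
        assert np.isclose(np.exp(beta0).sum(), 1.0)

    def test_degenerate_frequency_warns_but_proceeds(self):
        with pytest.warns(RuntimeWarning):
            beta0 = linkage_equilibrium_prior([0.0, 0.4])
        assert np.isfinite(beta0).all()


class TestFitPCLM:
    def test_single_snp_gene_counting(self):
        fit = fit_genotype_counts(np.array([30.0, 40.0, 30.0]), lam=0.0)
        assert np.allclose(fit.p_hat, [0.5, 0.5], atol=1e-8)

    def test_large_penalty_pushes_to_prior(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1e6)
        fit = fit_pclm(prob)
        assert np.max(np.abs(fit.p_hat - np.exp(beta0))) < 1e-3

    def test_matches_gene_counting_em(self, two_snp_counts):
        fit = fit_genotype_counts(two_snp_counts, lam=1e-4)
        em = em_haplotype_freqs(two_snp_counts, haplo_space(2), tol=1e-10)
        assert np.max(np.abs(fit.p_hat - em)) < 5e-3

    @pytest.mark.parametrize("n_snps", [1, 2, 3])
    def test_oracle_equivalence_random_datasets(self, n_snps):
        # interior EM solutions agree with the weakly penalized PCLM
        rng = np.random.default_rng(7)
        space = haplo_space(n_snps)
        checked = 0
        for rep in range(20):
            p = rng.dirichlet(np.full(space.n_hap, 2.0))
            g = simulate_population(SimulationSpec(n_snps, p, 500, seed=100 + rep))
            counts = aggregate_genotypes(g)
            em = em_haplotype_freqs(counts, space, tol=1e-10)
            if em.min() <= 0.01:
                continue
            fit = fit_genotype_counts(counts, lam=1e-4)
            assert np.max(np.abs(fit.p_hat - em)) < 5e-3
            checked += 1
        assert checked >= 5

    def test_fit_invariants(self, two_snp_counts):
        for lam in (1e-3, 1.0, 1e3):
            fit = fit_genotype_counts(two_snp_counts, lam=lam)
            assert fit.converged
            assert np.isclose(fit.p_hat.sum(), 1.0, atol=1e-8)
            assert np.isclose(fit.q_hat.sum(), 1.0, atol=1e-8)
            assert np.isclose(fit.mu.sum(), two_snp_counts.sum(), atol=1e-6)
            assert fit.p_hat.min() > 0
            assert 0 <= fit.ed <= 4
            # accepted objective trace is monotone by construction
            assert np.all(np.diff(fit.objective_trace) >= -1e-9)

    def test_nonconvergence_is_flagged(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1e-4)
        fit = fit_pclm(prob, max_iter=2)
        assert not fit.converged


class TestDiagnostics:
    def test_effective_dimension_limits(self):
        counts = np.array([30.0, 40.0, 30.0])
        lo = fit_genotype_counts(counts, lam=1e-8)
        hi = fit_genotype_counts(counts, lam=1e8)
        assert abs(lo.ed - 1.0) < 0.05  # one free parameter after normalization
        assert hi.ed < 1.05

    def test_effective_dimension_monotone_in_lambda(self, two_snp_counts):
        eds = [
            fit_genotype_counts(two_snp_counts, lam=10.0**l).ed
            for l in np.arange(-2, 4.01, 0.5)
        ]
        assert np.all(np.diff(eds) <= 1e-8)

    def test_perfect_fit_has_zero_deviance(self):
        # HWE-exact counts are perfectly reproduced by the one-SNP model
        fit = fit_genotype_counts(np.array([25.0, 50.0, 25.0]), lam=1e-8)
        assert fit.deviance < 1e-6
        assert abs(fit.aic - 2 * fit.ed) < 1e-6

    def test_standard_errors_vanish_for_large_penalty(self, two_snp_counts):
        small = fit_genotype_counts(two_snp_counts, lam=1e-2)
        big = fit_genotype_counts(two_snp_counts, lam=1e6)
        assert np.all(big.se_p < small.se_p)
        assert big.se_p.max() < 1e-3

    def test_standard_errors_scale_with_sample_size(self, two_snp_counts):
        fit1 = fit_genotype_counts(two_snp_counts, lam=1e-4)
        fit2 = fit_genotype_counts(2 * two_snp_counts, lam=1e-4)
        ratio = fit2.se_p / fit1.se_p
        assert np.allclose(ratio, 1 / np.sqrt(2), atol=0.01)

    def test_standard_errors_nonnegative_and_sandwich_available(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1.0)
        plain = fit_pclm(prob, se_method="inverse")
        sandwich = fit_pclm(prob, se_method="sandwich")
        assert np.all(plain.se_p >= 0)
        assert np.all(sandwich.se_p >= 0)


class TestLambdaSelection:
    def test_single_element_grid(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1.0)
        lam, profile, _ = select_lambda(prob, grid_log10=[0.5])
        assert np.isclose(lam, 10**0.5)
        assert len(profile) == 1

    def test_selected_lambda_minimizes_profile(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1.0)
        lam, profile, _ = select_lambda(prob)
        assert np.isclose(
            profile.loc[profile["lam"] == lam, "aic"].iloc[0], profile["aic"].min()
        )

    def test_warm_start_matches_cold_start(self, two_snp_counts):
        beta0 = le_prior_from_counts(two_snp_counts, 2)
        prob = build_aggregated_problem(two_snp_counts, beta0, 1.0)
        _, warm, _ = select_lambda(prob, grid_log10=np.arange(-1, 2.1, 0.5))
        _, cold, _ = select_lambda(
            prob, grid_log10=np.arange(-1, 2.1, 0.5), warm_start=False
        )
        assert np.allclose(warm["aic"], cold["aic"], atol=1e-6)

    def test_aic_profile_has_interior_minimum_under_ld(self):
        from pclmhap import correlated_hap_freqs

        p = correlated_hap_freqs(5)
        g = simulate_population(SimulationSpec(5, p, 120, seed=1))
        est = PCLMHaplotypeEstimator(lam="aic").fit(g)
        aics = est.profile_["aic"].to_numpy()
        best = int(np.argmin(aics))
        assert 0 < best < len(aics) - 1
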