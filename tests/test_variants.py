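import numpy as np
import pytest

from pclmhap import (
    DoseProbTable,
    aggregate_genotypes,
    confusion_rows,
    fit_fuzzy,
    fit_pclm,
    fit_genotype_counts,
    haplo_space,
    individual_composition,
)
from pclmhap.variants import MISSING_TRIPLE, build_individual_problem

from conftest import le_prior_from_counts


class TestAggregation:
    def test_counts_include_zero_states(self):
        counts = aggregate_genotypes(np.array([[0], [1], [1]]))
        assert counts.tolist() == [1, 2, 0]

    def test_conservation_on_random_data(self, four_hap_panel):
        _, g = four_hap_panel
        counts = aggregate_genotypes(g)
        assert counts.sum() == g.shape[0]
        assert counts.size == 3**4

    def test_invalid_entry_is_located(self):
        with pytest.raises(ValueError, match="individual 1, SNP 0"):
            aggregate_genotypes(np.array([[0, 1], [3, 2]]))


class TestIndividualComposition:
    def test_rows_are_composition_rows(self):
        space = haplo_space(2)
        g = np.array([[0, 0], [1, 1], [1, 1]])
        Cb = individual_composition(g, space)
        assert Cb.shape == (3, 16)
        assert (Cb[1] != Cb[2]).nnz == 0  # identical genotypes, identical rows
        # homozygous-reference individual: single 1 at diplotype (0, 0)
        assert Cb[0].nonzero()[1].tolist() == [0]

    def test_individual_fit_equals_aggregated_fit(self, two_snp_genotypes):
        counts = aggregate_genotypes(two_snp_genotypes)
        beta0 = le_prior_from_counts(counts, 2)
        agg = fit_genotype_counts(counts, lam=1e-3)
        ind = fit_pclm(build_individual_problem(two_snp_genotypes, beta0, 1e-3))
        assert np.max(np.abs(agg.p_hat - ind.p_hat)) < 1e-9
        assert abs(agg.aic - ind.aic) < 1e-6
        assert abs(agg.ed - ind.ed) < 1e-6


class TestDoseProbTable:
    def test_triples_renormalized_on_ingest(self):
        t = DoseProbTable(np.array([[[2.0, 1.0, 1.0]]]))
        assert np.allclose(t.probs[0, 0], [0.5, 0.25, 0.25])

    def test_rejects_zero_and_negative_triples(self):
        with pytest.raises(ValueError):
            DoseProbTable(np.zeros((1, 1, 3)))
        with pytest.raises(ValueError):
            DoseProbTable(np.array([[[0.5, 0.6, -0.1]]]))

    def test_from_crisp_with_missing(self):
        t = DoseProbTable.from_crisp(np.array([[0.0, np.nan], [2.0, 1.0]]))
        assert np.allclose(t.probs[0, 0], [1, 0, 0])
        assert np.allclose(t.probs[0, 1], MISSING_TRIPLE)
        assert np.allclose(t.probs[1, 1], [0, 1, 0])
        assert t.is_crisp() is False


class TestConfusionRows:
    def test_crisp_rows_are_unit_vectors(self):
        t = DoseProbTable.from_crisp(np.array([[1, 2]]))
        F = confusion_rows(t)
        row = F.toarray()[0]
        assert row.sum() == 1.0
        assert row[1 * 3 + 2] == 1.0  # ternary index of dose vector [1, 2]

    def test_one_and_two_missing_snps(self):
        g = np.array([[1.0, np.nan], [np.nan, np.nan]])
        F = confusion_rows(DoseProbTable.from_crisp(g)).toarray()
        assert (F[0] > 0).sum() == 3
        assert np.allclose(F[0][F[0] > 0], 1 / 3)
        assert (F[1] > 0).sum() == 9
        assert np.allclose(F[1][F[1] > 0], 1 / 9)

    def test_rows_sum_to_one(self, two_snp_genotypes):
        t = DoseProbTable.from_crisp(two_snp_genotypes.astype(float))
        t.probs[0, 0] = [0.2, 0.5, 0.3]
        F = confusion_rows(DoseProbTable(t.probs))
        assert np.allclose(np.asarray(F.sum(axis=1)).ravel(), 1.0)


class TestFuzzyFit:
    def test_identity_confusion_equals_crisp_fit(self, two_snp_genotypes):
        counts = aggregate_genotypes(two_snp_genotypes)
        beta0 = le_prior_from_counts(counts, 2)
        crisp = fit_genotype_counts(counts, lam=1e-3)
        fuzzy = fit_fuzzy(
            DoseProbTable.from_crisp(two_snp_genotypes.astype(float)), beta0, 1e-3
        )
        assert np.max(np.abs(crisp.p_hat - fuzzy.p_hat)) < 1e-9

    def test_all_missing_returns_prior(self):
        g = np.full((30, 2), np.nan)
        beta0 = np.log(np.array([0.4, 0.1, 0.2, 0.3]))
        fit = fit_fuzzy(DoseProbTable.from_crisp(g), beta0, 1.0)
        assert np.max(np.abs(fit.p_hat - np.exp(beta0))) < 1e-6

    def test_composite_rows_conserve_probability(self, two_snp_genotypes):
        space = haplo_space(2)
        t = DoseProbTable.from_crisp(two_snp_genotypes.astype(float))
        t.probs[:10, 0] = MISSING_TRIPLE
        F = confusion_rows(DoseProbTable(t.probs))
        comp = F @ space.C
        p = np.array([0.4, 0.1, 0.2, 0.3])
        gamma = np.exp(space.M @ np.log(p))
        pi = comp @ gamma
        assert np.allclose(pi, np.asarray(F @ (space.C @ gamma)).ravel())
        # each individual's observation probability is a proper probability,
        # and F rows are distributions over genotype states
        assert np.all((pi > 0) & (pi <= 1))
        assert np.allclose(np.asarray(F.sum(axis=1)).ravel(), 1.0)

    def test_fit_is_lipschitz_in_confusion_weights(self, two_snp_genotypes):
        beta0 = le_prior_from_counts(aggregate_genotypes(two_snp_genotypes), 2)
        base = DoseProbTable.from_crisp(two_snp_genotypes.astype(float))
        eps = 1e-4
        perturbed = base.probs.copy()
        perturbed[0, 0] = np.array([1 - eps, eps, 0.0])
        f0 = fit_fuzzy(base, beta0, 1e-3)
        f1 = fit_fuzzy(DoseProbTable(perturbed), beta0, 1e-3)
        delta = np.max(np.abs(f0.p_hat - f1.p_hat))
        assert delta < 100 * eps
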