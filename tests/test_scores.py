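"""Genetic scores, liability/slope variance explained, and score correlations."""

import numpy as np
import pytest
from scipy import stats

from pleioscore.catalog import EffectType, OutcomeType
from pleioscore.errors import ConfigurationError, DomainError
from pleioscore.scores import (compute_genetic_scores, score_correlation_matrix,
                               solve_penetrances, trait_variance_summary,
                               variance_explained_binary,
                               variance_explained_continuous)

from conftest import make_catalog, make_cohort, make_variant


class TestGeneticScores:
    def test_hand_computed_weighted_sum(self):
        """weights {0.2, 0.4} and dosages {2, 1} give (0.4+0.4)/0.3 = 2.6667."""
        catalog = make_catalog([
            make_variant(variant_id="rs1", effect_size=0.2),
            make_variant(variant_id="rs2", pos=4_000_000, effect_size=0.4),
        ])
        cohort = make_cohort([[2.0, 1.0], [0.0, 0.0]])
        scores = compute_genetic_scores(cohort, catalog)
        assert scores.values[0, 0] == pytest.approx(0.8 / 0.3)
        assert scores.values[1, 0] == 0.0      # no risk alleles, score 0
        assert scores.mean_weight["T1"] == pytest.approx(0.3)

    def test_one_allele_moves_score_by_weight_over_mean(self):
        catalog = make_catalog([
            make_variant(variant_id="rs1", effect_size=0.2),
            make_variant(variant_id="rs2", pos=4_000_000, effect_size=0.4),
        ])
        base = make_cohort([[1.0, 1.0]])
        plus = make_cohort([[2.0, 1.0]])
        s0 = compute_genetic_scores(base, catalog).values[0, 0]
        s1 = compute_genetic_scores(plus, catalog).values[0, 0]
        assert s1 - s0 == pytest.approx(0.2 / 0.3)

    def test_score_invariant_under_weight_rescaling(self):
        dosages = np.random.default_rng(1).integers(0, 3, size=(20, 3)).astype(float)
        cohort = make_cohort(dosages)
        weights = [0.1, 0.25, 0.4]
        for c in (1.0, 3.7, 0.01):
            catalog = make_catalog([
                make_variant(variant_id=f"rs{j + 1}", pos=10 ** 6 * (1 + 3 * j),
                             effect_size=c * w)
                for j, w in enumerate(weights)
            ])
            scores = compute_genetic_scores(cohort, catalog)
            if c == 1.0:
                reference = scores.values.copy()
            np.testing.assert_allclose(scores.values, reference, rtol=1e-12)

    def test_missing_dosage_mean_imputed(self):
        catalog = make_catalog([make_variant(variant_id="rs1"),
                                make_variant(variant_id="rs2", pos=4_000_000)])
        dosages = np.array([[np.nan, 1.0], [2.0, 1.0], [0.0, 1.0]])
        scores = compute_genetic_scores(make_cohort(dosages), catalog)
        # rs1 imputed to the observed mean 1.0 for the first sample
        assert scores.values[0, 0] == pytest.approx((0.1 * 1.0 + 0.1 * 1.0) / 0.1)

    def test_absent_variant_excluded_from_average_weight(self):
        catalog = make_catalog([
            make_variant(variant_id="rs1", effect_size=0.2),
            make_variant(variant_id="missing", pos=4_000_000, effect_size=0.9),
        ])
        cohort = make_cohort([[2.0]], variant_ids=["rs1"])
        scores = compute_genetic_scores(cohort, catalog)
        assert scores.mean_weight["T1"] == pytest.approx(0.2)
        assert scores.values[0, 0] == pytest.approx(2.0)

    def test_unoriented_catalog_rejected(self):
        catalog = make_catalog([make_variant(effect_size=-0.1)])
        with pytest.raises(ValueError, match="oriented"):
            compute_genetic_scores(make_cohort([[1.0]]), catalog)

    def test_dosage_flipped_when_cohort_counts_other_allele(self):
        catalog = make_catalog([make_variant(effect_allele="G", other_allele="A")])
        cohort = make_cohort([[2.0]], effect_allele="A", other_allele="G")
        scores = compute_genetic_scores(cohort, catalog)
        assert scores.values[0, 0] == pytest.approx(0.0)


class TestLiabilityVariance:
    def test_no_effect_explains_nothing(self):
        assert variance_explained_binary(0.3, 1.0, 0.01) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_below_one(self):
        for eaf in (0.05, 0.3, 0.7):
            for or_pa in (1.2, 3.0, 10.0):
                for k in (0.001, 0.05, 0.3):
                    assert 0.0 <= variance_explained_binary(eaf, or_pa, k) < 1.0

    def test_solved_penetrances_reproduce_prevalence_exactly(self):
        f, K = solve_penetrances(0.3, 1.5, 0.01)
        assert f @ K == pytest.approx(0.01, rel=1e-10)
        # odds are multiplicative in the allele count
        odds = K / (1 - K)
        assert odds[1] / odds[0] == pytest.approx(1.5, rel=1e-9)
        assert odds[2] / odds[1] == pytest.approx(1.5, rel=1e-9)

    def test_monte_carlo_self_consistency(self):
        """Forward simulation from the solved penetrances matches the analytic
        liability variance: realized per-genotype risks, converted to threshold
        shifts, reproduce the returned value (>= 1e6 draws)."""
        eaf, or_pa, k = 0.3, 1.5, 0.01
        analytic = variance_explained_binary(eaf, or_pa, k)
        f, K = solve_penetrances(eaf, or_pa, k)
        rng = np.random.default_rng(2024)
        n = 4_000_000
        n_g = rng.multinomial(n, f)
        cases_g = rng.binomial(n_g, K)
        k_hat = cases_g.sum() / n
        assert k_hat == pytest.approx(k, rel=0.02)
        f_hat = n_g / n
        K_hat = cases_g / n_g
        T_hat = stats.norm.isf(k_hat)
        m = T_hat - stats.norm.isf(K_hat)
        mc = float(f_hat @ m ** 2 - (f_hat @ m) ** 2)
        assert mc == pytest.approx(analytic, rel=0.10)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            variance_explained_binary(0.0, 1.5, 0.01)
        with pytest.raises(DomainError):
            variance_explained_binary(0.3, -1.0, 0.01)
        with pytest.raises(DomainError):
            variance_explained_binary(0.3, 1.5, 1.5)


class TestContinuousVariance:
    def test_null_slope(self):
        assert variance_explained_continuous(0.0, 0.01, 1000) == 0.0

    def test_z10_identity(self):
        """z = 10, n = 10^4: r^2 = 100 / (100 + 9998)."""
        assert variance_explained_continuous(0.1, 0.01, 10_000) == pytest.approx(
            100.0 / 10_098.0)

    def test_matches_simple_regression_oracle(self):
        """The t/r^2 identity holds on an actually fitted regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 5_000
        x = rng.standard_normal(n)
        y = 0.05 * x + rng.standard_normal(n)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        slope, se = fit.params[1], fit.bse[1]
        assert variance_explained_continuous(slope, se, n) == pytest.approx(
            fit.rsquared, rel=1e-6)

    def test_monotone_in_abs_z(self):
        values = [variance_explained_continuous(z * 0.01, 0.01, 1_000)
                  for z in (0.5, 1, 2, 5, 10)]
        assert values == sorted(values)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            variance_explained_continuous(0.1, 0.0, 1000)
        with pytest.raises(DomainError):
            variance_explained_continuous(0.1, 0.01, 2)


class TestVarianceSummary:
    def test_mean_and_range_are_unweighted(self):
        variants_a = [make_variant(variant_id=f"a{i}", pos=10 ** 6 * (1 + 3 * i),
                                   trait_id="A", effect_size=0.3)
                      for i in range(3)]
        variants_b = [make_variant(variant_id=f"b{i}", pos=10 ** 6 * (1 + 3 * i),
                                   chrom="2", trait_id="B", effect_size=0.1)
                      for i in range(3)]
        catalog = make_catalog(variants_a + variants_b)
        frame, summary = trait_variance_summary(catalog)
        per = dict(zip(frame["trait_id"], frame["variance_explained_pct"]))
        expected_a = 3 * 100 * variance_explained_binary(0.3, np.exp(0.3), 0.1)
        assert per["A"] == pytest.approx(expected_a, rel=1e-9)
        assert summary["mean_pct"] == pytest.approx((per["A"] + per["B"]) / 2)
        assert summary["min_pct"] == pytest.approx(per["B"])
        assert summary["max_pct"] == pytest.approx(per["A"])

    def test_survival_not_estimable(self):
        catalog = make_catalog([make_variant(effect_type=EffectType.LOGHR)],
                               outcome_type=OutcomeType.SURVIVAL)
        frame, summary = trait_variance_summary(catalog)
        assert frame["method"].iloc[0] == "NOT_ESTIMABLE"
        assert summary["n_traits"] == 0

    def test_binary_without_prevalence_errors(self):
        catalog = make_catalog([make_variant()], prevalence=None)
        with pytest.raises(ConfigurationError, match="prevalence"):
            trait_variance_summary(catalog)

    def test_continuous_without_n_errors(self):
        catalog = make_catalog([make_variant(effect_type=EffectType.SLOPE, se=0.01)],
                               outcome_type=OutcomeType.CONTINUOUS, gwas_n=None)
        with pytest.raises(ConfigurationError, match="sample size"):
            trait_variance_summary(catalog)

    def test_generative_liability_variance_recovered(self, small_study):
        """Summing the generative per-variant liability variances matches the
        analytic total for the simulated trait's true effects."""
        spec = small_study.spec
        beta = small_study.liability_effects
        shared = np.flatnonzero(beta[:spec.variants_per_trait])
        eafs = small_study.eafs
        expected = sum(beta[j] ** 2 * 2 * eafs[j] * (1 - eafs[j]) for j in shared)
        var_total = float(np.sum(beta ** 2 * 2 * eafs * (1 - eafs)))
        # per-variant liability variance through the OR route: convert the
        # generative liability effect to a per-allele OR and back
        from pleioscore.validation import _grouped_logistic_or
        total = 0.0
        for j in shared:
            p = small_study.eafs[j]
            f = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
            g = np.arange(3)
            sigma_e = np.sqrt(1 - var_total)
            T = stats.norm.isf(spec.disease_prevalence)
            K_g = stats.norm.cdf((beta[j] * (g - 2 * p) - T) / sigma_e)
            or_pa = _grouped_logistic_or(f * 1e9, K_g * f * 1e9)
            total += variance_explained_binary(p, or_pa, spec.disease_prevalence)
        assert total == pytest.approx(expected, rel=0.15)


class TestScoreCorrelation:
    def test_symmetric_unit_diagonal_q_above_p(self, small_study):
        from pleioscore.scores import compute_genetic_scores

        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        corr = score_correlation_matrix(scores)
        np.testing.assert_allclose(corr.rho.values, corr.rho.values.T)
        np.testing.assert_allclose(np.diag(corr.rho.values), 1.0)
        off = ~np.eye(len(corr.q), dtype=bool)
        assert np.all(corr.q.values[off] >= corr.p.values[off] - 1e-15)

    def test_disjoint_ld_independent_traits_uncorrelated(self, small_study):
        from pleioscore.scores import compute_genetic_scores

        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        corr = score_correlation_matrix(scores)
        n = len(scores.sample_ids)
        assert abs(corr.rho.loc["T02", "T03"]) < 3 / np.sqrt(n)

    def test_shared_variants_induce_positive_correlation(self, small_study):
        """Two traits built on 80%-overlapping variant sets correlate."""
        meta = small_study.cohort.variant_meta
        ids = list(meta["variant_id"][:10])
        mk = {v.variant_id: v for v in small_study.catalog.all_variants}

        def variant_for(vid, tid):
            import dataclasses
            base = mk.get(vid) or make_variant(variant_id=vid)
            return dataclasses.replace(base, trait_id=tid)

        overlapping = make_catalog(
            [variant_for(v, "A") for v in ids[:10]]
            + [variant_for(v, "B") for v in ids[2:10]])
        scores = compute_genetic_scores(small_study.cohort, overlapping)
        corr = score_correlation_matrix(scores)
        assert corr.rho.loc["A", "B"] > 0.5

    def test_constant_score_reported_missing(self):
        from pleioscore.scores import ScoreMatrix

        rng = np.random.default_rng(3)
        values = np.column_stack([rng.standard_normal(20), np.ones(20)])
        scores = ScoreMatrix(sample_ids=[f"S{i}" for i in range(20)],
                             trait_ids=["A", "B"], values=values)
        corr = score_correlation_matrix(scores)
        assert np.isnan(corr.rho.loc["A", "B"])

    def test_requires_two_traits_and_ten_samples(self):
        from pleioscore.scores import ScoreMatrix

        one = ScoreMatrix(sample_ids=[f"S{i}" for i in range(20)],
                          trait_ids=["A"], values=np.zeros((20, 1)))
        with pytest.raises(ConfigurationError):
            score_correlation_matrix(one)
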