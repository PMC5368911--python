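"""Logistic fits, BH adjustment, screens, conditioning, and subgroups."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleioscore.association import (associate_all_scores, associate_score,
                                    bh_adjust, conditional_screen, fit_logistic,
                                    results_to_frame, screen_variants,
                                    subgroup_association)
from pleioscore.errors import CollinearityError, DomainError, SeparationError
from pleioscore.scores import ScoreMatrix, compute_genetic_scores
from pleioscore.validation import bh_brute_force

from conftest import make_catalog, make_cohort, make_variant


def _expand_2x2(a, b, c, d):
    """Rows for a 2x2 table: a/b cases with x=1/0, c/d controls with x=1/0."""
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_matches_contingency_closed_form(self):
        """a=10 b=20 c=30 d=40: LOR = ln(ad/bc), SE = sqrt(sum of 1/counts)."""
        y, X = _expand_2x2(10, 20, 30, 40)
        fit = fit_logistic(y, X, ["intercept", "x"])
        assert fit.coefficients[1] == pytest.approx(np.log(10 * 40 / (20 * 30)),
                                                    abs=1e-8)
        assert fit.ses[1] == pytest.approx(
            np.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40), abs=1e-8)
        assert fit.converged

    def test_null_type_i_error_calibrated(self):
        """Independent predictor: ~5% of replicates reject at alpha = 0.05."""
        rng = np.random.default_rng(17)
        n, reps = 2_000, 300
        rejections = 0
        for _ in range(reps):
            y = (rng.random(n) < 0.5).astype(float)
            x = rng.standard_normal(n)
            fit = fit_logistic(y, np.column_stack([np.ones(n), x]))
            rejections += fit.p_values[1] < 0.05
        rate = rejections / reps
        assert 0.02 < rate < 0.09

    def test_constant_predictor_is_collinear(self):
        y = np.array([0.0, 1.0] * 20)
        X = np.column_stack([np.ones(40), np.full(40, 2.0)])
        with pytest.raises(CollinearityError):
            fit_logistic(y, X, ["intercept", "constant_dosage"])

    def test_perfect_separation_detected(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.raises(SeparationError):
            fit_logistic(y, np.column_stack([np.ones(40), x]), ["intercept", "x"])

    def test_missing_rows_dropped_pairwise(self):
        y, X = _expand_2x2(10, 20, 30, 40)
        X = X.copy()
        X[0, 1] = np.nan
        fit = fit_logistic(y, X)
        assert fit.n_dropped == 1
        assert fit.n_used == 99


class TestBHAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.001, 0.01, 0.02, 0.9])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.0266667, 0.9], rtol=1e-5)

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert bh_adjust([]).size == 0

    def test_domain_errors(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(DomainError):
                bh_adjust(bad)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.sampled_from([0.001, 0.01, 0.03, 0.2, 0.5, 0.77, 1.0]),
                    min_size=1, max_size=8))
    def test_matches_brute_force_step_up(self, p):
        got = bh_adjust(p)
        expected = bh_brute_force(p)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # monotone in p, q >= p, capped at 1
        order = np.argsort(p)
        assert np.all(np.diff(got[order]) >= -1e-15)
        assert np.all(got >= np.asarray(p) - 1e-15)
        assert np.all(got <= 1.0)


class TestScoreAssociation:
    def test_pleiotropic_score_recovered_and_significant(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        res = associate_score(scores, small_study.cohort, "T01")
        assert res.lor > 0
        assert res.p < 1e-4
        lo, hi = res.ci95
        assert lo == pytest.approx(res.lor - 1.96 * res.se)
        assert hi == pytest.approx(res.lor + 1.96 * res.se)

    def test_null_score_not_extreme(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        res = associate_score(scores, small_study.cohort, "T02")
        assert abs(res.lor / res.se) < 4

    def test_family_q_values_attached(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        results = associate_all_scores(scores, small_study.cohort)
        assert len(results) == 3
        assert all(r.q >= r.p - 1e-15 for r in results)
        frame = results_to_frame(results)
        assert set(frame["target_id"]) == {"T01", "T02", "T03"}

    def test_single_score_q_equals_p(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        only = ScoreMatrix(sample_ids=scores.sample_ids, trait_ids=["T01"],
                           values=scores.values[:, :1])
        res = associate_all_scores(only, small_study.cohort)
        assert res[0].q == pytest.approx(res[0].p)

    def test_score_collinear_with_pc_captured(self, small_study):
        cohort = small_study.cohort
        collinear = ScoreMatrix(
            sample_ids=cohort.sample_ids, trait_ids=["PCCOPY"],
            values=cohort.samples["pc1"].to_numpy()[:, None])
        res = associate_all_scores(collinear, cohort)
        assert res[0].error is not None


class TestVariantScreens:
    def test_duplicate_variant_screened_once(self, small_study):
        import dataclasses

        cohort = small_study.cohort
        v = next(iter(small_study.catalog.all_variants))
        doubled = make_catalog([v, dataclasses.replace(v, trait_id="T99")])
        results = screen_variants(cohort, doubled)
        assert len(results) == 1

    def test_monomorphic_variant_captured_not_fatal(self, small_study):
        cohort = small_study.cohort
        frozen = cohort.dosages.copy()
        frozen[:, 0] = 1.0
        import dataclasses

        mono = dataclasses.replace(cohort, dosages=frozen)
        results = screen_variants(mono, small_study.catalog)
        by_id = {r.target_id: r for r in results}
        first = cohort.variant_meta["variant_id"].iat[0]
        assert by_id[first].error is not None
        assert sum(r.error is None for r in results) == len(results) - 1

    def test_causal_variant_effect_recovered(self, small_study):
        """A disease-private causal variant shows its liability effect."""
        results = screen_variants(small_study.cohort, small_study.catalog)
        # shared variants of T01 carry real effects; at least one is significant
        shared = set(small_study.population.variant_meta["variant_id"][:3])
        sig = {r.target_id for r in results if r.significant}
        assert sig & shared

    def test_no_knowns_equals_raw_screen(self, small_study):
        raw = screen_variants(small_study.cohort, small_study.catalog)
        cond = conditional_screen(small_study.cohort, small_study.catalog, [])
        raw_by = {r.target_id: r for r in raw}
        for r in cond:
            assert r.lor == pytest.approx(raw_by[r.target_id].lor, abs=1e-10)

    def test_known_candidate_skipped(self, small_study):
        import dataclasses

        known_id = small_study.disease_variant_ids[0]
        meta = small_study.population.variant_meta
        row = meta[meta["variant_id"] == known_id].iloc[0]
        catalog = make_catalog([
            make_variant(variant_id=known_id, chrom=str(row["chrom"]),
                         pos=int(row["pos"]))])
        cond = conditional_screen(small_study.cohort, catalog, [known_id])
        assert cond == []

    def test_conditioning_on_unlinked_knowns_barely_moves_lor(self, small_study):
        """Known variants in separate LD blocks leave candidates untouched."""
        raw = {r.target_id: r for r in
               screen_variants(small_study.cohort, small_study.catalog)}
        cond = conditional_screen(small_study.cohort, small_study.catalog,
                                  small_study.disease_variant_ids)
        moved = [abs(r.lor - raw[r.target_id].lor) / raw[r.target_id].se
                 for r in cond if r.error is None]
        assert np.mean(moved) < 1.0


class TestSubgroups:
    def test_sex_strata_agree_without_interaction(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        strata = subgroup_association(scores, small_study.cohort, "SEX")
        male = {r.target_id: r for r in strata["male"]}
        female = {r.target_id: r for r in strata["female"]}
        for tid in scores.trait_ids:
            diff = male[tid].lor - female[tid].lor
            joint_se = np.hypot(male[tid].se, female[tid].se)
            assert abs(diff) < 3.5 * joint_se

    def test_age75_partition_is_exhaustive(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        strata = subgroup_association(scores, small_study.cohort, "AGE75")
        n_lo = strata["age<75"][0].n
        n_hi = strata["age>=75"][0].n
        assert n_lo + n_hi == small_study.cohort.n_samples

    def test_subtype_strata_keep_all_controls(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        strata = subgroup_association(scores, small_study.cohort, "SUBTYPE")
        n_controls = int(small_study.cohort.control_mask.sum())
        status = small_study.cohort.samples["status"]
        assert strata["GA"][0].n == n_controls + int((status == "GA").sum())
        assert strata["NV"][0].n == n_controls + int(status.isin(["NV", "MIXED"]).sum())

    def test_population_based_restriction_matches_flag(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        strata = subgroup_association(scores, small_study.cohort, "POPULATION_BASED")
        expected = int(small_study.cohort.samples["population_based"].sum())
        assert strata["population_based"][0].n == expected

    def test_empty_ga_stratum_flagged_not_fatal(self, small_study):
        cohort = small_study.cohort
        relabeled = cohort.samples.copy()
        relabeled.loc[relabeled["status"] == "GA", "status"] = "NV"
        import dataclasses

        no_ga = dataclasses.replace(cohort, samples=relabeled)
        scores = compute_genetic_scores(no_ga, small_study.catalog)
        strata = subgroup_association(scores, no_ga, "SUBTYPE")
        assert all(r.underpowered for r in strata["GA"])
        assert all(r.error is not None for r in strata["GA"])
        assert any(r.error is None for r in strata["NV"])

    def test_unknown_stratifier_rejected(self, small_study):
        scores = compute_genetic_scores(small_study.cohort, small_study.catalog)
        with pytest.raises(ValueError):
            subgroup_association(scores, small_study.cohort, "REGION")
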