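"""Calibration studies: the model-level checks the package makes of itself.

Each routine here runs a self-contained simulation study against an
independent expectation — an exact enumeration, a closed form, or a null
distribution — and reports summary numbers:

* :func:`liability_consistency_grid` — forward-simulates disease from the
  penetrances solved by the liability-threshold model and checks that the
  realized prevalence and per-allele odds ratio reproduce the inputs.
* :func:`score_recovery_study` — checks that the full pipeline (simulate,
  catalog, score, covariate-adjusted logistic fit) recovers the
  analytically forward-computed score log odds ratio.
* :func:`null_calibration_study` — with all pleiotropy switched off, the
  score family's BH discoveries at q < 0.01 stay at the nominal rate.
* :func:`conditional_confounding_study` — a candidate variant whose signal
  is pure linkage to a known causal variant is significant raw and loses
  significance once conditioned on the known variant.

The forward-computed truth in the recovery study is exact, not simulated:
with independent variants and equal published weights the score is an allele
count whose joint distribution with disease status follows from convolving
per-variant genotype distributions through the liability model, and the
infinite-sample case-control logistic slope is obtained by Newton iteration
on that finite discrete joint.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .association import associate_score, bh_adjust, fit_logistic
from .cohort import CohortData
from .scores import compute_genetic_scores, solve_penetrances
from .synthetic_data import (PleiotropySpec, SimulationSpec, sample_case_control,
                             simulate_study)


# ---------------------------------------------------------------------------
# Liability model self-consistency
# ---------------------------------------------------------------------------

def _grouped_logistic_or(n_by_g: np.ndarray, cases_by_g: np.ndarray) -> float:
    """Per-allele OR from grouped counts via a logistic fit on {0,1,2}."""
    g = np.repeat(np.arange(3), 2)
    y = np.tile([1.0, 0.0], 3)
    w = np.column_stack([cases_by_g, n_by_g - cases_by_g]).reshape(-1)
    keep = w > 0
    X = np.column_stack([np.ones(6), g])[keep]
    yk, wk = y[keep], w[keep]
    beta = np.zeros(2)
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (wk * (yk - mu))
        hess = (X * (wk * mu * (1 - mu))[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(np.exp(beta[1]))


def liability_consistency_grid(
    seed: int = 0,
    eafs=(0.1, 0.3, 0.5),
    ors=(1.1, 1.5, 2.5),
    prevalences=(0.01, 0.1),
    n_draws: int = 20_000_000,
) -> dict:
    """Forward-simulate disease from solved penetrances over a parameter grid.

    For each (eaf, OR, prevalence), genotypes are drawn under HWE and disease
    with the solved per-genotype risks; the realized prevalence and realized
    per-allele OR (grouped logistic fit) are compared with the inputs as
    relative errors.  Genotype and disease draws use exact multinomial /
    binomial sampling of the grouped counts, which is distributionally
    identical to individual-level simulation at any ``n_draws``.
    """
    rng = np.random.default_rng(seed)
    cells = []
    for eaf in eafs:
        for or_pa in ors:
            for k in prevalences:
                f, K = solve_penetrances(eaf, or_pa, k)
                n_by_g = rng.multinomial(n_draws, f).astype(float)
                cases_by_g = rng.binomial(n_by_g.astype(int), K).astype(float)
                k_hat = cases_by_g.sum() / n_draws
                or_hat = _grouped_logistic_or(n_by_g, cases_by_g)
                cells.append({
                    "eaf": eaf, "or": or_pa, "prevalence": k,
                    "prevalence_rel_err": abs(k_hat - k) / k,
                    "or_rel_err": abs(or_hat - or_pa) / or_pa,
                })
    return {
        "cells": cells,
        "max_prevalence_rel_err": max(c["prevalence_rel_err"] for c in cells),
        "max_or_rel_err": max(c["or_rel_err"] for c in cells),
        "n_draws": n_draws,
    }


# ---------------------------------------------------------------------------
# Exact forward truth for the score-association log odds ratio
# ---------------------------------------------------------------------------

def _genotype_count_distribution(eafs: np.ndarray) -> np.ndarray:
    """PMF of the summed allele count over independent HWE genotypes."""
    dist = np.array([1.0])
    for p in eafs:
        geno = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        dist = np.convolve(dist, geno)
    return dist


def forward_truth_lor(shared_eafs: np.ndarray, other_eafs: np.ndarray,
                      beta: float, prevalence: float) -> float:
    """Infinite-sample case-control logistic slope of disease on the score.

    Assumes equal published weights (score = total allele count), disease
    liability ``beta`` per shared allele, independent variants, and balanced
    case-control sampling.  The joint distribution of (score, status) is
    computed exactly; the slope is the maximizer of the expected
    case-control logistic likelihood, found by Newton iteration.
    """
    shared_eafs = np.asarray(shared_eafs, dtype=float)
    other_eafs = np.asarray(other_eafs, dtype=float)
    dist_sh = _genotype_count_distribution(shared_eafs)
    dist_oth = _genotype_count_distribution(other_eafs)
    g_sh = np.arange(len(dist_sh))
    mu_sh = 2.0 * shared_eafs.sum()
    var_g = beta ** 2 * np.sum(2.0 * shared_eafs * (1 - shared_eafs))
    sigma_e = np.sqrt(1.0 - var_g)
    T = stats.norm.isf(prevalence)
    k_given_sh = stats.norm.cdf((beta * (g_sh - mu_sh) - T) / sigma_e)

    # joint over total score s = g_shared + g_other
    n_s = len(dist_sh) + len(dist_oth) - 1
    p_case_s = np.convolve(dist_sh * k_given_sh, dist_oth)
    p_ctrl_s = np.convolve(dist_sh * (1 - k_given_sh), dist_oth)
    s = np.arange(n_s, dtype=float)
    # balanced case-control reweighting
    w_case = 0.5 * p_case_s / p_case_s.sum()
    w_ctrl = 0.5 * p_ctrl_s / p_ctrl_s.sum()

    X = np.column_stack([np.ones(n_s), s])
    params = np.zeros(2)
    for _ in range(100):
        eta = X @ params
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w_case * (1 - mu)) - X.T @ (w_ctrl * mu)
        w = (w_case + w_ctrl) * mu * (1 - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        params += step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(params[1])


def _recovery_spec(seed: int, n_cases: int, n_controls: int,
                   n_variants: int = 20, shared_fraction: float = 0.5,
                   effect: float = 0.08, prevalence: float = 0.05,
                   n_population: int | None = None) -> SimulationSpec:
    if n_population is None:
        # enough expected cases for the requested draw, with head-room
        n_population = int(np.ceil(1.6 * n_cases / prevalence))
    return SimulationSpec(
        n_population=n_population, n_cases=n_cases, n_controls=n_controls,
        n_traits=1, variants_per_trait=n_variants, ld_rho=0.0,
        disease_prevalence=prevalence, n_disease_variants=0,
        pleiotropy={"T01": PleiotropySpec(shared_fraction=shared_fraction,
                                          sign=1, effect=effect)},
        seed=seed,
    )


def score_recovery_study(n_seeds: int = 100, seed0: int = 1,
                         n_cases: int = 5_000, n_controls: int = 5_000) -> dict:
    """Pipeline recovery of the forward-computed score log odds ratio.

    One pleiotropic trait (20 variants, half disease-causal at 0.08 liability
    per allele), balanced case-control draws of the stated size.  Per seed
    the truth is recomputed exactly for that seed's allele frequencies, and
    coverage counts estimates within 3 standard errors of the truth.
    """
    covered, estimates, truths = [], [], []
    for i in range(n_seeds):
        spec = _recovery_spec(seed=seed0 + i, n_cases=n_cases, n_controls=n_controls)
        study = simulate_study(spec)
        k = spec.variants_per_trait // 2
        truth = forward_truth_lor(study.eafs[:k], study.eafs[k:],
                                  beta=0.08, prevalence=spec.disease_prevalence)
        scores = compute_genetic_scores(study.cohort, study.catalog)
        res = associate_score(scores, study.cohort, "T01")
        covered.append(abs(res.lor - truth) <= 3.0 * res.se)
        estimates.append(res.lor)
        truths.append(truth)
    return {
        "n_seeds": n_seeds,
        "coverage": float(np.mean(covered)),
        "mean_estimate": float(np.mean(estimates)),
        "mean_truth": float(np.mean(truths)),
    }


def null_calibration_study(n_reps: int = 200, seed0: int = 10_000,
                           n_traits: int = 10, variants_per_trait: int = 10,
                           n_cases: int = 2_000, n_controls: int = 2_000) -> dict:
    """Score-family false discovery rate with all pleiotropy switched off.

    The disease is driven only by private causal variants unlinked to any
    trait's variant set, so every score association is null.  Reports the
    mean fraction of traits reaching q < 0.01 across replicates.
    """
    from .association import associate_all_scores

    fractions = []
    for i in range(n_reps):
        spec = SimulationSpec(
            n_population=int(np.ceil(1.6 * n_cases / 0.05)),
            n_cases=n_cases, n_controls=n_controls,
            n_traits=n_traits, variants_per_trait=variants_per_trait,
            ld_rho=0.0, disease_prevalence=0.05,
            n_disease_variants=10, disease_effect=0.08,
            seed=seed0 + i,
        )
        study = simulate_study(spec)
        scores = compute_genetic_scores(study.cohort, study.catalog)
        results = associate_all_scores(scores, study.cohort)
        frac = np.mean([r.significant for r in results])
        fractions.append(frac)
    return {
        "n_reps": n_reps,
        "mean_fraction_discovered": float(np.mean(fractions)),
    }


# ---------------------------------------------------------------------------
# Conditional screen: linkage-only candidates lose significance
# ---------------------------------------------------------------------------

def _simulate_ld_pair_cohort(rng: np.random.Generator, n_population: int,
                             eaf: float, hap_corr: float, beta_known: float,
                             prevalence: float, n_cases: int, n_controls: int
                             ) -> CohortData:
    """Cohort with a causal known variant and a linkage-only candidate.

    The candidate's haplotype allele copies the known variant's allele with
    probability ``hap_corr`` (else an independent draw at the same
    frequency), giving dosage correlation ``hap_corr`` and hence
    r^2 = hap_corr^2.  Two further null known variants are independent.
    """
    import pandas as pd

    from .synthetic_data import _SUBTYPE_PROBS

    hap_known = rng.random((n_population, 2)) < eaf
    copy = rng.random((n_population, 2)) < hap_corr
    hap_fresh = rng.random((n_population, 2)) < eaf
    hap_cand = np.where(copy, hap_known, hap_fresh)
    g_known = hap_known.sum(axis=1).astype(float)
    g_cand = hap_cand.sum(axis=1).astype(float)
    g_null1 = rng.binomial(2, eaf, n_population).astype(float)
    g_null2 = rng.binomial(2, eaf, n_population).astype(float)

    systematic = beta_known * (g_known - 2 * eaf)
    sigma_e = np.sqrt(1.0 - beta_known ** 2 * 2 * eaf * (1 - eaf))
    liability = systematic + rng.standard_normal(n_population) * sigma_e
    case = liability > stats.norm.isf(prevalence)
    status = np.full(n_population, "CONTROL", dtype=object)
    status[case] = rng.choice(list(_SUBTYPE_PROBS), size=int(case.sum()),
                              p=list(_SUBTYPE_PROBS.values()))

    dosages = np.column_stack([g_cand, g_known, g_null1, g_null2]).astype(np.float32)
    meta = pd.DataFrame({
        "variant_id": ["cand", "known1", "known2", "known3"],
        "chrom": ["1", "1", "2", "3"],
        "pos": [1_000_000, 1_050_000, 1_000_000, 1_000_000],
        "effect_allele": ["A"] * 4, "other_allele": ["G"] * 4,
        "imputation_quality": [1.0] * 4,
    })
    samples = pd.DataFrame({
        "status": status,
        "age": rng.normal(76, 7, n_population).clip(55, 98),
        "sex": np.where(rng.random(n_population) < 0.5, "F", "M"),
        "dna_source": (rng.random(n_population) < 0.3).astype(int),
        "pc1": rng.standard_normal(n_population),
        "pc2": rng.standard_normal(n_population),
        "population_based": (rng.random(n_population) < 0.19).astype(int),
    }, index=pd.Index([f"S{i}" for i in range(n_population)], name="sample_id"))
    population = CohortData(dosages=dosages, variant_meta=meta, samples=samples)
    return sample_case_control(population, n_cases, n_controls, rng)


def conditional_confounding_study(n_seeds: int = 100, seed0: int = 20_000,
                                  n: int = 10_000, r2: float = 0.9,
                                  beta_known: float = 0.2, eaf: float = 0.3,
                                  prevalence: float = 0.05) -> dict:
    """Raw-significant, conditionally-null behavior of a linkage-only candidate.

    Per seed: a candidate in r^2 ~ 0.9 LD with a causal known variant (no
    direct effect) is screened raw and conditioned on the known variants.
    Success means raw p < 0.01 and conditioned p > 0.05.
    """
    from .association import build_design

    hap_corr = float(np.sqrt(r2))
    n_cases = n_controls = n // 2
    n_population = int(np.ceil(1.6 * n_cases / prevalence))
    successes, raw_sig, cond_ns = [], [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed0 + i)
        cohort = _simulate_ld_pair_cohort(
            rng, n_population, eaf, hap_corr, beta_known, prevalence,
            n_cases, n_controls)
        y = cohort.case_mask.astype(float)
        design, names = build_design(cohort)
        cand = cohort.dosage("cand")
        raw = fit_logistic(y, np.column_stack([design, cand]), names + ["cand"])
        knowns = np.column_stack([cohort.dosage(k) for k in
                                  ("known1", "known2", "known3")])
        cond = fit_logistic(
            y, np.column_stack([design, knowns, cand]),
            names + ["known1", "known2", "known3", "cand"])
        p_raw = raw.p_values[-1]
        p_cond = cond.p_values[-1]
        raw_sig.append(p_raw < 0.01)
        cond_ns.append(p_cond > 0.05)
        successes.append(p_raw < 0.01 and p_cond > 0.05)
    return {
        "n_seeds": n_seeds,
        "success_rate": float(np.mean(successes)),
        "raw_significant_rate": float(np.mean(raw_sig)),
        "conditioned_nonsignificant_rate": float(np.mean(cond_ns)),
    }


# ---------------------------------------------------------------------------
# Brute-force BH oracle (kept here so tests and acceptance share one copy)
# ---------------------------------------------------------------------------

def bh_brute_force(p_values) -> np.ndarray:
    """Literal step-up definition: q_i = min over p_(j) >= p_i of p_(j)*m/rank(j)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = np.empty(m)
    for idx, pi in enumerate(p):
        candidates = [ranked[j] * m / (j + 1)
                      for j in range(m) if ranked[j] >= pi]
        q[idx] = min(1.0, min(candidates))
    return q


def bh_oracle_equivalence(grid=(0.001, 0.02, 0.05, 0.5, 1.0),
                          max_len: int = 6) -> dict:
    """Compare bh_adjust with the brute-force step-up on a fixed grid.

    Enumerates every p-vector of length <= ``max_len`` over the grid (as
    multisets — BH is permutation equivariant, which is asserted on a
    sample) and counts discrepancies beyond 1e-12.
    """
    from itertools import combinations_with_replacement

    n_checked = 0
    n_discrepant = 0
    for length in range(1, max_len + 1):
        for combo in combinations_with_replacement(grid, length):
            p = np.array(combo)
            expected = bh_brute_force(p)
            got = bh_adjust(p)
            n_checked += 1
            if np.max(np.abs(expected - got)) > 1e-12:
                n_discrepant += 1
    return {"n_checked": n_checked, "n_discrepant": n_discrepant}
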