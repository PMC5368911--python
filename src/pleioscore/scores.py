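"""Weighted genetic scores, liability-scale variance explained, and score correlations.

The genetic score of an individual for a trait is the weighted count of
risk-increasing alleles divided by the trait's average weight,

    S_i = ( sum_j w_j d_ij ) / w_bar,    w_bar = mean_j w_j,

with d_ij the effect-allele dosage and w_j the published effect size (log OR,
log HR, or slope) oriented to the risk-/trait-increasing allele.  The
normalization gives the score an allele-count interpretation: an individual
whose score is one unit larger carries one additional risk allele of average
effect size, and a score of 50 corresponds to 50 "average" risk alleles.

Per-variant trait variance explained uses a liability-threshold model for
binary traits (allele frequency + per-allele OR + prevalence) and the exact
t-statistic/r^2 identity of simple linear regression for continuous traits.
Survival (log-HR) effects contribute to scores but have no variance method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalog import EffectType, OutcomeType, VariantCatalog
from .cohort import CohortData
from .errors import ConfigurationError, DomainError, NumericalError

logger = logging.getLogger(__name__)


@dataclass
class ScoreMatrix:
    """Per-individual genetic scores for a set of traits."""

    sample_ids: list[str]
    trait_ids: list[str]
    values: np.ndarray                                  # individuals x traits
    weights_used: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    mean_weight: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.trait_ids)

    def column(self, trait_id: str) -> np.ndarray:
        return self.values[:, self.trait_ids.index(trait_id)]


def compute_genetic_scores(cohort: CohortData, catalog: VariantCatalog) -> ScoreMatrix:
    """Weighted allele counts normalized by the trait's average weight.

    The catalog must be oriented (all weights >= 0).  Dosages are keyed to
    the risk-increasing allele; missing dosages are mean-imputed per variant
    (the cohort column mean, i.e. twice the cohort allele frequency).
    Variants absent from the cohort are excluded from both the numerator and
    the average weight, with a log record.  A trait whose surviving weights
    are all zero has no defined score and is skipped with a warning.
    """
    trait_ids, columns = [], []
    weights_used: dict[str, list[tuple[str, float]]] = {}
    mean_weight: dict[str, float] = {}
    for tid, trait in catalog.traits.items():
        total = np.zeros(cohort.n_samples)
        used: list[tuple[str, float]] = []
        for v in trait.variants:
            if v.effect_size < 0:
                raise ValueError(
                    f"catalog not oriented: {v.variant_id} has negative weight")
            if not cohort.has_variant(v.variant_id):
                logger.info("variant %s (%s) absent from cohort; excluded", v.variant_id, tid)
                continue
            d = cohort.dosage(v.variant_id, v.effect_allele)
            if np.isnan(d).any():
                fill = np.nanmean(d)
                d = np.where(np.isnan(d), fill, d)
            total += v.effect_size * d
            used.append((v.variant_id, v.effect_size))
        if not used or all(w == 0 for _, w in used):
            logger.warning("trait %s has no nonzero weights in the cohort; skipped", tid)
            continue
        w_bar = float(np.mean([w for _, w in used]))
        trait_ids.append(tid)
        columns.append(total / w_bar)
        weights_used[tid] = used
        mean_weight[tid] = w_bar
    values = np.column_stack(columns) if columns else np.empty((cohort.n_samples, 0))
    return ScoreMatrix(
        sample_ids=cohort.sample_ids, trait_ids=trait_ids, values=values,
        weights_used=weights_used, mean_weight=mean_weight,
    )


def solve_penetrances(eaf: float, or_per_allele: float, prevalence: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """HWE genotype frequencies and per-genotype disease risks.

    Solves for the baseline (zero-copy) risk K0 such that the per-genotype
    risks with odds(K_g) = odds(K0) * OR^g average to the population
    prevalence under Hardy-Weinberg genotype frequencies.
    Returns ``(f, K)`` with ``f = (f0, f1, f2)`` and ``K = (K0, K1, K2)``.
    """
    if not 0.0 < eaf < 1.0:
        raise DomainError(f"eaf {eaf} outside (0, 1)")
    if or_per_allele <= 0:
        raise DomainError(f"or_per_allele {or_per_allele} must be positive")
    if not 0.0 < prevalence < 1.0:
        raise DomainError(f"prevalence {prevalence} outside (0, 1)")
    f = np.array([(1 - eaf) ** 2, 2 * eaf * (1 - eaf), eaf ** 2])
    g = np.arange(3)

    def mean_risk(k0: float) -> float:
        odds = k0 / (1 - k0) * or_per_allele ** g
        return float(f @ (odds / (1 + odds))) - prevalence

    lo, hi = 1e-14, 1 - 1e-14
    try:
        k0 = optimize.brentq(mean_risk, lo, hi, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:
        raise NumericalError(
            f"penetrance solve failed for eaf={eaf}, OR={or_per_allele}, "
            f"K={prevalence}: {exc}")
    odds = k0 / (1 - k0) * or_per_allele ** g
    K = odds / (1 + odds)
    if K[2] >= 1.0:
        raise DomainError(
            f"OR {or_per_allele} too extreme: homozygote risk reaches 1")
    return f, K


def variance_explained_binary(eaf: float, or_per_allele: float, prevalence: float) -> float:
    """Liability-scale variance explained by one variant of a binary trait.

    Converts per-genotype risks (from the solved penetrances) to liability
    threshold shifts m_g = T - Phi^{-1}(1 - K_g), with T the population
    threshold, and returns the genotype-frequency-weighted variance of m_g.
    """
    f, K = solve_penetrances(eaf, or_per_allele, prevalence)
    T = stats.norm.isf(prevalence)
    m = T - stats.norm.isf(K)
    mean_m = float(f @ m)
    return float(f @ m ** 2 - mean_m ** 2)


def variance_explained_continuous(slope: float, se: float, n: int) -> float:
    """Variance explained by one variant of a continuous trait.

    Uses the exact identity between the regression t-statistic and r^2 in
    simple linear regression: with z = slope/se, r^2 = z^2 / (z^2 + n - 2).
    """
    if se <= 0:
        raise DomainError(f"se {se} must be positive")
    if n < 3:
        raise DomainError(f"n {n} must be >= 3")
    z = slope / se
    return float(z ** 2 / (z ** 2 + n - 2))


@dataclass
class VarianceExplained:
    trait_id: str
    per_variant: dict[str, float]
    total: float
    method: str          # "LIABILITY" | "SLOPE_SE" | "NOT_ESTIMABLE"


def trait_variance_summary(catalog: VariantCatalog) -> tuple[pd.DataFrame, dict]:
    """Per-trait variance explained (summed over variants) and the grand mean.

    Binary traits require a prevalence; continuous traits require per-variant
    standard errors and the GWAS sample size.  Survival traits are flagged
    not estimable.  Returns a per-trait frame (totals as percentages) and a
    summary dict with the unweighted mean, min and max across estimable
    traits.
    """
    rows = []
    for tid, trait in catalog.traits.items():
        if trait.outcome_type is OutcomeType.SURVIVAL:
            rows.append({"trait_id": tid, "method": "NOT_ESTIMABLE",
                         "n_variants": len(trait.variants),
                         "variance_explained_pct": np.nan})
            continue
        if trait.outcome_type is OutcomeType.BINARY:
            if trait.prevalence is None:
                raise ConfigurationError(f"binary trait {tid} has no prevalence")
            total = 0.0
            for v in trait.variants:
                if v.effect_type is EffectType.LOGHR:
                    continue  # no liability mapping for hazard ratios
                total += variance_explained_binary(
                    v.eaf, float(np.exp(v.effect_size)), trait.prevalence)
            method = "LIABILITY"
        else:
            if trait.gwas_n is None:
                raise ConfigurationError(
                    f"continuous trait {tid} has no GWAS sample size")
            total = 0.0
            for v in trait.variants:
                if v.se is None:
                    raise ConfigurationError(
                        f"continuous trait {tid}: variant {v.variant_id} has no se")
                total += variance_explained_continuous(v.effect_size, v.se, trait.gwas_n)
            method = "SLOPE_SE"
        rows.append({"trait_id": tid, "method": method,
                     "n_variants": len(trait.variants),
                     "variance_explained_pct": 100.0 * total})
    frame = pd.DataFrame(rows, columns=["trait_id", "method", "n_variants",
                                        "variance_explained_pct"])
    est = frame["variance_explained_pct"].dropna()
    summary = {
        "mean_pct": float(est.mean()) if len(est) else float("nan"),
        "min_pct": float(est.min()) if len(est) else float("nan"),
        "max_pct": float(est.max()) if len(est) else float("nan"),
        "n_traits": int(len(est)),
    }
    return frame, summary


@dataclass
class CorrelationResult:
    """Pairwise Spearman correlation of genetic scores with BH q-values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    def significance_tier(self, trait_a: str, trait_b: str) -> str:
        """'', '*', '**', '***' at q < 0.01 / 0.001 / 0.0001."""
        q = self.q.loc[trait_a, trait_b]
        if not np.isfinite(q):
            return ""
        for stars, cut in (("***", 1e-4), ("**", 1e-3), ("*", 1e-2)):
            if q < cut:
                return stars
        return ""


def score_correlation_matrix(scores: ScoreMatrix) -> CorrelationResult:
    """Spearman correlation for each trait pair with BH-adjusted q-values.

    Constant score vectors have undefined correlation and are reported as
    missing.  Requires at least two traits and ten individuals.
    """
    from .association import bh_adjust  # local import to avoid a cycle

    t = len(scores.trait_ids)
    if t < 2:
        raise ConfigurationError("correlation needs at least two traits")
    if len(scores.sample_ids) < 10:
        raise ConfigurationError("correlation needs at least ten individuals")
    rho = np.eye(t)
    p = np.full((t, t), np.nan)
    np.fill_diagonal(p, 0.0)
    constant = [np.ptp(scores.values[:, i]) == 0 for i in range(t)]
    pairs = []
    for i in range(t):
        for j in range(i + 1, t):
            if constant[i] or constant[j]:
                rho[i, j] = rho[j, i] = np.nan
                continue
            r, pv = stats.spearmanr(scores.values[:, i], scores.values[:, j])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
            pairs.append((i, j, pv))
    q = np.full((t, t), np.nan)
    np.fill_diagonal(q, 0.0)
    if pairs:
        # guard against p underflowing to exactly 0 for near-perfect correlations
        qvals = bh_adjust(np.clip([pv for _, _, pv in pairs], 1e-300, 1.0))
        for (i, j, _), qv in zip(pairs, qvals):
            q[i, j] = q[j, i] = qv
    ids = scores.trait_ids
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p=pd.DataFrame(p, index=ids, columns=ids),
        q=pd.DataFrame(q, index=ids, columns=ids),
    )
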