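"""Covariate-adjusted logistic association of scores and variants with disease.

Every model is a logistic regression of case/control status on the quantity
of interest (a genetic score, or a single variant's effect-allele dosage)
plus the covariate set — by default age, sex, DNA source, and the first two
genotype principal components.  Effects are reported as log odds ratios with
Wald standard errors and p-values; multiple testing is controlled with the
Benjamini-Hochberg step-up at FDR < 1%, separately within the score family
and the variant family.

The conditional screen refits each candidate variant with the known disease
variants' dosages appended to the covariates, so that a candidate owing its
signal purely to linkage with a known variant loses significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .catalog import VariantCatalog
from .cohort import DEFAULT_COVARIATES, CohortData
from .errors import CollinearityError, DomainError, NumericalError, SeparationError
from .scores import ScoreMatrix

logger = logging.getLogger(__name__)

FDR_LEVEL = 0.01
MIN_STRATUM_SIZE = 50
_MAX_ABS_COEF = 30.0


@dataclass
class FitResult:
    coefficients: np.ndarray
    ses: np.ndarray
    p_values: np.ndarray
    converged: bool
    names: list[str]
    n_used: int
    n_dropped: int


@dataclass
class AssociationResult:
    """Effect of one score or variant on disease, raw or conditioned."""

    target_id: str
    lor: float
    se: float
    p: float
    q: float = float("nan")
    model: str = "RAW"            # "RAW" | "CONDITIONED"
    subgroup: str | None = None
    n: int = 0
    underpowered: bool = False
    error: str | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.lor - 1.96 * self.se, self.lor + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.lor))

    @property
    def significant(self) -> bool:
        return np.isfinite(self.q) and self.q < FDR_LEVEL


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci95
        rows.append({
            "target_id": r.target_id, "model": r.model, "subgroup": r.subgroup,
            "lor": r.lor, "se": r.se, "or": r.odds_ratio,
            "ci95_low": lo, "ci95_high": hi, "p": r.p, "q": r.q,
            "significant": r.significant, "n": r.n,
            "underpowered": r.underpowered, "error": r.error,
        })
    return pd.DataFrame(rows)


def fit_logistic(response: np.ndarray, design: np.ndarray,
                 names: Sequence[str] | None = None) -> FitResult:
    """Maximum-likelihood logistic fit with Wald z p-values.

    ``design`` must include an intercept column.  Rows with any missing value
    are dropped pairwise (count logged).  Rank-deficient designs raise
    :class:`CollinearityError` naming the offending column; perfect
    separation (or any |coefficient| > 30) raises :class:`SeparationError`.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("response and design are not aligned")
    names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]

    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing values", n_dropped)
        y, X = y[keep], X[keep]

    # rank check before fitting, naming a dependent column via QR pivoting
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        col = int(np.argmin(diag))
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"column {names[col]!r} is collinear", column=names[col])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=50,
                                     tol=1e-10, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation in logistic fit: {exc}")
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular information matrix: {exc}")

    coefs = np.asarray(res.params, dtype=float)
    if np.any(np.abs(coefs) > _MAX_ABS_COEF):
        col = int(np.argmax(np.abs(coefs)))
        raise SeparationError(
            f"coefficient for {names[col]!r} diverged (|{coefs[col]:.1f}| > "
            f"{_MAX_ABS_COEF:g}); data are likely separated", column=names[col])
    ses = np.asarray(res.bse, dtype=float)
    z = coefs / ses
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(coefficients=coefs, ses=ses, p_values=p,
                     converged=bool(res.mle_retvals.get("converged", True)),
                     names=names, n_used=len(y), n_dropped=n_dropped)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), capped at
    1; monotone non-decreasing in p, with ties sharing a q.  An empty vector
    yields an empty vector; p outside (0, 1] is a domain error.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_design(cohort: CohortData, covariates: Sequence[str] = DEFAULT_COVARIATES,
                 extra: dict[str, np.ndarray] | None = None
                 ) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns (+ optional extra columns) as a matrix."""
    allowed = {"age", "sex", "dna_source", "pc1", "pc2"}
    bad = set(covariates) - allowed
    if bad:
        raise ValueError(f"unknown covariates: {sorted(bad)}")
    cols = [np.ones(cohort.n_samples)]
    names = ["intercept"]
    for cov in covariates:
        col = cohort.samples[cov]
        if cov == "sex":
            col = col.map({"F": 0.0, "M": 1.0, 0: 0.0, 1: 1.0, "0": 0.0, "1": 1.0})
        cols.append(col.to_numpy(dtype=float))
        names.append(cov)
    for name, col in (extra or {}).items():
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
    return np.column_stack(cols), names


def _fit_target(cohort: CohortData, target: np.ndarray, target_name: str,
                covariates: Sequence[str],
                extra: dict[str, np.ndarray] | None = None,
                model: str = "RAW", subgroup: str | None = None
                ) -> AssociationResult:
    design, names = build_design(cohort, covariates, extra=extra)
    design = np.column_stack([design, target])
    names = names + [target_name]
    y = cohort.case_mask.astype(float)
    fit = fit_logistic(y, design, names)
    return AssociationResult(
        target_id=target_name, lor=float(fit.coefficients[-1]),
        se=float(fit.ses[-1]), p=float(max(fit.p_values[-1], 5e-324)),
        model=model, subgroup=subgroup, n=fit.n_used,
    )


def associate_score(scores: ScoreMatrix, cohort: CohortData, trait_id: str,
                    covariates: Sequence[str] = DEFAULT_COVARIATES,
                    subgroup: str | None = None) -> AssociationResult:
    """Association of one trait's genetic score with case/control status.

    The log odds ratio is per unit score, i.e. the disease-risk increase per
    one additional risk allele of average effect size.
    """
    if trait_id not in scores.trait_ids:
        raise KeyError(f"no score column for trait {trait_id}")
    return _fit_target(cohort, scores.column(trait_id), trait_id, covariates,
                       subgroup=subgroup)


def associate_all_scores(scores: ScoreMatrix, cohort: CohortData,
                         covariates: Sequence[str] = DEFAULT_COVARIATES,
                         subgroup: str | None = None) -> list[AssociationResult]:
    """All score associations with BH q-values across the score family.

    Per-score failures (collinearity, separation) are captured in the result
    rather than aborting the family.
    """
    results: list[AssociationResult] = []
    for tid in scores.trait_ids:
        try:
            results.append(associate_score(scores, cohort, tid, covariates,
                                           subgroup=subgroup))
        except (CollinearityError, SeparationError, NumericalError) as exc:
            logger.warning("score %s failed: %s", tid, exc)
            results.append(AssociationResult(
                target_id=tid, lor=float("nan"), se=float("nan"),
                p=float("nan"), subgroup=subgroup, error=str(exc)))
    _attach_q(results)
    return results


def _attach_q(results: list[AssociationResult]) -> None:
    ok = [r for r in results if np.isfinite(r.p)]
    if ok:
        q = bh_adjust([r.p for r in ok])
        for r, qv in zip(ok, q):
            r.q = float(qv)


def screen_variants(cohort: CohortData, catalog: VariantCatalog,
                    covariates: Sequence[str] = DEFAULT_COVARIATES
                    ) -> list[AssociationResult]:
    """Per-variant association screen across all catalog variants.

    Variants listed under several traits are screened once.  Per-variant
    failures (e.g. monomorphic dosage columns) are captured per entry and
    never abort the screen.  BH q-values span all successfully screened
    variants.
    """
    by_id = {}
    for v in catalog.all_variants:
        by_id.setdefault(v.variant_id, v)
    results: list[AssociationResult] = []
    for vid, v in by_id.items():
        if not cohort.has_variant(vid):
            logger.info("variant %s absent from cohort; not screened", vid)
            continue
        try:
            d = cohort.dosage(vid, v.effect_allele)
            results.append(_fit_target(cohort, d, vid, covariates))
        except (CollinearityError, SeparationError, KeyError) as exc:
            logger.warning("variant %s failed: %s", vid, exc)
            results.append(AssociationResult(
                target_id=vid, lor=float("nan"), se=float("nan"),
                p=float("nan"), error=str(exc)))
    _attach_q(results)
    return results


def conditional_screen(cohort: CohortData, catalog: VariantCatalog,
                       known_variant_ids: Sequence[str],
                       covariates: Sequence[str] = DEFAULT_COVARIATES
                       ) -> list[AssociationResult]:
    """Variant screen conditioned on the known disease variants.

    Each candidate is refit with the known variants' dosage columns appended
    to the covariates; q-values are recomputed on the conditioned p-values.
    A candidate that itself is a known variant is skipped (it cannot be
    conditioned on itself).  With no known variants the output equals the
    raw screen.
    """
    known = [k for k in known_variant_ids if cohort.has_variant(k)]
    absent = set(known_variant_ids) - set(known)
    if absent:
        logger.warning("known variants absent from cohort: %s", sorted(absent))
    extra = {f"known:{k}": cohort.dosage(k) for k in known}
    by_id = {}
    for v in catalog.all_variants:
        by_id.setdefault(v.variant_id, v)
    results: list[AssociationResult] = []
    for vid, v in by_id.items():
        if vid in set(known_variant_ids):
            logger.info("candidate %s is a known variant; skipped", vid)
            continue
        if not cohort.has_variant(vid):
            continue
        try:
            d = cohort.dosage(vid, v.effect_allele)
            results.append(_fit_target(cohort, d, vid, covariates, extra=extra,
                                       model="CONDITIONED"))
        except (CollinearityError, SeparationError, KeyError) as exc:
            logger.warning("variant %s failed conditioned fit: %s", vid, exc)
            results.append(AssociationResult(
                target_id=vid, lor=float("nan"), se=float("nan"),
                p=float("nan"), model="CONDITIONED", error=str(exc)))
    _attach_q(results)
    return results


STRATIFIERS = ("AGE75", "SEX", "SUBTYPE", "POPULATION_BASED")


def _strata(cohort: CohortData, stratifier: str) -> list[tuple[str, np.ndarray, list[str]]]:
    """(label, sample mask, covariates to drop) per stratum."""
    s = cohort.samples
    if stratifier == "AGE75":
        age = s["age"].to_numpy(dtype=float)
        return [("age<75", age < 75, ["age"]), ("age>=75", age >= 75, ["age"])]
    if stratifier == "SEX":
        sex = s["sex"].astype(str).str.upper()
        male = sex.isin(["M", "1"]).to_numpy()
        return [("male", male, ["sex"]), ("female", ~male, ["sex"])]
    if stratifier == "SUBTYPE":
        status = s["status"]
        controls = (status == "CONTROL").to_numpy()
        ga = controls | (status == "GA").to_numpy()
        nv = controls | status.isin(["NV", "MIXED"]).to_numpy()
        return [("GA", ga, []), ("NV", nv, [])]
    if stratifier == "POPULATION_BASED":
        flag = s["population_based"].astype(bool).to_numpy()
        return [("population_based", flag, [])]
    raise ValueError(f"unknown stratifier {stratifier!r}; one of {STRATIFIERS}")


def subgroup_association(scores: ScoreMatrix, cohort: CohortData, stratifier: str,
                         covariates: Sequence[str] = DEFAULT_COVARIATES
                         ) -> dict[str, list[AssociationResult]]:
    """Score associations within each stratum of a stratifier.

    AGE75 splits at age < 75 vs >= 75; SEX at male vs female (dropping the
    sex covariate); SUBTYPE keeps all controls and restricts cases to GA or
    to NV + mixed; POPULATION_BASED restricts to flagged samples.  Strata
    with fewer than 50 cases or 50 controls are flagged underpowered but
    still reported.  Subgroup results are descriptive: q-values are computed
    within each stratum's score family only.
    """
    out: dict[str, list[AssociationResult]] = {}
    for label, mask, dropped in _strata(cohort, stratifier):
        sub = cohort.subset_samples(mask)
        sub_scores = ScoreMatrix(
            sample_ids=[sid for sid, m in zip(scores.sample_ids, mask) if m],
            trait_ids=scores.trait_ids, values=scores.values[mask],
            weights_used=scores.weights_used, mean_weight=scores.mean_weight)
        covs = [c for c in covariates if c not in dropped]
        results = associate_all_scores(sub_scores, sub, covs, subgroup=label)
        n_cases = int(sub.case_mask.sum())
        n_controls = int(sub.control_mask.sum())
        if n_cases < MIN_STRATUM_SIZE or n_controls < MIN_STRATUM_SIZE:
            for r in results:
                r.underpowered = True
        out[label] = results
    return out
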