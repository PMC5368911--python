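"""Published-variant catalogs: loading, validation, orientation, and inclusion filters.

A catalog holds, per disease/trait, the published genome-wide significant lead
variants together with their effect alleles and effect sizes (log odds ratio
for binary outcomes, log hazard ratio for survival, slope for continuous
traits).  The operations here enforce the inclusion rules of the scan:

* genome-wide significance (p < 5e-8) at ingestion;
* at least three surviving variants per trait;
* one lead variant per +/- 1 Mbp cluster (smallest association p), unless a
  variant is explicitly flagged as an independent secondary signal;
* imputation quality > 0.3 in the genotyped cohort, with substitution of a
  published proxy (r^2 > 0.95) when the primary variant is poorly imputed;
* orientation of every effect to the risk-/trait-increasing allele, so all
  score weights are non-negative.

Every dropped row carries a reason code in a :class:`FilterReport`, so a run
can account for each published variant.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

# Inclusion thresholds of the scan.
GWS_THRESHOLD = 5e-8
MIN_VARIANTS_PER_TRAIT = 3
IMPUTATION_QUALITY_MIN = 0.3
PROXY_R2_MIN = 0.95
LEAD_WINDOW_BP = 1_000_000

_STRAND_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_ALLELE_RE = re.compile(r"^(?:[ACGT]+|<[^<>]+>)$")


class EffectType(str, enum.Enum):
    """Scale of a published effect size."""

    LOR = "LOR"        # log odds ratio (binary outcome)
    LOGHR = "LOGHR"    # log hazard ratio (survival outcome)
    SLOPE = "SLOPE"    # linear-regression slope (continuous outcome)


class OutcomeType(str, enum.Enum):
    BINARY = "BINARY"
    CONTINUOUS = "CONTINUOUS"
    SURVIVAL = "SURVIVAL"


@dataclass(frozen=True)
class CatalogVariant:
    """One published trait-associated variant.

    ``effect_size`` is always stored on the log/slope scale.  ``proxy_of``
    names a published proxy variant (r^2 ``proxy_r2`` with this one) that may
    stand in when this variant is poorly imputed in the cohort.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    effect_size: float
    effect_type: EffectType
    p_value: float
    eaf: float
    trait_id: str
    imputation_quality: float | None = None
    se: float | None = None
    proxy_of: str | None = None
    proxy_r2: float | None = None
    multi_signal: bool = False

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.effect_allele, self.other_allele) in _STRAND_AMBIGUOUS

    @property
    def is_structural(self) -> bool:
        return self.effect_allele.startswith("<") or self.other_allele.startswith("<")


@dataclass
class TraitDefinition:
    """A disease/trait with its outcome type and surviving variant set."""

    trait_id: str
    name: str
    category: str
    outcome_type: OutcomeType
    prevalence: float | None = None
    gwas_n: int | None = None
    variants: list[CatalogVariant] = field(default_factory=list)


@dataclass
class VariantCatalog:
    """Mapping of trait_id to :class:`TraitDefinition`."""

    traits: dict[str, TraitDefinition]

    @property
    def all_variants(self) -> list[CatalogVariant]:
        return [v for t in self.traits.values() for v in t.variants]

    @property
    def n_variants(self) -> int:
        return sum(len(t.variants) for t in self.traits.values())

    def unique_variant_ids(self) -> list[str]:
        """Variant IDs deduplicated across traits, in first-seen order."""
        seen: dict[str, None] = {}
        for v in self.all_variants:
            seen.setdefault(v.variant_id, None)
        return list(seen)


@dataclass(frozen=True)
class FilterRecord:
    variant_id: str
    trait_id: str
    action: str   # "kept" | "dropped" | "proxy_substituted" | "flagged"
    reason: str


@dataclass
class FilterReport:
    """Per-variant accounting of a filtering step."""

    records: list[FilterRecord] = field(default_factory=list)

    def add(self, variant_id: str, trait_id: str, action: str, reason: str) -> None:
        self.records.append(FilterRecord(variant_id, trait_id, action, reason))

    @property
    def n_kept(self) -> int:
        return sum(r.action in ("kept", "proxy_substituted") for r in self.records)

    @property
    def n_dropped(self) -> int:
        return sum(r.action == "dropped" for r in self.records)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            if r.action != "flagged":
                out[r.reason] = out.get(r.reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.variant_id, r.trait_id, r.action, r.reason) for r in self.records],
            columns=["variant_id", "trait_id", "action", "reason"],
        )


_REQUIRED_CATALOG_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "effect_size", "effect_type", "p_value", "eaf", "trait_id",
]
_REQUIRED_TRAIT_COLUMNS = ["trait_id", "name", "category", "outcome_type"]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    return (special.get(c.upper(), 99), c)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == ".":
        return None
    return float(value)


def _parse_row(row: Mapping, exp_scale: bool) -> CatalogVariant:
    """Build one validated CatalogVariant from a raw table row.

    Raises ValueError with a row-level message for unparseable fields.
    """
    ea = str(row["effect_allele"]).strip().upper()
    oa = str(row["other_allele"]).strip().upper()
    for allele in (ea, oa):
        if not _ALLELE_RE.match(allele):
            raise ValueError(f"invalid allele {allele!r}")
    if ea == oa:
        raise ValueError(f"effect allele equals other allele ({ea})")

    effect_type = EffectType(str(row["effect_type"]).strip().upper())
    effect_size = float(row["effect_size"])
    if exp_scale:
        # Published as an OR/HR ratio: move to the log scale at ingestion.
        if effect_type in (EffectType.LOR, EffectType.LOGHR):
            if effect_size <= 0:
                raise ValueError(f"ratio-scale effect must be positive, got {effect_size}")
            effect_size = math.log(effect_size)

    p_value = float(row["p_value"])
    if not 0.0 < p_value <= 1.0:
        raise ValueError(f"p_value {p_value} outside (0, 1]")
    eaf = float(row["eaf"])
    if not 0.0 < eaf < 1.0:
        raise ValueError(f"eaf {eaf} outside (0, 1)")
    pos = int(row["pos"])
    if pos < 1:
        raise ValueError(f"pos {pos} must be >= 1 (1-based coordinates)")

    proxy_of = row.get("proxy_of")
    proxy_of = None if proxy_of in (None, ".", "") or (
        isinstance(proxy_of, float) and math.isnan(proxy_of)) else str(proxy_of)
    proxy_r2 = _opt_float(row.get("proxy_r2"))
    if proxy_of is not None and (proxy_r2 is None or not 0.0 < proxy_r2 <= 1.0):
        raise ValueError(
            f"proxy {proxy_of} requires proxy_r2 in (0, 1], got {proxy_r2}")

    multi = row.get("multi_signal")
    multi_signal = bool(int(multi)) if multi not in (None, ".", "") and not (
        isinstance(multi, float) and math.isnan(multi)) else False

    return CatalogVariant(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        effect_size=effect_size,
        effect_type=effect_type,
        p_value=p_value,
        eaf=eaf,
        trait_id=str(row["trait_id"]),
        imputation_quality=_opt_float(row.get("imputation_quality")),
        se=_opt_float(row.get("se")),
        proxy_of=proxy_of,
        proxy_r2=proxy_r2,
        multi_signal=multi_signal,
    )


def load_variant_catalog(
    catalog_path, traits_path
) -> tuple[VariantCatalog, FilterReport]:
    """Read and validate a variant catalog and its trait-definition table.

    Both files are UTF-8 TSV with a header row and '.' for missing values.
    Rows failing genome-wide significance (p >= 5e-8) are rejected with a
    logged reason; traits left with fewer than three variants are dropped
    with a warning.  Row-level parse failures are collected in the report
    rather than aborting the load; a missing required column aborts with
    :class:`FormatError`.
    """
    cat = pd.read_csv(catalog_path, sep="\t", dtype={"chrom": str}, na_values=["."])
    missing = [c for c in _REQUIRED_CATALOG_COLUMNS if c not in cat.columns]
    if missing:
        raise FormatError(f"catalog file missing required columns: {missing}")

    tra = pd.read_csv(traits_path, sep="\t", dtype={"trait_id": str}, na_values=["."])
    missing = [c for c in _REQUIRED_TRAIT_COLUMNS if c not in tra.columns]
    if missing:
        raise FormatError(f"trait file missing required columns: {missing}")

    report = FilterReport()
    traits: dict[str, TraitDefinition] = {}
    for _, trow in tra.iterrows():
        tid = str(trow["trait_id"])
        traits[tid] = TraitDefinition(
            trait_id=tid,
            name=str(trow["name"]),
            category=str(trow["category"]),
            outcome_type=OutcomeType(str(trow["outcome_type"]).strip().upper()),
            prevalence=_opt_float(trow.get("prevalence")),
            gwas_n=None if _opt_float(trow.get("gwas_n")) is None else int(trow["gwas_n"]),
        )

    exp_scale = "exp_scale" in cat.columns
    seen: set[tuple[str, str]] = set()
    for _, row in cat.iterrows():
        rowd = row.to_dict()
        if exp_scale:
            es = rowd.get("exp_scale")
            rowd_exp = bool(int(es)) if es not in (None, "") and not (
                isinstance(es, float) and math.isnan(es)) else False
        else:
            rowd_exp = False
        vid, tid = str(rowd.get("variant_id")), str(rowd.get("trait_id"))
        try:
            variant = _parse_row(rowd, rowd_exp)
        except (ValueError, KeyError) as exc:
            report.add(vid, tid, "dropped", f"parse_error: {exc}")
            continue
        if (variant.trait_id, variant.variant_id) in seen:
            report.add(vid, tid, "dropped", "duplicate_trait_variant_pair")
            continue
        if variant.trait_id not in traits:
            report.add(vid, tid, "dropped", "unknown_trait")
            continue
        if variant.p_value >= GWS_THRESHOLD:
            report.add(vid, tid, "dropped", "not_genome_wide_significant")
            continue
        seen.add((variant.trait_id, variant.variant_id))
        traits[variant.trait_id].variants.append(variant)
        report.add(vid, tid, "kept", "passed_ingestion")
        if variant.is_strand_ambiguous:
            report.add(vid, tid, "flagged", "strand_ambiguous")

    catalog = VariantCatalog(traits=traits)
    catalog, report = _drop_small_traits(catalog, report, "after ingestion")
    for tid, trait in catalog.traits.items():
        logger.info("trait %s: %d variants after ingestion", tid, len(trait.variants))
    return catalog, report


def _drop_small_traits(
    catalog: VariantCatalog, report: FilterReport, stage: str
) -> tuple[VariantCatalog, FilterReport]:
    kept: dict[str, TraitDefinition] = {}
    for tid, trait in catalog.traits.items():
        if len(trait.variants) < MIN_VARIANTS_PER_TRAIT:
            logger.warning(
                "trait %s dropped %s: %d variants (< %d required)",
                tid, stage, len(trait.variants), MIN_VARIANTS_PER_TRAIT,
            )
            doomed = {(v.variant_id, tid) for v in trait.variants}
            # a variant kept earlier in this step is ultimately dropped with
            # its trait: replace the record so kept + dropped = input count
            doomed_ids = {vid for vid, _ in doomed}
            report.records = [
                r for r in report.records
                if r.action == "flagged"
                or ((r.variant_id, r.trait_id) not in doomed
                    # a proxy-substituted record carries the original id
                    and not (r.trait_id == tid
                             and r.reason.split(":")[-1] in doomed_ids))
            ]
            for v in trait.variants:
                report.add(v.variant_id, tid, "dropped", "trait_below_min_variants")
        else:
            kept[tid] = trait
    return VariantCatalog(traits=kept), report


def orient_effects(catalog: VariantCatalog) -> VariantCatalog:
    """Orient every effect to the risk-/trait-increasing allele.

    A variant with a negative published effect has its alleles swapped, its
    effect-allele frequency complemented, and its effect size negated, so
    that afterwards all weights are >= 0.  Zero effects are retained with a
    warning (weight-0 alleles never move a score).  Idempotent.
    """
    traits: dict[str, TraitDefinition] = {}
    for tid, trait in catalog.traits.items():
        oriented = []
        for v in trait.variants:
            if v.effect_size < 0:
                v = replace(
                    v,
                    effect_allele=v.other_allele,
                    other_allele=v.effect_allele,
                    effect_size=-v.effect_size,
                    eaf=1.0 - v.eaf,
                )
            elif v.effect_size == 0:
                logger.warning("variant %s (%s) has zero effect size", v.variant_id, tid)
            oriented.append(v)
        traits[tid] = replace(trait, variants=oriented)
    return VariantCatalog(traits=traits)


def select_lead_variants(variants: Iterable[CatalogVariant]) -> list[CatalogVariant]:
    """One lead variant per +/- 1 Mbp cluster on a chromosome.

    Iteratively takes the remaining variant with the smallest association p
    value and removes all others within 1 Mbp on the same chromosome.
    Variants flagged ``multi_signal`` (explicitly reported independent
    secondary signals) bypass removal.  Ties on p break deterministically by
    chromosome order, then position, then variant_id.
    """
    def sort_key(v: CatalogVariant):
        return (v.p_value, _chrom_sort_key(v.chrom), v.pos, v.variant_id)

    remaining = sorted(variants, key=sort_key)
    kept: list[CatalogVariant] = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        remaining = [
            v for v in remaining
            if v.multi_signal
            or v.chrom != lead.chrom
            or abs(v.pos - lead.pos) > LEAD_WINDOW_BP
        ]
    kept.sort(key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.variant_id))
    return kept


def select_leads(catalog: VariantCatalog) -> VariantCatalog:
    """Apply :func:`select_lead_variants` within each trait."""
    traits = {
        tid: replace(t, variants=select_lead_variants(t.variants))
        for tid, t in catalog.traits.items()
    }
    return VariantCatalog(traits=traits)


def apply_quality_filters(
    catalog: VariantCatalog, quality: Mapping[str, float]
) -> tuple[VariantCatalog, FilterReport]:
    """Enforce cohort imputation-quality rules with proxy substitution.

    ``quality`` maps variant_id to imputation quality in the genotyped
    cohort.  A variant is kept when its quality is > 0.3.  Otherwise, if a
    published proxy (r^2 > 0.95) is itself well imputed, the proxy is
    substituted (the record keeps the published weight and alleles but takes
    the proxy's identity and quality).  A variant absent from the quality map
    has no genotype support and is dropped under its own reason code.  Traits
    falling below three variants are dropped.
    """
    report = FilterReport()
    traits: dict[str, TraitDefinition] = {}
    for tid, trait in catalog.traits.items():
        surviving = []
        for v in trait.variants:
            q = quality.get(v.variant_id)
            if q is not None and q > IMPUTATION_QUALITY_MIN:
                surviving.append(replace(v, imputation_quality=q))
                report.add(v.variant_id, tid, "kept", "quality_ok")
                if v.is_strand_ambiguous:
                    report.add(v.variant_id, tid, "flagged", "strand_ambiguous")
                continue
            proxy_q = quality.get(v.proxy_of) if v.proxy_of else None
            if (
                v.proxy_of is not None
                and v.proxy_r2 is not None
                and v.proxy_r2 > PROXY_R2_MIN
                and proxy_q is not None
                and proxy_q > IMPUTATION_QUALITY_MIN
            ):
                surviving.append(
                    replace(v, variant_id=v.proxy_of, imputation_quality=proxy_q,
                            proxy_of=None, proxy_r2=None)
                )
                report.add(v.variant_id, tid, "proxy_substituted",
                           f"substituted_by:{v.proxy_of}")
                continue
            reason = "no_genotype_support" if q is None else "low_imputation_quality"
            report.add(v.variant_id, tid, "dropped", reason)
        traits[tid] = replace(trait, variants=surviving)
    catalog = VariantCatalog(traits=traits)
    return _drop_small_traits(catalog, report, "after quality filtering")


def write_catalog(catalog: VariantCatalog, path) -> None:
    """Serialize a catalog back to the TSV dialect read by the loader."""
    rows = []
    for v in catalog.all_variants:
        rows.append({
            "variant_id": v.variant_id, "chrom": v.chrom, "pos": v.pos,
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "effect_size": v.effect_size, "effect_type": v.effect_type.value,
            "p_value": v.p_value, "eaf": v.eaf, "trait_id": v.trait_id,
            "imputation_quality": v.imputation_quality if v.imputation_quality is not None else ".",
            "se": v.se if v.se is not None else ".",
            "proxy_of": v.proxy_of if v.proxy_of is not None else ".",
            "proxy_r2": v.proxy_r2 if v.proxy_r2 is not None else ".",
            "multi_signal": int(v.multi_signal),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_traits(catalog: VariantCatalog, path) -> None:
    rows = []
    for t in catalog.traits.values():
        rows.append({
            "trait_id": t.trait_id, "name": t.name, "category": t.category,
            "outcome_type": t.outcome_type.value,
            "prevalence": t.prevalence if t.prevalence is not None else ".",
            "gwas_n": t.gwas_n if t.gwas_n is not None else ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
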