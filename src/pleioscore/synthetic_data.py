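"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the minimal features the pipeline consumes: imputed
genotype dosages with block-wise linkage disequilibrium, a published-variant
catalog per trait, demographic covariates, and a case-control disease arising
from a liability-threshold model with tunable pleiotropic sharing between the
disease's causal variants and each trait's variant set.

Genotypes come from a latent-Gaussian copula: within a block, haplotype
alleles share a common Gaussian factor with loading sqrt(ld_rho), so pairwise
LD is controlled directly; blocks are independent and physically separated.
Disease liability is

    L = sum_j beta_j (g_j - 2 p_j) + covariate terms + eps,

with eps scaled so Var(L) = 1 over the population, and an individual is a
case when L exceeds the threshold Phi^{-1}(1 - prevalence).  This is exactly
the generative model under which the liability-threshold variance-explained
computation is calibrated, so the generator doubles as a ground-truth oracle
in parameter-recovery tests.

Reproducibility: one seed per spec, with derived per-stage substreams
(genotypes, covariates/phenotypes, catalog, sampling), so identical specs
give identical cohorts and individual stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (CatalogVariant, EffectType, OutcomeType, TraitDefinition,
                      VariantCatalog)
from .cohort import CohortData, write_dosage_tsv, write_samples_tsv
from .errors import DomainError
from .loci import LocusInterval, write_loci_bed

_SUBTYPE_PROBS = {"GA": 0.35, "NV": 0.45, "MIXED": 0.20}


@dataclass(frozen=True)
class PleiotropySpec:
    """Sharing between one trait's variant set and the disease's causal set.

    ``shared_fraction`` of the trait's variants carry a disease liability
    effect of ``sign * effect`` per allele (liability SD units).
    """

    shared_fraction: float = 0.0
    sign: int = 1
    effect: float = 0.0


@dataclass(frozen=True)
class CovariateEffects:
    """Liability effects (per SD of the covariate) for the covariate terms."""

    age: float = 0.0
    sex: float = 0.0
    dna_source: float = 0.0
    pc: float = 0.0


@dataclass
class SimulationSpec:
    n_population: int = 20_000
    n_cases: int = 1_000
    n_controls: int = 1_000
    n_traits: int = 5
    variants_per_trait: int = 10
    ld_block_size: int = 5
    ld_rho: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.5)
    disease_prevalence: float = 0.05
    n_disease_variants: int = 10          # disease-private causal variants
    disease_effect: float = 0.08          # their per-allele liability effect
    pleiotropy: dict[str, PleiotropySpec] = field(default_factory=dict)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    trait_effect_size: float = 0.1        # published per-allele weight (log OR)
    effect_noise_sd: float = 0.0          # estimation noise on published weights
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise DomainError(f"ld_rho {self.ld_rho} outside [0, 1)")
        lo, hi = self.eaf_range
        if not 0.0 < lo <= hi < 1.0:
            raise DomainError(f"eaf_range {self.eaf_range} outside (0, 1)")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise DomainError("disease_prevalence outside (0, 1)")

    @property
    def trait_ids(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_traits)]

    @property
    def n_variants(self) -> int:
        return self.n_traits * self.variants_per_trait + self.n_disease_variants

    def trait_slice(self, trait_index: int) -> slice:
        start = trait_index * self.variants_per_trait
        return slice(start, start + self.variants_per_trait)

    @property
    def disease_private_slice(self) -> slice:
        return slice(self.n_traits * self.variants_per_trait, self.n_variants)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("genotypes", "phenotypes", "catalog", "sampling")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _block_ids(spec: SimulationSpec) -> np.ndarray:
    """Per-variant LD-block label; blocks never straddle variant-set boundaries.

    A new block starts every ``ld_block_size`` variants and at the start of
    each trait's set and of the disease-private set, so LD links variants
    only within one set: cross-set dependence arises solely from the
    pleiotropy spec, never from the copula.
    """
    ids = np.empty(spec.n_variants, dtype=int)
    block = -1
    segments = [spec.trait_slice(i) for i in range(spec.n_traits)]
    segments.append(spec.disease_private_slice)
    for seg in segments:
        for offset, j in enumerate(range(seg.start, seg.stop)):
            if offset % spec.ld_block_size == 0:
                block += 1
            ids[j] = block
    return ids


def _variant_layout(spec: SimulationSpec) -> pd.DataFrame:
    """Physical layout: LD blocks contiguous, 5 kbp spacing, 3 Mbp gaps."""
    m = spec.n_variants
    block_ids = _block_ids(spec)
    chroms, positions = [], []
    pos_by_chrom: dict[str, int] = {}
    prev_block = -1
    within = 0
    for j in range(m):
        block = block_ids[j]
        within = 0 if block != prev_block else within + 1
        prev_block = block
        chrom = str(1 + block % 22)
        if within == 0:
            pos_by_chrom[chrom] = pos_by_chrom.get(chrom, 1_000_000) + 3_000_000
        chroms.append(chrom)
        positions.append(pos_by_chrom[chrom] + within * 5_000)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    ea = [alleles[j % 4][0] for j in range(m)]
    oa = [alleles[j % 4][1] for j in range(m)]
    return pd.DataFrame({
        "variant_id": [f"var{j + 1:05d}" for j in range(m)],
        "chrom": chroms, "pos": positions,
        "effect_allele": ea, "other_allele": oa,
    })


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Dosage matrix (population x variants), variant metadata, and EAFs.

    Haplotypes are drawn via the latent-Gaussian copula with within-block
    correlation ``ld_rho`` (zero across blocks); the dosage is the sum of two
    independent haplotypes, so dosages lie in {0, 1, 2} with the requested
    allele frequencies under Hardy-Weinberg equilibrium.
    """
    rng = rng if rng is not None else _stage_rngs(spec.seed)["genotypes"]
    n, m = spec.n_population, spec.n_variants
    eafs = rng.uniform(*spec.eaf_range, size=m)
    meta = _variant_layout(spec)
    meta["imputation_quality"] = rng.uniform(0.85, 1.0, size=m).round(3)

    dosages = np.empty((n, m), dtype=np.float32)
    if spec.ld_rho == 0.0:
        dosages[:] = rng.binomial(2, eafs, size=(n, m))
    else:
        thresh = stats.norm.ppf(eafs)
        rho = spec.ld_rho
        block_ids = _block_ids(spec)
        boundaries = np.flatnonzero(np.diff(block_ids)) + 1
        for start, stop in zip(np.r_[0, boundaries], np.r_[boundaries, m]):
            width = stop - start
            block = np.zeros((n, width), dtype=np.int8)
            for _hap in range(2):
                common = rng.standard_normal((n, 1))
                z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal((n, width))
                block += z < thresh[start:stop]
            dosages[:, start:stop] = block
    return dosages, meta, eafs


def disease_liability_effects(spec: SimulationSpec) -> np.ndarray:
    """Per-allele liability effect for every simulated variant.

    Within each trait's variant set, the first ``round(shared_fraction *
    variants_per_trait)`` variants are disease causal with the trait's
    pleiotropic sign and effect; the disease-private variants always carry
    ``disease_effect``.
    """
    beta = np.zeros(spec.n_variants)
    for i, tid in enumerate(spec.trait_ids):
        pleio = spec.pleiotropy.get(tid)
        if pleio is None or pleio.effect == 0.0 or pleio.shared_fraction == 0.0:
            continue
        k = int(round(pleio.shared_fraction * spec.variants_per_trait))
        sl = spec.trait_slice(i)
        beta[sl.start:sl.start + k] = pleio.sign * pleio.effect
    beta[spec.disease_private_slice] = spec.disease_effect
    return beta


def simulate_phenotypes(dosages: np.ndarray, spec: SimulationSpec,
                        liability_effects: np.ndarray | None = None,
                        eafs: np.ndarray | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample table (status, age, sex, DNA source, PCs, population flag).

    Liability is the centered weighted allele count plus covariate terms plus
    Gaussian noise scaled so the population liability variance is 1; an
    individual is a case when liability exceeds Phi^{-1}(1 - prevalence).
    Case subtypes are assigned by a fixed multinomial (GA 0.35 / NV 0.45 /
    mixed 0.20).
    """
    rng = rng if rng is not None else _stage_rngs(spec.seed)["phenotypes"]
    n = dosages.shape[0]
    beta = (liability_effects if liability_effects is not None
            else disease_liability_effects(spec))
    centers = (2.0 * eafs if eafs is not None
               else dosages.mean(axis=0, dtype=float))

    age = rng.normal(76.0, 7.0, size=n).clip(55, 98)
    sex = np.where(rng.random(n) < 0.578, "F", "M")
    dna_source = (rng.random(n) < 0.30).astype(int)
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)
    population_based = (rng.random(n) < 0.19).astype(int)

    ce = spec.covariate_effects
    causal = np.flatnonzero(beta)  # avoid a full-matrix copy for sparse effects
    systematic = (np.asarray(dosages[:, causal], dtype=float)
                  @ beta[causal] - float(centers[causal] @ beta[causal]))
    systematic += ce.age * (age - age.mean()) / age.std()
    systematic += ce.sex * (sex == "M").astype(float) * 2.0
    systematic += ce.dna_source * dna_source * 2.0
    systematic += ce.pc * (pc1 + pc2)
    systematic -= systematic.mean()   # keep the threshold calibrated to prevalence

    var_sys = float(np.var(systematic))
    if var_sys >= 1.0:
        raise DomainError(
            f"systematic liability variance {var_sys:.3f} >= 1; reduce effects")
    liability = systematic + rng.standard_normal(n) * np.sqrt(1.0 - var_sys)
    threshold = stats.norm.isf(spec.disease_prevalence)
    case = liability > threshold

    status = np.full(n, "CONTROL", dtype=object)
    subtypes = list(_SUBTYPE_PROBS)
    status[case] = rng.choice(subtypes, size=int(case.sum()),
                              p=list(_SUBTYPE_PROBS.values()))
    return pd.DataFrame({
        "status": status, "age": age.round(1), "sex": sex,
        "dna_source": dna_source, "pc1": pc1, "pc2": pc2,
        "population_based": population_based,
    }, index=pd.Index([f"S{i + 1:06d}" for i in range(n)], name="sample_id"))


def make_catalog(spec: SimulationSpec, meta: pd.DataFrame, eafs: np.ndarray,
                 rng: np.random.Generator | None = None) -> VariantCatalog:
    """Published-variant catalog over the simulated pool, with known truth.

    Published per-allele weights equal the generative trait effect size plus
    optional Gaussian estimation noise; published p-values all pass the
    genome-wide threshold, so the catalog round-trips the ingestion filters
    unchanged.
    """
    rng = rng if rng is not None else _stage_rngs(spec.seed)["catalog"]
    traits: dict[str, TraitDefinition] = {}
    for i, tid in enumerate(spec.trait_ids):
        sl = spec.trait_slice(i)
        variants = []
        for j in range(sl.start, sl.stop):
            w = spec.trait_effect_size
            if spec.effect_noise_sd > 0:
                w += rng.normal(0.0, spec.effect_noise_sd)
            variants.append(CatalogVariant(
                variant_id=meta["variant_id"].iat[j],
                chrom=str(meta["chrom"].iat[j]), pos=int(meta["pos"].iat[j]),
                effect_allele=meta["effect_allele"].iat[j],
                other_allele=meta["other_allele"].iat[j],
                effect_size=float(w), effect_type=EffectType.LOR,
                p_value=1e-9, eaf=float(eafs[j]), trait_id=tid,
                imputation_quality=float(meta["imputation_quality"].iat[j]),
                # every simulated variant carries its own generative effect,
                # so co-located variants are genuinely independent signals
                # and must bypass lead-variant pruning
                multi_signal=True,
            ))
        traits[tid] = TraitDefinition(
            trait_id=tid, name=f"Synthetic trait {tid}", category="synthetic",
            outcome_type=OutcomeType.BINARY, prevalence=0.1, variants=variants)
    return VariantCatalog(traits=traits)


def sample_case_control(population: CohortData, n_cases: int, n_controls: int,
                        rng: np.random.Generator | int | None = None) -> CohortData:
    """Uniform sampling without replacement within cases and controls."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cases = np.flatnonzero(population.case_mask)
    controls = np.flatnonzero(population.control_mask)
    if len(cases) < n_cases:
        raise DomainError(
            f"requested {n_cases} cases but population has only {len(cases)}")
    if len(controls) < n_controls:
        raise DomainError(
            f"requested {n_controls} controls but population has only {len(controls)}")
    chosen = np.concatenate([
        rng.choice(cases, size=n_cases, replace=False),
        rng.choice(controls, size=n_controls, replace=False),
    ])
    chosen.sort()
    mask = np.zeros(population.n_samples, dtype=bool)
    mask[chosen] = True
    return population.subset_samples(mask)


@dataclass
class SimulatedStudy:
    """A fully simulated study: population cohort, catalog, and ground truth."""

    spec: SimulationSpec
    population: CohortData
    cohort: CohortData            # the sampled case-control subset
    catalog: VariantCatalog
    eafs: np.ndarray
    liability_effects: np.ndarray

    @property
    def disease_variant_ids(self) -> list[str]:
        sl = self.spec.disease_private_slice
        return list(self.population.variant_meta["variant_id"].iloc[sl])


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Run every generator stage and sample the case-control cohort."""
    rngs = _stage_rngs(spec.seed)
    dosages, meta, eafs = simulate_genotypes(spec, rngs["genotypes"])
    samples = simulate_phenotypes(dosages, spec, eafs=eafs, rng=rngs["phenotypes"])
    population = CohortData(dosages=dosages, variant_meta=meta, samples=samples)
    catalog = make_catalog(spec, meta, eafs, rngs["catalog"])
    cohort = sample_case_control(population, spec.n_cases, spec.n_controls,
                                 rngs["sampling"])
    return SimulatedStudy(spec=spec, population=population, cohort=cohort,
                          catalog=catalog, eafs=eafs,
                          liability_effects=disease_liability_effects(spec))


def known_loci_from_truth(study: SimulatedStudy, margin: int = 100_000
                          ) -> list[LocusInterval]:
    """Known-locus intervals around the disease-private causal variants."""
    meta = study.population.variant_meta
    sl = study.spec.disease_private_slice
    out = []
    for j in range(sl.start, sl.stop):
        pos = int(meta["pos"].iat[j])
        out.append(LocusInterval(
            chrom=str(meta["chrom"].iat[j]), start=max(1, pos - margin),
            end=pos + margin, lead_variant=meta["variant_id"].iat[j], known=True))
    return out


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Emit the study in the TSV/BED formats the pipeline reads."""
    from .catalog import write_catalog, write_traits
    from .loci import merge_loci

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.tsv",
        "traits": outdir / "traits.tsv",
        "genotypes": outdir / "dosages.tsv",
        "samples": outdir / "samples.tsv",
        "known_variants": outdir / "known_variants.txt",
        "known_loci": outdir / "known_loci.bed",
    }
    write_catalog(study.catalog, paths["catalog"])
    write_traits(study.catalog, paths["traits"])
    write_dosage_tsv(study.cohort, paths["genotypes"])
    write_samples_tsv(study.cohort, paths["samples"])
    paths["known_variants"].write_text(
        "\n".join(study.disease_variant_ids) + "\n")
    write_loci_bed(merge_loci(known_loci_from_truth(study)), paths["known_loci"])
    return paths
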