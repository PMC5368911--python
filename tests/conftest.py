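"""Shared fixtures: tiny hand-built cohorts/catalogs and one simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pleioscore.catalog import (CatalogVariant, EffectType, OutcomeType,
                                TraitDefinition, VariantCatalog)
from pleioscore.cohort import CohortData
from pleioscore.synthetic_data import PleiotropySpec, SimulationSpec, simulate_study


def make_variant(**kw) -> CatalogVariant:
    """A CatalogVariant with sensible defaults, overridable per test."""
    defaults = dict(
        variant_id="rs1", chrom="1", pos=1_000_000, effect_allele="A",
        other_allele="G", effect_size=0.1, effect_type=EffectType.LOR,
        p_value=1e-9, eaf=0.3, trait_id="T1", imputation_quality=0.9,
    )
    defaults.update(kw)
    return CatalogVariant(**defaults)


def make_catalog(variants, outcome_type=OutcomeType.BINARY, prevalence=0.1,
                 gwas_n=None) -> VariantCatalog:
    """Group variants by trait_id into a VariantCatalog."""
    traits: dict[str, TraitDefinition] = {}
    for v in variants:
        traits.setdefault(v.trait_id, TraitDefinition(
            trait_id=v.trait_id, name=v.trait_id, category="test",
            outcome_type=outcome_type, prevalence=prevalence, gwas_n=gwas_n,
        )).variants.append(v)
    return VariantCatalog(traits=traits)


def make_cohort(dosages, variant_ids=None, positions=None, chroms=None,
                status=None, effect_allele="A", other_allele="G",
                rng_seed=0) -> CohortData:
    """A cohort around an (n_samples x n_variants) dosage array.

    Covariates are filled with seeded draws; status defaults to all controls.
    """
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    rng = np.random.default_rng(rng_seed)
    variant_ids = variant_ids or [f"rs{j + 1}" for j in range(m)]
    meta = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chroms or ["1"] * m,
        "pos": positions or [1_000_000 + 10_000 * j for j in range(m)],
        "effect_allele": [effect_allele] * m,
        "other_allele": [other_allele] * m,
        "imputation_quality": [1.0] * m,
    })
    samples = pd.DataFrame({
        "status": status if status is not None else ["CONTROL"] * n,
        "age": rng.normal(75, 7, n),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "dna_source": (rng.random(n) < 0.3).astype(int),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "population_based": (rng.random(n) < 0.2).astype(int),
    }, index=pd.Index([f"S{i + 1}" for i in range(n)], name="sample_id"))
    return CohortData(dosages=dosages, variant_meta=meta, samples=samples)


@pytest.fixture(scope="session")
def small_study():
    """One simulated study reused across read-only tests.

    Three traits (T01 pleiotropic with half its variants disease causal, T02
    and T03 null), block LD, five disease-private causal variants.
    """
    spec = SimulationSpec(
        n_population=40_000, n_cases=1_000, n_controls=1_000,
        n_traits=3, variants_per_trait=6, ld_block_size=3, ld_rho=0.4,
        disease_prevalence=0.05, n_disease_variants=5, disease_effect=0.12,
        pleiotropy={"T01": PleiotropySpec(shared_fraction=0.5, sign=1, effect=0.1)},
        seed=42,
    )
    return simulate_study(spec)
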