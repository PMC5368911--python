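"""Case-control cohort container: dosage matrix plus sample covariates.

The cohort is the unit of all association computation: an individuals x
variants matrix of imputed effect-allele dosages in [0, 2], variant metadata
(position, counted allele, imputation quality), and a sample table with
disease status (control vs. the late-stage subtypes GA / NV / mixed), age,
sex, DNA source (whole-genome amplified or not), principal components, and a
population-based-study flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

CASE_STATUSES = ("GA", "NV", "MIXED")
VALID_STATUSES = ("CONTROL",) + CASE_STATUSES

#: Covariates adjusted for in every default model: DNA source and the first
#: two genotype principal components guard against batch and population
#: structure; age and sex are standard demographic adjustments.
DEFAULT_COVARIATES = ("age", "sex", "dna_source", "pc1", "pc2")

_SAMPLE_COLUMNS = ["sample_id", "status", "age", "sex", "dna_source",
                   "pc1", "pc2", "population_based"]


@dataclass
class CohortData:
    """Dosages and covariates for a set of unrelated individuals.

    ``dosages`` has one row per sample (aligned with ``samples``) and one
    column per variant (aligned with ``variant_meta``).  Missing dosages are
    NaN until imputed downstream.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame   # variant_id, chrom, pos, effect_allele, other_allele, imputation_quality
    samples: pd.DataFrame        # indexed by sample_id; status/age/sex/dna_source/pc1/pc2/population_based

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.variant_meta) != m:
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variant_meta)} variants")
        bad = ~self.samples["status"].isin(VALID_STATUSES)
        if bad.any():
            raise ValueError(
                f"unknown status values: {sorted(self.samples['status'][bad].unique())}")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self._index = {v: i for i, v in enumerate(self.variant_meta["variant_id"])}

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def case_mask(self) -> np.ndarray:
        return self.samples["status"].isin(CASE_STATUSES).to_numpy()

    @property
    def control_mask(self) -> np.ndarray:
        return (self.samples["status"] == "CONTROL").to_numpy()

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant_index(self, variant_id: str) -> int:
        return self._index[variant_id]

    def dosage(self, variant_id: str, effect_allele: str | None = None) -> np.ndarray:
        """Dosage column for a variant, keyed to ``effect_allele``.

        When the requested effect allele is the cohort's *other* allele, the
        column is flipped (2 - dosage) so the count refers to the requested
        allele.
        """
        j = self._index[variant_id]
        d = self.dosages[:, j].astype(float)
        if effect_allele is None:
            return d
        counted = self.variant_meta["effect_allele"].iat[j]
        if effect_allele == counted:
            return d
        other = self.variant_meta["other_allele"].iat[j]
        if effect_allele == other:
            return 2.0 - d
        raise KeyError(
            f"allele {effect_allele} not present at {variant_id} ({counted}/{other})")

    def imputation_quality_map(self) -> dict[str, float]:
        return dict(zip(self.variant_meta["variant_id"],
                        self.variant_meta["imputation_quality"].astype(float)))

    def subset_samples(self, mask: np.ndarray) -> "CohortData":
        return CohortData(
            dosages=self.dosages[mask],
            variant_meta=self.variant_meta,
            samples=self.samples.loc[mask],
        )


def read_samples_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "status": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    df = df.set_index("sample_id")
    df["status"] = df["status"].str.upper()
    return df


def read_dosage_tsv(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a plain dosage matrix: variants as rows, samples as columns.

    The first five columns are ``variant_id chrom pos effect_allele
    other_allele imputation_quality``; remaining columns are per-sample
    dosages (``.``/empty for missing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele",
                 "other_allele", "imputation_quality"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"dosage table missing columns: {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=float).T  # samples x variants
    meta = df[meta_cols].reset_index(drop=True)
    return dosages, meta, sample_ids


def read_dosage_vcf(path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read imputed dosages from a VCF carrying a per-sample DS FORMAT field.

    The ALT allele is taken as the counted (effect) allele.  Imputation
    quality is read from the INFO field ``R2`` (or ``DR2``/``INFO``), 1.0
    when absent.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise FormatError(f"record {rec.ID or rec.POS} has no DS field")
        quality = None
        for key in ("R2", "DR2", "INFO"):
            if rec.INFO.get(key) is not None:
                quality = float(rec.INFO.get(key))
                break
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        meta.append({
            "variant_id": vid, "chrom": str(rec.CHROM), "pos": int(rec.POS),
            "effect_allele": rec.ALT[0], "other_allele": rec.REF,
            "imputation_quality": 1.0 if quality is None else quality,
        })
        rows.append(np.asarray(ds, dtype=float).reshape(-1))
    dosages = np.vstack(rows).T if rows else np.empty((len(sample_ids), 0))
    return dosages, pd.DataFrame(meta), sample_ids


def load_cohort(genotypes_path, samples_path) -> CohortData:
    """Assemble a cohort from a genotype file (TSV or VCF) and a sample table."""
    genotypes_path = Path(genotypes_path)
    if genotypes_path.suffix in (".vcf",) or str(genotypes_path).endswith(".vcf.gz"):
        dosages, meta, sample_ids = read_dosage_vcf(genotypes_path)
    else:
        dosages, meta, sample_ids = read_dosage_tsv(genotypes_path)
    samples = read_samples_tsv(samples_path)
    if list(samples.index) != sample_ids:
        try:
            samples = samples.loc[sample_ids]
        except KeyError as exc:
            raise FormatError(f"sample table does not cover genotyped samples: {exc}")
    return CohortData(dosages=dosages, variant_meta=meta, samples=samples)


def write_dosage_tsv(cohort: CohortData, path) -> None:
    meta = cohort.variant_meta.copy()
    dos = pd.DataFrame(cohort.dosages.T, columns=cohort.sample_ids)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False, na_rep=".")


def write_samples_tsv(cohort: CohortData, path) -> None:
    cohort.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False)


def write_dosage_vcf(cohort: CohortData, path) -> None:
    """Write dosages as a minimal VCFv4.2 with a DS FORMAT field."""
    meta = cohort.variant_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.sample_ids) + "\n")
        for j in range(len(meta)):
            row = meta.iloc[j]
            ds = "\t".join(
                "." if not np.isfinite(d) else f"{d:.3f}"
                for d in cohort.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t"
                f"R2={float(row['imputation_quality']):.3f}\tDS\t{ds}\n")
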