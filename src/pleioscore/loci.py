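"""LD, locus boundaries, known-locus exclusion, merging, and coding consequences.

A locus around a lead variant spans the most distant variants with r^2 > 0.5
to the lead within +/- 1 Mbp, extended by a 100 kbp margin on both sides.
Candidates falling inside a known disease locus are "known"; the remainder
are novel, and overlapping novel intervals merge into distinct loci.
Protein-consequence strings (HGVS-style ``p.<ref><pos><alt>`` with one-letter
amino-acid codes) classify as synonymous exactly when the reference and
alternate residues agree.

Coordinates are 1-based inclusive throughout; BED files are converted to and
from 0-based half-open form at the I/O boundary only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .catalog import CatalogVariant, _chrom_sort_key
from .cohort import CohortData
from .errors import DomainError, FormatError

LD_R2_THRESHOLD = 0.5
LOCUS_MARGIN_BP = 100_000
LOCUS_WINDOW_BP = 1_000_000

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CONSEQUENCE_RE = re.compile(rf"^p\.([{_AA}])(\d+)([{_AA}])$")


@dataclass
class LocusInterval:
    """A 1-based inclusive genomic interval with its member variants."""

    chrom: str
    start: int
    end: int
    lead_variant: str
    member_variants: list[str] = field(default_factory=list)
    known: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if not self.member_variants:
            self.member_variants = [self.lead_variant]

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ProteinConsequence:
    raw: str
    ref_aa: str
    position: int
    alt_aa: str

    @property
    def classification(self) -> str:
        return "SYNONYMOUS" if self.ref_aa == self.alt_aa else "NONSYNONYMOUS"


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be equal-length 1-D arrays")
    if len(a) < 10:
        raise DomainError("need at least 10 samples for LD")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DomainError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def define_locus(lead: CatalogVariant, cohort: CohortData,
                 window_bp: int = LOCUS_WINDOW_BP,
                 r2_threshold: float = LD_R2_THRESHOLD,
                 controls_only: bool = True) -> LocusInterval:
    """Locus interval around a lead variant from the cohort's LD structure.

    Among cohort variants within ``window_bp`` of the lead on the same
    chromosome, the minimal and maximal positions with r^2 > ``r2_threshold``
    to the lead (the lead always qualifies) define the core; the interval is
    that core extended by 100 kbp on each side, floored at position 1.  LD is
    computed on control samples by default, since case ascertainment distorts
    LD at disease loci.
    """
    if not cohort.has_variant(lead.variant_id):
        raise KeyError(f"lead {lead.variant_id} absent from cohort")
    sub = cohort.subset_samples(cohort.control_mask) if controls_only else cohort
    lead_d = sub.dosage(lead.variant_id)
    if np.ptp(lead_d[np.isfinite(lead_d)]) == 0:
        raise DomainError(f"lead {lead.variant_id} is monomorphic")
    meta = sub.variant_meta
    in_window = (
        (meta["chrom"].astype(str) == str(lead.chrom))
        & ((meta["pos"] - lead.pos).abs() <= window_bp)
    )
    members = [lead.variant_id]
    lo = hi = lead.pos
    for j in np.flatnonzero(in_window.to_numpy()):
        vid = meta["variant_id"].iat[j]
        if vid == lead.variant_id:
            continue
        d = sub.dosages[:, j]
        ok = np.isfinite(d) & np.isfinite(lead_d)
        if ok.sum() < 10 or np.ptp(d[ok]) == 0:
            continue
        if ld_r2(d[ok], lead_d[ok]) > r2_threshold:
            pos = int(meta["pos"].iat[j])
            members.append(vid)
            lo, hi = min(lo, pos), max(hi, pos)
    return LocusInterval(
        chrom=str(lead.chrom), start=max(1, lo - LOCUS_MARGIN_BP),
        end=hi + LOCUS_MARGIN_BP, lead_variant=lead.variant_id,
        member_variants=members)


def flag_known(candidates: list[CatalogVariant],
               known_loci: list[LocusInterval]
               ) -> tuple[list[CatalogVariant], list[CatalogVariant]]:
    """Partition candidates into (known, novel) by known-locus membership.

    A candidate is known exactly when its position falls inside any known
    interval (same chromosome, inclusive bounds).
    """
    known, novel = [], []
    for v in candidates:
        if any(iv.contains(str(v.chrom), v.pos) for iv in known_loci):
            known.append(v)
        else:
            novel.append(v)
    return known, novel


def merge_loci(intervals: list[LocusInterval]) -> list[LocusInterval]:
    """Merge overlapping (or touching) same-chromosome intervals.

    Members are unioned; the merged lead is the first interval's lead in
    positional order and names join with ';'.  Touching intervals (gap of
    zero bases) merge, since loci are physical regions.  Idempotent and
    permutation invariant.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (_chrom_sort_key(iv.chrom), iv.start, iv.end))
    merged = [replace(ordered[0], member_variants=list(ordered[0].member_variants))]
    for iv in ordered[1:]:
        cur = merged[-1]
        if iv.chrom == cur.chrom and iv.start <= cur.end + 1:
            cur.end = max(cur.end, iv.end)
            cur.member_variants += [m for m in iv.member_variants
                                    if m not in cur.member_variants]
            cur.known = cur.known or iv.known
            if iv.name and iv.name not in (cur.name or "").split(";"):
                cur.name = f"{cur.name};{iv.name}" if cur.name else iv.name
        else:
            merged.append(replace(iv, member_variants=list(iv.member_variants)))
    return merged


def classify_consequence(raw: str) -> ProteinConsequence:
    """Parse ``p.<AA><position><AA>`` and classify synonymous vs not."""
    m = _CONSEQUENCE_RE.match(raw.strip())
    if not m:
        raise FormatError(f"unparseable protein consequence: {raw!r}")
    return ProteinConsequence(raw=raw.strip(), ref_aa=m.group(1),
                              position=int(m.group(2)), alt_aa=m.group(3))


def read_known_loci_bed(path) -> list[LocusInterval]:
    """Known disease loci from a BED file (0-based half-open on disk)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed BED line: {line!r}")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            out.append(LocusInterval(
                chrom=chrom.removeprefix("chr"), start=start0 + 1, end=end0,
                lead_variant=name or f"{chrom}:{start0 + 1}", known=True, name=name))
    return out


def write_loci_bed(intervals: list[LocusInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or iv.lead_variant
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def loci_to_frame(intervals: list[LocusInterval]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": iv.chrom, "start": iv.start, "end": iv.end,
        "lead_variant": iv.lead_variant, "n_members": len(iv.member_variants),
        "members": ";".join(iv.member_variants),
        "known": iv.known, "name": iv.name,
    } for iv in intervals])


# ---------------------------------------------------------------------------
# Bundled published summary tables from a genome-wide pleiotropy screen of
# late-stage AMD: the 28 novel associated variants with their printed locus
# boundaries, and the 25 coding variants linked (r^2 > 0.5) to those loci.
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("pleioscore.data").joinpath(name)

def load_published_novel_variants() -> pd.DataFrame:
    """The 28 published novel AMD-associated pleiotropic variants.

    Columns include the variant, position (GRCh37), source phenotype, locus
    name, and the published locus boundaries in Mbp.
    """
    with resources.as_file(_data_path("amd_novel_pleiotropic_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def load_published_coding_variants() -> pd.DataFrame:
    """The 25 published coding variants in LD with the novel AMD loci."""
    with resources.as_file(_data_path("amd_novel_locus_coding_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


def published_novel_intervals() -> list[LocusInterval]:
    """Printed locus-boundary intervals of the 28 novel variants, in bp."""
    df = load_published_novel_variants()
    out = []
    for _, row in df.iterrows():
        out.append(LocusInterval(
            chrom=str(row["chrom"]),
            start=int(round(float(row["boundary_start_mbp"]) * 1_000_000)),
            end=int(round(float(row["boundary_end_mbp"]) * 1_000_000)),
            lead_variant=str(row["variant_id"]),
            name=str(row["locus_name"]),
        ))
    return out
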