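"""Cohort screening for rare coding variants in target genes.

Reads a multi-sample VCF, restricts sites to configured gene regions,
joins externally supplied consequence annotations, applies a rare-variant
minor-allele-frequency (MAF) filter, and summarises per-variant carrier
counts and frequencies.  Upstream alignment, variant calling and
consequence prediction are consumed as inputs, never recomputed here.

Conventions
-----------
* Chromosome names are normalised to the ``chr``-prefixed style.
* Multiallelic sites are decomposed into one biallelic record per
  alternate allele; ref/alt pairs are reduced to minimal representation.
* The MAF denominator is the number of *called* alleles (missing
  genotypes shrink it), i.e. standard VCF ``AN`` semantics.
* A "carrier" is an individual with at least one alternate allele,
  which matches autosomal-dominant actionability reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Consequence(str, Enum):
    """Functional consequence classes recognised by the screen."""

    missense = "missense"
    stop_gained = "stop_gained"
    frameshift = "frameshift"
    inframe_deletion = "inframe_deletion"
    splice_donor = "splice_donor"
    splice_acceptor = "splice_acceptor"
    synonymous = "synonymous"
    other = "other"


#: Consequence classes kept by default: everything protein-altering or
#: splice-disrupting, i.e. all classes except synonymous/other.
DEFAULT_KEPT_CONSEQUENCES = frozenset(
    c for c in Consequence if c not in (Consequence.synonymous, Consequence.other)
)


def normalize_chrom(chrom: str) -> str:
    """Return the ``chr``-prefixed chromosome name."""
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce a ref/alt pair to minimal representation.

    Shared suffix bases are trimmed first, then shared prefix bases
    (advancing ``pos``), always leaving at least one base on each side.
    Without a reference sequence full left-alignment is not possible;
    minimal representation is sufficient to make variant-key joins
    between the cohort and classification tables deterministic.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalised identity of a biallelic variant (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a key with chromosome and allele normalisation applied."""
        pos, ref, alt = normalize_alleles(int(pos), ref, alt)
        return cls(normalize_chrom(chrom), pos, ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def compute_maf(allele_count: int, allele_number: int) -> float:
    """Minor allele frequency from alt-allele count and called-allele count.

    The minor allele may be either allele:
    ``maf = min(ac, an - ac) / an``.
    """
    if allele_number <= 0:
        raise ValueError("MAF is undefined when no alleles were called")
    if not 0 <= allele_count <= allele_number:
        raise ValueError(
            f"allele_count {allele_count} outside [0, {allele_number}]"
        )
    return min(allele_count, allele_number - allele_count) / allele_number


@dataclass
class VariantRecord:
    """Per-variant cohort summary."""

    key: VariantKey
    gene: str
    consequence: Consequence
    allele_count: int
    allele_number: int
    maf: float
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("allele_count must lie in [0, allele_number]")
        n_car = len(self.carriers)
        if n_car > self.allele_count:
            raise ValueError("more carriers than alt alleles")
        if 2 * n_car < self.allele_count:
            raise ValueError("fewer carriers than hom-alt genotypes allow")


@dataclass
class CohortVariantTable:
    """Ordered, duplicate-free collection of variant records for one cohort."""

    records: list[VariantRecord]
    cohort_size: int
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.key)
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in cohort table")
        for r in self.records:
            if r.allele_number > 2 * self.cohort_size:
                raise ValueError(
                    f"{r.key}: allele_number {r.allele_number} exceeds "
                    f"2 x cohort_size ({2 * self.cohort_size})"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CarrierReport:
    """Carrier count and frequency for one variant or a merged variant set."""

    variant: VariantKey | None
    n_carriers: int
    cohort_size: int
    frequency: float
    one_in_n: int | None

    @property
    def percent(self) -> float:
        """Carrier frequency as a percentage, two significant figures."""
        return float(f"{self.frequency * 100:.2g}")


def _one_in_n(cohort_size: int, n_carriers: int) -> int | None:
    """Reciprocal carrier frequency rounded to the nearest 10."""
    if n_carriers == 0:
        return None
    return int(round(cohort_size / n_carriers / 10.0) * 10)


def carrier_report(
    records: VariantRecord | Iterable[VariantRecord],
    cohort_size: int,
    variant: VariantKey | None = None,
) -> CarrierReport:
    """Summarise carriers for one record or for a merged set of records.

    For a merged set the carrier sets are unioned, so an individual
    carrying two of the variants is counted once.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if isinstance(records, VariantRecord):
        carriers = set(records.carriers)
        variant = records.key
    else:
        carriers = set()
        for rec in records:
            carriers |= rec.carriers
    n = len(carriers)
    return CarrierReport(
        variant=variant,
        n_carriers=n,
        cohort_size=cohort_size,
        frequency=n / cohort_size,
        one_in_n=_one_in_n(cohort_size, n),
    )


def filter_rare_coding(
    table: CohortVariantTable,
    maf_threshold: float = 0.001,
    kept_consequences: frozenset[Consequence] | set[Consequence] = DEFAULT_KEPT_CONSEQUENCES,
) -> CohortVariantTable:
    """Keep records with ``maf < maf_threshold`` (strict) and a kept consequence."""
    if not 0 < maf_threshold <= 0.5:
        raise ValueError("maf_threshold must lie in (0, 0.5]")
    kept = frozenset(kept_consequences)
    records = [
        r for r in table.records
        if r.maf < maf_threshold and r.consequence in kept
    ]
    return CohortVariantTable(
        records=records,
        cohort_size=table.cohort_size,
        cohort_label=table.cohort_label,
    )


# ---------------------------------------------------------------------------
# input readers


def read_gene_regions_bed(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read gene regions from BED (0-based half-open) into 1-based inclusive."""
    regions: dict[str, tuple[str, int, int]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{i}: BED line needs chrom,start,end,name")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        regions[name] = (normalize_chrom(chrom), start + 1, end)
    return regions


def read_annotations_tsv(path: str | Path) -> dict[VariantKey, tuple[str, Consequence]]:
    """Read a variant annotation table (chrom, pos, ref, alt, gene, consequence)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    annotations = {}
    for row in df.itertuples(index=False):
        key = VariantKey.make(row.chrom, row.pos, row.ref, row.alt)
        annotations[key] = (row.gene, Consequence(row.consequence))
    return annotations


def load_cohort_variants(
    vcf_path: str | Path,
    gene_regions: Mapping[str, tuple[str, int, int]],
    annotations: Mapping[VariantKey, tuple[str, Consequence]],
    cohort_label: str = "",
) -> CohortVariantTable:
    """Build a :class:`CohortVariantTable` from a multi-sample VCF.

    One record is emitted per biallelic alternate allele that falls inside
    a gene region; multiallelic sites are decomposed.  ``allele_number``
    counts non-missing called alleles only.  In-region variants missing
    from ``annotations`` are kept with ``consequence=other`` and a logged
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []

    for site in vcf:
        chrom = normalize_chrom(site.CHROM)
        region_genes = [
            gene for gene, (rchrom, start, end) in gene_regions.items()
            if rchrom == chrom and start <= site.POS <= end
        ]
        if not region_genes:
            continue
        genotypes = site.genotypes  # [[a1, a2, phased], ...]
        called = [a for gt in genotypes for a in gt[:2] if a >= 0]
        allele_number = len(called)
        for alt_index, alt in enumerate(site.ALT, start=1):
            if not set(alt.upper()) <= _BASES:
                logger.warning("skipping non-sequence alt %s at %s:%d",
                               alt, chrom, site.POS)
                continue
            try:
                key = VariantKey.make(chrom, site.POS, site.REF, alt)
            except ValueError as exc:
                raise ValueError(
                    f"malformed variant at {chrom}:{site.POS}: {exc}"
                ) from exc
            allele_count = sum(1 for a in called if a == alt_index)
            carriers = frozenset(
                samples[i] for i, gt in enumerate(genotypes)
                if alt_index in gt[:2]
            )
            annot = annotations.get(key)
            if annot is None:
                logger.warning("no annotation for in-region variant %s; "
                               "keeping with consequence=other", key)
                gene, consequence = region_genes[0], Consequence.other
            else:
                gene, consequence = annot
            records.append(VariantRecord(
                key=key,
                gene=gene,
                consequence=Consequence(consequence),
                allele_count=allele_count,
                allele_number=allele_number,
                maf=compute_maf(allele_count, allele_number) if allele_number else 0.0,
                carriers=carriers,
            ))
    return CohortVariantTable(
        records=records,
        cohort_size=len(samples),
        cohort_label=cohort_label,
    )


# ---------------------------------------------------------------------------
# report writers / readers


_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "allele_count", "allele_number", "maf", "n_carriers", "carriers",
]


def write_variant_table_tsv(table: CohortVariantTable, path: str | Path) -> None:
    """Write the per-variant screen report as TSV (MAF kept at full precision)."""
    rows = [
        {
            "chrom": r.key.chrom, "pos": r.key.pos,
            "ref": r.key.ref, "alt": r.key.alt,
            "gene": r.gene, "consequence": r.consequence.value,
            "allele_count": r.allele_count, "allele_number": r.allele_number,
            "maf": repr(r.maf), "n_carriers": len(r.carriers),
            "carriers": ",".join(sorted(r.carriers)),
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table_tsv(
    path: str | Path, cohort_size: int, cohort_label: str = ""
) -> CohortVariantTable:
    """Re-read a TSV screen report written by :func:`write_variant_table_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "carriers": str},
                     keep_default_na=False, float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        carriers = frozenset(c for c in str(row.carriers).split(",") if c)
        records.append(VariantRecord(
            key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
            gene=row.gene,
            consequence=Consequence(row.consequence),
            allele_count=int(row.allele_count),
            allele_number=int(row.allele_number),
            maf=float(row.maf),
            carriers=carriers,
        ))
    return CohortVariantTable(records, cohort_size, cohort_label)


def write_cohort_summary_json(
    table: CohortVariantTable, report: CarrierReport, path: str | Path
) -> None:
    """Write a JSON summary of a screened cohort and its merged carrier report."""
    payload = {
        "cohort_label": table.cohort_label,
        "cohort_size": table.cohort_size,
        "n_variants": len(table),
        "n_carriers": report.n_carriers,
        "carrier_frequency": report.frequency,
        "carrier_frequency_percent": report.percent,
        "one_in_n": report.one_in_n,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
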