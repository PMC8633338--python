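"""Aggregation of ClinVar-style classifications into actionability verdicts.

A classification table lists, per variant, the number of submissions under
each clinical-significance label.  Variants with pathogenic-side support are
"actionable" unless benign-side submissions create a conflict; the conflict
rule is explicit and comes in two flavours:

``majority`` (default)
    actionable iff at least one pathogenic-side submission exists and the
    pathogenic-side tally strictly outnumbers the benign-side tally.
    Uncertain-significance submissions are neutral.  This keeps a variant
    with tallies {Pathogenic: 10, Likely benign: 1} actionable.

``strict``
    actionable only with pathogenic-side support and *no* benign-side or
    uncertain submissions at all; any dissent excludes the variant as
    conflicting.

"Drug response pathogenic" submissions count pathogenic-side: in this
screening context they flag diagnostic anaesthesia-risk variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .population_screen import (
    CarrierReport,
    CohortVariantTable,
    VariantKey,
    carrier_report,
)

logger = logging.getLogger(__name__)


class Label(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    drug_response_pathogenic = "drug_response_pathogenic"
    uncertain = "uncertain"
    likely_benign = "likely_benign"
    benign = "benign"


_PATHOGENIC_SIDE = (Label.pathogenic, Label.likely_pathogenic,
                    Label.drug_response_pathogenic)
_BENIGN_SIDE = (Label.benign, Label.likely_benign)

_LABEL_ALIASES = {
    "pathogenic": Label.pathogenic,
    "likely pathogenic": Label.likely_pathogenic,
    "drug response pathogenic": Label.drug_response_pathogenic,
    "uncertain": Label.uncertain,
    "uncertain significance": Label.uncertain,
    "vus": Label.uncertain,
    "likely benign": Label.likely_benign,
    "benign": Label.benign,
}


def parse_label(text: str) -> Label:
    """Map a label string (case-insensitive, space or underscore separated)."""
    norm = str(text).strip().lower().replace("_", " ")
    try:
        return _LABEL_ALIASES[norm]
    except KeyError:
        raise ValueError(f"unknown classification label {text!r}") from None


class Verdict(str, Enum):
    actionable = "actionable"
    conflicting_excluded = "conflicting_excluded"
    not_actionable = "not_actionable"


class Rule(str, Enum):
    majority = "majority"
    strict = "strict"


@dataclass
class ClassificationEntry:
    """Per-variant submission tallies plus descriptive annotations."""

    key: VariantKey
    tallies: dict[Label, int]
    phenotype: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        self.tallies = {Label(k): int(v) for k, v in self.tallies.items()}
        if any(v < 0 for v in self.tallies.values()):
            raise ValueError(f"{self.key}: negative submission tally")
        if not any(v > 0 for v in self.tallies.values()):
            raise ValueError(f"{self.key}: entry has no submissions")

    def side_counts(self) -> tuple[int, int, int]:
        """(pathogenic-side, benign-side, uncertain) submission totals."""
        p = sum(self.tallies.get(l, 0) for l in _PATHOGENIC_SIDE)
        b = sum(self.tallies.get(l, 0) for l in _BENIGN_SIDE)
        u = self.tallies.get(Label.uncertain, 0)
        return p, b, u


@dataclass
class ActionabilityCall:
    key: VariantKey
    aggregate: Verdict
    rationale: str


def parse_classifications(path_or_buffer) -> list[ClassificationEntry]:
    """Parse a classification TSV into one entry per variant.

    Expected columns: chrom, pos, ref, alt, gene, hgvs_c, hgvs_p, label,
    n_submissions, phenotype — one row per (variant, label).  Duplicate
    (variant, label) rows and unknown labels are errors.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"chrom": str},
                     keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt", "label", "n_submissions"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"classification table lacks columns: {sorted(missing)}")

    entries: dict[VariantKey, ClassificationEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = VariantKey.make(row.chrom, row.pos, row.ref, row.alt)
        try:
            label = parse_label(row.label)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        entry = entries.get(key)
        if entry is None:
            entries[key] = ClassificationEntry(
                key=key,
                tallies={label: int(row.n_submissions)},
                phenotype=str(getattr(row, "phenotype", "")),
                hgvs_c=str(getattr(row, "hgvs_c", "")),
                hgvs_p=str(getattr(row, "hgvs_p", "")),
            )
        else:
            if label in entry.tallies:
                raise ValueError(
                    f"row {i}: duplicate label {label.value!r} for {key}"
                )
            entry.tallies[label] = int(row.n_submissions)
    return list(entries.values())


def aggregate_classification(
    entry: ClassificationEntry, rule: Rule | str = Rule.majority
) -> ActionabilityCall:
    """Collapse a variant's submission tallies into one actionability verdict."""
    rule = Rule(rule)
    p, b, u = entry.side_counts()
    tally_text = ", ".join(
        f"{l.value}={n}" for l, n in sorted(entry.tallies.items(),
                                            key=lambda kv: kv[0].value) if n
    )
    if rule is Rule.majority:
        if p >= 1 and p > b:
            verdict = Verdict.actionable
            branch = f"pathogenic-side {p} > benign-side {b}"
        elif p >= 1:
            verdict = Verdict.conflicting_excluded
            branch = f"pathogenic-side {p} <= benign-side {b}"
        else:
            verdict = Verdict.not_actionable
            branch = "no pathogenic-side submissions"
    else:
        if p >= 1 and b == 0 and u == 0:
            verdict = Verdict.actionable
            branch = f"pathogenic-side {p} with no dissent"
        elif p >= 1:
            verdict = Verdict.conflicting_excluded
            branch = f"pathogenic-side {p} with dissent (benign {b}, uncertain {u})"
        else:
            verdict = Verdict.not_actionable
            branch = "no pathogenic-side submissions"
    return ActionabilityCall(
        key=entry.key,
        aggregate=verdict,
        rationale=f"[{tally_text}] {rule.value} rule: {branch}",
    )


def actionable_carrier_report(
    screened: CohortVariantTable,
    calls: Iterable[ActionabilityCall],
) -> tuple[list[CarrierReport], CarrierReport]:
    """Join actionable calls onto a screened table and count carriers.

    Returns one carrier report per actionable variant present in the
    screened table plus a merged report over the union of their carriers.
    Calls for variants absent from the screened cohort are ignored with a
    logged note (classification tables routinely cover variants a given
    cohort does not harbour).
    """
    by_key = {r.key: r for r in screened.records}
    per_variant: list[CarrierReport] = []
    matched = []
    for call in calls:
        if call.aggregate is not Verdict.actionable:
            continue
        record = by_key.get(call.key)
        if record is None:
            logger.info("actionable variant %s not present in screened cohort",
                        call.key)
            continue
        matched.append(record)
        per_variant.append(carrier_report(record, screened.cohort_size))
    merged = carrier_report(matched, screened.cohort_size)
    return per_variant, merged


def extend_with_imputed(
    report: CarrierReport,
    imputed_dosages: Mapping[str, float],
    dosage_threshold: float = 0.9,
    extended_cohort_size: int | None = None,
    known_carriers: frozenset[str] | set[str] | None = None,
) -> CarrierReport:
    """Add imputation-derived carriers to a sequencing-based carrier report.

    ``imputed_dosages`` maps individual id to expected alternate-allele
    dosage (an individual carrying any variant of a merged set reports the
    maximum dosage over the set).  Individuals with dosage >= threshold are
    added to the carrier set; individuals listed in ``known_carriers`` are
    assumed already counted.  The frequency is recomputed against
    ``extended_cohort_size`` (defaults to the report's cohort size).
    """
    if not 0 < dosage_threshold < 2:
        raise ValueError("dosage_threshold must lie in (0, 2)")
    for ind, dose in imputed_dosages.items():
        if not 0 <= dose <= 2:
            raise ValueError(f"dosage {dose} for {ind} outside [0, 2]")
    known = set(known_carriers or ())
    added = {
        ind for ind, dose in imputed_dosages.items()
        if dose >= dosage_threshold and ind not in known
    }
    n = report.n_carriers + len(added)
    cohort = extended_cohort_size or report.cohort_size
    return CarrierReport(
        variant=report.variant,
        n_carriers=n,
        cohort_size=cohort,
        frequency=n / cohort,
        one_in_n=(int(round(cohort / n / 10.0) * 10) if n else None),
    )


def write_actionability_tsv(
    screened: CohortVariantTable,
    entries: Iterable[ClassificationEntry],
    calls: Iterable[ActionabilityCall],
    path: str | Path,
) -> None:
    """Write a per-variant table of tallies, verdicts and carrier counts."""
    by_key = {r.key: r for r in screened.records}
    entry_by_key = {e.key: e for e in entries}
    rows = []
    for call in calls:
        entry = entry_by_key.get(call.key)
        record = by_key.get(call.key)
        tallies = entry.tallies if entry else {}
        rows.append({
            "chrom": call.key.chrom, "pos": call.key.pos,
            "ref": call.key.ref, "alt": call.key.alt,
            "hgvs_c": entry.hgvs_c if entry else "",
            "hgvs_p": entry.hgvs_p if entry else "",
            "interpretation": "; ".join(
                f"{l.value} ({n})" for l, n in tallies.items() if n),
            "verdict": call.aggregate.value,
            "n_carriers": len(record.carriers) if record else 0,
            "maf": record.maf if record else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
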