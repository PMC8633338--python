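"""Allelic-balance testing for somatic/germline mosaicism.

A constitutional heterozygote is expected to show roughly equal read
support for the two alleles at a variant site; a somatic mosaic carries
the variant in only a fraction *m* of cells and therefore shows an
expected alternate-read fraction of m/2.  Each individual's allelic
ratio is tested against the 50/50 heterozygous expectation with an exact
binomial test (sequencing depths at a single site are small, so a normal
approximation would be inappropriate), and a carrier state is called
from the genotype, the read depths and the test.

The two-sided p-value uses the minimum-likelihood method: the sum of
``Pr(x | n, p0)`` over every outcome ``x`` no more probable than the one
observed.  For ``p0 = 0.5`` this equals twice the smaller tail
probability, capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from scipy.stats import binomtest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AllelicDepth:
    """Read counts supporting the reference and alternate allele."""

    individual: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads


def allelic_ratio(depth: AllelicDepth) -> float:
    """Alternate-read fraction alt/(ref+alt).

    Kept at full precision internally; round only when reporting.
    """
    if depth.total == 0:
        raise ValueError(
            f"{depth.individual}: no reads, allelic ratio is indeterminate"
        )
    return depth.alt_reads / depth.total


@dataclass(frozen=True)
class BalanceTestResult:
    ratio: float
    n: int
    p_two_sided: float


def binomial_balance_test(
    alt_reads: int, total_reads: int, null_fraction: float = 0.5
) -> BalanceTestResult:
    """Exact two-sided binomial test of the alt-read count against ``null_fraction``."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 < null_fraction < 1:
        raise ValueError("null_fraction must lie in (0, 1)")
    p = binomtest(alt_reads, total_reads, null_fraction,
                  alternative="two-sided").pvalue
    return BalanceTestResult(
        ratio=alt_reads / total_reads,
        n=total_reads,
        p_two_sided=float(p),
    )


class Genotype(str, Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


class State(str, Enum):
    non_carrier = "non_carrier"
    heterozygous = "heterozygous"
    mosaic_candidate = "mosaic_candidate"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class BalanceConfig:
    """Thresholds for carrier-state calling.

    alpha
        significance level for the allelic-balance deviation (0.01: at
        typical 30x depths only a clearly skewed ratio rejects).
    min_alt
        minimum alternate reads required to consider the variant observed
        (guards against isolated sequencing-error reads).
    min_depth
        below this total depth no confident state is called.
    mosaic_ratio_max
        a significantly *low* ratio below this bound is labelled mosaic;
        significantly high ratios are left indeterminate rather than
        over-interpreted.
    """

    alpha: float = 0.01
    min_alt: int = 3
    min_depth: int = 10
    mosaic_ratio_max: float = 0.35


@dataclass
class CarrierState:
    individual: str
    state: State
    genotype: Genotype
    test: BalanceTestResult | None = None


def classify_carrier_state(
    genotype: Genotype | str,
    depth: AllelicDepth,
    config: BalanceConfig = BalanceConfig(),
) -> CarrierState:
    """Call an individual's carrier state at the focal variant.

    Decision order: conflicting inputs (called het with zero alternate
    reads) are indeterminate; a homozygous-reference genotype with fewer
    than ``min_alt`` alternate reads is a non-carrier; depths below
    ``min_depth`` are indeterminate; otherwise the variant is considered
    observed when ``alt_reads >= min_alt`` and the exact balance test
    separates mosaic candidates (significantly low ratio) from ordinary
    heterozygotes (no significant deviation).
    """
    genotype = Genotype(genotype)
    if genotype in (Genotype.het, Genotype.hom_alt) and depth.alt_reads == 0:
        logger.warning("%s: genotype %s but zero alt reads; indeterminate",
                       depth.individual, genotype.value)
        return CarrierState(depth.individual, State.indeterminate, genotype)
    if depth.alt_reads < config.min_alt and genotype is Genotype.hom_ref:
        return CarrierState(depth.individual, State.non_carrier, genotype)
    if depth.total < config.min_depth:
        return CarrierState(depth.individual, State.indeterminate, genotype)
    if depth.alt_reads < config.min_alt:
        # variant not confidently observed, but genotype is not hom-ref
        return CarrierState(depth.individual, State.indeterminate, genotype)
    test = binomial_balance_test(depth.alt_reads, depth.total)
    if test.p_two_sided < config.alpha and test.ratio < config.mosaic_ratio_max:
        state = State.mosaic_candidate
    elif test.p_two_sided >= config.alpha:
        state = State.heterozygous
    else:
        # significant deviation towards the alternate allele: not a
        # low-fraction mosaic, but not a clean heterozygote either
        state = State.indeterminate
    return CarrierState(depth.individual, state, genotype, test)


def read_allelic_depths_tsv(path: str | Path) -> list[AllelicDepth]:
    """Read per-individual read counts (columns: individual, ref_reads, alt_reads)."""
    df = pd.read_csv(path, sep="\t")
    return [
        AllelicDepth(str(row.individual), int(row.ref_reads), int(row.alt_reads))
        for row in df.itertuples(index=False)
    ]


def write_states_tsv(states: list[CarrierState], path: str | Path) -> None:
    """Write per-individual carrier-state calls; ratios rounded to two decimals."""
    rows = []
    for s in states:
        rows.append({
            "individual": s.individual,
            "genotype": s.genotype.value,
            "ratio": round(s.test.ratio, 2) if s.test else "",
            "n": s.test.n if s.test else "",
            "p_two_sided": s.test.p_two_sided if s.test else "",
            "state": s.state.value,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
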