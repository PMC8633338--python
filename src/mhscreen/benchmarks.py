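"""Seeded simulation benchmarks for the pipeline's statistical behaviour.

These drive the synthetic-data generator through the analysis modules and
score the results against the ground-truth ledger: carrier-state
calibration at heterozygous and mosaic sites, recovery of the planted
mutation origin through haplotype tracing, recovery of transmitted
segment boundaries, and an exact end-to-end check of the population
screen against the planted cohort.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic_data as synth
from .actionability import (
    Rule,
    Verdict,
    actionable_carrier_report,
    aggregate_classification,
    parse_classifications,
)
from .haplotype_tracing import (
    HapOrigin,
    Individual,
    OriginMode,
    Pedigree,
    Sex,
    detect_discordant_sharers,
    infer_origin,
    shared_segment,
    trace_parental_origin,
)
from .mosaicism import (
    BalanceConfig,
    Genotype,
    State,
    classify_carrier_state,
)
from .population_screen import (
    Consequence,
    VariantKey,
    filter_rare_coding,
    load_cohort_variants,
    read_annotations_tsv,
    read_gene_regions_bed,
)
from .synthetic_data import SimConfig, Transmission


# ---------------------------------------------------------------------------
# carrier-state calibration


@dataclass
class CalibrationResult:
    n_replicates: int
    false_mosaic_rate: float      # heterozygotes miscalled mosaic_candidate
    mosaic_detection_rate: float  # true mosaics called mosaic_candidate


def mosaic_calibration(
    seed: int,
    n_replicates: int = 10_000,
    depth_mean: float = 30.0,
    cell_fraction: float = 0.4,
    config: BalanceConfig = BalanceConfig(),
) -> CalibrationResult:
    """Carrier-state calling rates on simulated heterozygous and mosaic reads.

    Depths are Poisson(``depth_mean``); heterozygous alternate reads are
    Binomial(depth, 0.5) and mosaic ones Binomial(depth, m/2).  Balance
    tests are cached per (alt, depth) pair, so large replicate counts stay
    cheap.
    """
    sim = SimConfig(seed=seed, depth_mean=depth_mean,
                    mosaic_cell_fraction=cell_fraction)
    cache: dict[tuple[int, int], State] = {}

    def call(state: str, rng: np.random.Generator) -> State:
        depth = synth.sim_reads(state, sim, rng)
        key = (depth.alt_reads, depth.total)
        if key not in cache:
            genotype = Genotype.het if depth.alt_reads >= config.min_alt \
                else Genotype.hom_ref
            cache[key] = classify_carrier_state(genotype, depth, config).state
        return cache[key]

    rng_het = sim.rng("calibration-het")
    rng_mosaic = sim.rng("calibration-mosaic")
    false_mosaic = sum(
        call("heterozygous", rng_het) is State.mosaic_candidate
        for _ in range(n_replicates))
    detected = sum(
        call("mosaic", rng_mosaic) is State.mosaic_candidate
        for _ in range(n_replicates))
    return CalibrationResult(
        n_replicates=n_replicates,
        false_mosaic_rate=false_mosaic / n_replicates,
        mosaic_detection_rate=detected / n_replicates,
    )


# ---------------------------------------------------------------------------
# origin recovery


def origin_benchmark_pedigree() -> Pedigree:
    """Three-generation pedigree for origin recovery.

    The planted origin II-2 has typed parents (I-1, I-2) and a typed
    sibling II-1, mirroring the discordance sources the tracing relies
    on; three children and two grandchildren provide carrier descendants.
    """
    spec = [
        ("I-1", Sex.male, None, None),
        ("I-2", Sex.female, None, None),
        ("II-1", Sex.female, "I-1", "I-2"),     # sibling of the origin
        ("II-2", Sex.female, "I-1", "I-2"),     # planted mosaic origin
        ("II-3", Sex.male, None, None),         # spouse of II-2
        ("III-1", Sex.male, "II-3", "II-2"),
        ("III-2", Sex.female, "II-3", "II-2"),
        ("III-3", Sex.male, "II-3", "II-2"),
        ("III-4", Sex.female, None, None),      # spouse of III-1
        ("IV-1", Sex.male, "III-1", "III-4"),
        ("IV-2", Sex.female, "III-1", "III-4"),
    ]
    return Pedigree({
        ind_id: Individual(ind_id, sex, father, mother, ind_id)
        for ind_id, sex, father, mother in spec
    })


@dataclass
class OriginRecoveryResult:
    n_replicates: int
    n_mosaic_mode_correct: int       # planted individual + mosaic mode
    n_individual_correct: int        # planted individual, any de novo mode
    n_origin_called_mosaic: int      # origin's read-based state was mosaic
    modes: dict[str, int] = field(default_factory=dict)

    @property
    def mosaic_mode_rate(self) -> float:
        return self.n_mosaic_mode_correct / self.n_replicates

    @property
    def individual_rate(self) -> float:
        return self.n_individual_correct / self.n_replicates


def origin_recovery(
    seed: int,
    n_replicates: int = 100,
    depth_mean: float = 30.0,
    cell_fraction: float = 0.4,
    balance_config: BalanceConfig = BalanceConfig(),
) -> OriginRecoveryResult:
    """Recover a planted mosaic origin over seeded gene-dropping replicates.

    Each replicate gene-drops haplotypes through the benchmark pedigree,
    plants a mosaic mutation in II-2 (typed sibling II-1 and typed
    parents), simulates reads at ``depth_mean`` for every member,
    classifies carrier states from those reads, finds the shared segment
    among read-confirmed carriers, detects discordant sharers and runs the
    origin inference.  Scores both strict recovery (planted individual
    with the germline-mosaic mode) and individual-only recovery (either
    de novo mode naming the planted origin).
    """
    pedigree = origin_benchmark_pedigree()
    origin = "II-2"
    result = OriginRecoveryResult(n_replicates, 0, 0, 0, {})

    for rep in range(n_replicates):
        config = SimConfig(
            seed=(seed * 100_003 + rep) & 0x7FFFFFFF,
            depth_mean=depth_mean,
            mosaic_cell_fraction=cell_fraction,
        )
        phased, ledger = synth.drop_haplotypes(pedigree, config)
        synth.plant_mutation(phased, pedigree, origin, "mosaic", config, ledger)
        depths, genotypes = synth.sim_family_reads(ledger, pedigree, config)

        states = {
            ind: classify_carrier_state(genotypes[ind], depths[ind],
                                        balance_config)
            for ind in pedigree.members
        }
        result.n_origin_called_mosaic += (
            states[origin].state is State.mosaic_candidate)
        focal = phased.marker_map.focal_index
        carriers = {
            ind for ind, s in states.items()
            if s.state in (State.heterozygous, State.mosaic_candidate)
            # phased genotypes must confirm a variant-bearing haplotype
            and bool(np.any(phased.data[ind].alleles[:, focal] == 1))
        }
        mode = "no_carriers"
        inferred = None
        if carriers:
            try:
                segment = shared_segment(phased, carriers)
                path = trace_parental_origin(segment, pedigree, phased)
                relatives = set(pedigree.members) - carriers
                discordant = detect_discordant_sharers(
                    segment, phased, states, relatives)
                inference = infer_origin(pedigree, states, segment,
                                         discordant, path)
                mode = inference.mode.value
                inferred = inference.originating_individual
            except ValueError:
                mode = "tracing_error"
        result.modes[mode] = result.modes.get(mode, 0) + 1
        if inferred == origin:
            if mode == OriginMode.de_novo_germline_mosaic.value:
                result.n_mosaic_mode_correct += 1
                result.n_individual_correct += 1
            elif mode == OriginMode.de_novo_full_heterozygote.value:
                result.n_individual_correct += 1
    return result


# ---------------------------------------------------------------------------
# segment recovery


@dataclass
class SegmentRecoveryResult:
    n_replicates: int
    max_start_offset_markers: int
    max_end_offset_markers: int


def _marker_offset(positions: np.ndarray, recovered_pos: int,
                   true_breakpoint: float, side: str) -> int:
    """Markers between the recovered bound and the true breakpoint.

    On the left side the true segment starts at the breakpoint, so the
    ideal recovered start is the first marker at or after it; on the right
    side the ideal end is the last marker before it.  Returns the index
    distance from that ideal marker (0 = exact recovery).
    """
    if side == "left":
        ideal = int(np.searchsorted(positions, true_breakpoint, side="left"))
        recovered = int(np.searchsorted(positions, recovered_pos))
    else:
        ideal = int(np.searchsorted(positions, true_breakpoint, side="right")) - 1
        recovered = int(np.searchsorted(positions, recovered_pos))
    return abs(recovered - ideal)


def segment_recovery(
    seed: int,
    n_replicates: int = 30,
    n_markers: int = 200,
) -> SegmentRecoveryResult:
    """Recover transmitted-segment boundaries against recorded breakpoints.

    A parent with two fully distinguishable haplotypes (complementary at
    every marker, i.e. a maximally informative panel) transmits a
    recombinant gamete to a child; the variant is planted on whichever
    parental slot supplied the focal site, so parent and child share
    exactly the transmission block around it.  The recovered segment
    bounds must sit within one marker interval of the recorded crossover
    breakpoints (or at the map ends when no crossover flanks the site).
    """
    pedigree = Pedigree({
        "P1": Individual("P1", Sex.male),
        "P2": Individual("P2", Sex.female),
        "C1": Individual("C1", Sex.male, "P1", "P2"),
    })
    max_start = 0
    max_end = 0
    from .haplotype_tracing import HaplotypePair, PhasedGenotypes

    for rep in range(n_replicates):
        config = SimConfig(seed=(seed * 100_003 + rep) & 0x7FFFFFFF,
                           n_markers=n_markers, recomb_rate=2.0)
        marker_map = config.make_marker_map()
        n = len(marker_map)
        rng = config.rng("segment-bench")

        base = (rng.random(n) < 0.5).astype(np.int8)
        father = HaplotypePair(np.stack([base, 1 - base]))
        mother_alleles = (rng.random((2, n)) < 0.5).astype(np.int8)
        mother = HaplotypePair(mother_alleles)
        for pair in (father, mother):
            pair.alleles[:, marker_map.focal_index] = 0

        hap_p, transmission = synth._gamete(father, marker_map, config, rng)
        hap_m, _ = synth._gamete(mother, marker_map, config, rng)
        child = HaplotypePair(np.stack([hap_p, hap_m]),
                              origins=(HapOrigin.paternal, HapOrigin.maternal))

        variant_slot = transmission.source_slot_at(marker_map.focal_pos)
        father.alleles[variant_slot, marker_map.focal_index] = 1
        child.alleles[0, marker_map.focal_index] = 1
        phased = PhasedGenotypes(marker_map, {
            "P1": father, "P2": mother, "C1": child})

        segment = shared_segment(phased, {"P1", "C1"})

        flanking_left = [b for b in transmission.breakpoints
                         if b <= marker_map.focal_pos]
        flanking_right = [b for b in transmission.breakpoints
                          if b > marker_map.focal_pos]
        positions = marker_map.positions
        if flanking_left:
            max_start = max(max_start, _marker_offset(
                positions, segment.start_pos, max(flanking_left), "left"))
        elif segment.start_pos != int(positions[0]):
            max_start = max(max_start, n)  # should have reached the map end
        if flanking_right:
            max_end = max(max_end, _marker_offset(
                positions, segment.end_pos, min(flanking_right), "right"))
        elif segment.end_pos != int(positions[-1]):
            max_end = max(max_end, n)
    return SegmentRecoveryResult(n_replicates, max_start, max_end)


# ---------------------------------------------------------------------------
# end-to-end population screen


@dataclass
class ScreenOracleResult:
    n_variants_expected: int
    n_variants_screened: int
    carriers_match: bool
    counts_match: bool
    kept_match: bool
    majority_actionable_match: bool
    strict_actionable_match: bool
    conflict_profile_checked: bool

    @property
    def all_match(self) -> bool:
        return (self.n_variants_expected == self.n_variants_screened
                and self.carriers_match and self.counts_match
                and self.kept_match and self.majority_actionable_match
                and self.strict_actionable_match)


def screen_oracle_check(
    seed: int,
    cohort_size: int = 2000,
    n_variants: int = 50,
    work_dir: str | Path | None = None,
) -> ScreenOracleResult:
    """Run the full screen on a generated cohort and score it exactly.

    The generated VCF/TSV files are written to disk, re-read through the
    same loaders a real analysis would use, filtered, aggregated under
    both conflict rules and compared record by record with the
    generator's ledger — allele counts, carrier sets, filter survivors and
    actionable sets must all match exactly, including the
    {pathogenic: 10, likely_benign: 1} profile being actionable under the
    majority rule and excluded under the strict rule.
    """
    config = SimConfig(seed=seed, cohort_size=cohort_size,
                       n_variants=n_variants)
    sim = synth.gen_cohort(config)

    if work_dir is None:
        tmp = tempfile.TemporaryDirectory()
        work_dir = tmp.name
    paths = sim.write(work_dir)

    regions = read_gene_regions_bed(paths["regions"])
    annotations = read_annotations_tsv(paths["annotations"])
    table = load_cohort_variants(paths["vcf"], regions, annotations,
                                 cohort_label="synthetic cohort")

    truth = {
        VariantKey.make(v["chrom"], v["pos"], v["ref"], v["alt"]): v
        for v in sim.ledger.cohort_variants
    }
    screened_by_key = {r.key: r for r in table.records}

    carriers_match = counts_match = True
    for key, v in truth.items():
        record = screened_by_key.get(key)
        if record is None:
            carriers_match = counts_match = False
            continue
        if set(record.carriers) != set(v["carriers"]):
            carriers_match = False
        if (record.allele_count != v["allele_count"]
                or record.allele_number != v["allele_number"]):
            counts_match = False

    filtered = filter_rare_coding(table, maf_threshold=0.001)
    kept_truth = {k for k, v in truth.items() if v["kept_by_filter"]}
    kept_match = {r.key for r in filtered.records} == kept_truth

    entries = parse_classifications(paths["classifications"])
    results = {}
    for rule in (Rule.majority, Rule.strict):
        calls = [aggregate_classification(e, rule) for e in entries]
        actionable_keys = {
            c.key for c in calls if c.aggregate is Verdict.actionable
        } & set(truth)
        truth_keys = {
            k for k, v in truth.items()
            if v[f"actionable_{rule.value}"]
        }
        results[rule] = actionable_keys == truth_keys

    conflict_checked = False
    for key, v in truth.items():
        if v["profile"] == {"pathogenic": 10, "likely_benign": 1}:
            entry = next(e for e in entries if e.key == key)
            conflict_checked = (
                aggregate_classification(entry, Rule.majority).aggregate
                is Verdict.actionable
                and aggregate_classification(entry, Rule.strict).aggregate
                is Verdict.conflicting_excluded)
            break

    return ScreenOracleResult(
        n_variants_expected=len(truth),
        n_variants_screened=len(table),
        carriers_match=carriers_match,
        counts_match=counts_match,
        kept_match=kept_match,
        majority_actionable_match=results[Rule.majority],
        strict_actionable_match=results[Rule.strict],
        conflict_profile_checked=conflict_checked,
    )
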