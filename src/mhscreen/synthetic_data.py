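"""Synthetic pedigrees, haplotypes, read depths and cohorts with ground truth.

Everything the pipeline consumes can be generated here: multi-generation
pedigrees, phased parent-of-origin haplotypes dropped through the pedigree
with Poisson recombination, a planted rare variant (constitutional
heterozygous or mosaic, with thinned germline transmission out of a mosaic
origin), per-individual read depths, and a population cohort VCF with a
matching ClinVar-style classification table.  Every simulation records a
ground-truth ledger sufficient to score pipeline outputs without
re-simulation; the ledger is a separate artifact and never leaks into the
generated files themselves.

Randomness is organised as one pseudo-random stream per operation, seeded
from ``SimConfig.seed`` plus an operation tag, so adding an operation never
perturbs another's output and a fixed seed yields byte-identical files.

Model notes
-----------
* Crossovers per meiosis are Poisson(``recomb_rate``) with positions
  uniform on the chromosome (no interference) — the simplest transmission
  model that exercises segment recovery.
* A mosaic founder with heterozygous-cell fraction *m* yields reads with
  expected alternate fraction m/2, and transmits the variant on its
  background haplotype with probability ``germline_transmission_fraction``
  per meiosis; a constitutional heterozygote transmits it with the
  haplotype always.
* The focal marker is the rare-variant site itself: founders carry the
  reference allele there until a mutation is planted.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .haplotype_tracing import (
    HapOrigin,
    HaplotypePair,
    Individual,
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
    Sex,
)
from .mosaicism import AllelicDepth, Genotype
from .population_screen import Consequence, VariantKey

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]

#: Default tally profiles cycled over planted cohort variants; includes the
#: canonical conflict cases (pathogenic majority over one likely-benign,
#: and an exact pathogenic/benign tie).
DEFAULT_CLASSIFICATION_MIX: tuple[Mapping[str, int], ...] = (
    {"pathogenic": 2},
    {"pathogenic": 10, "likely_benign": 1},
    {"uncertain": 3},
    {"pathogenic": 1, "benign": 1},
    {"likely_pathogenic": 1},
    {"benign": 2},
    {"drug_response_pathogenic": 2},
    {"likely_benign": 1, "uncertain": 1},
)

#: Gene regions used by the synthetic cohort (1-based inclusive).
DEFAULT_GENE_REGIONS: dict[str, tuple[str, int, int]] = {
    "RYR1": ("chr19", 38433691, 38595273),
    "CACNA1S": ("chr1", 201039512, 201112451),
}

DEFAULT_FOCAL_POS = 38_496_455


@dataclass
class SimConfig:
    """Study conditions for all synthetic-data operations."""

    seed: int = 0
    # pedigree shape
    n_generations: int = 3
    children_per_couple: int = 2
    # marker panel
    n_markers: int = 200
    chrom: str = "chr19"
    chrom_length: int = 59_000_000
    focal_pos: int = DEFAULT_FOCAL_POS
    marker_allele_freq: float = 0.5
    # transmission and sequencing
    recomb_rate: float = 1.0
    depth_mean: float = 30.0
    error_rate: float = 0.002
    mosaic_cell_fraction: float = 0.4
    germline_transmission_fraction: float = 0.5
    # population cohort
    cohort_size: int = 2000
    n_variants: int = 50
    max_variant_maf: float = 0.0008
    common_variant_fraction: float = 0.15
    classified_fraction: float = 0.75
    missing_genotype_rate: float = 0.002
    classification_mix: tuple[Mapping[str, int], ...] = DEFAULT_CLASSIFICATION_MIX

    def rng(self, tag: str, *extra: int) -> np.random.Generator:
        """Operation-tagged generator: independent stream per (seed, tag)."""
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(tag.encode()), *extra])

    def make_marker_map(self) -> MarkerMap:
        """Evenly spaced marker panel with the focal variant site inserted."""
        lo = max(1, int(self.chrom_length * 0.01))
        hi = int(self.chrom_length * 0.99)
        base = np.unique(np.linspace(lo, hi, self.n_markers).astype(np.int64))
        positions = np.unique(np.append(base, self.focal_pos))
        focal_index = int(np.searchsorted(positions, self.focal_pos))
        return MarkerMap(self.chrom, positions, focal_index)


@dataclass
class Transmission:
    """One meiosis: which parental haplotype slot a child received where."""

    start_slot: int
    breakpoints: list[int]

    def source_slot_at(self, pos: int) -> int:
        crossings = sum(1 for b in self.breakpoints if b <= pos)
        return self.start_slot ^ (crossings % 2)


@dataclass
class GroundTruthLedger:
    """Everything needed to score pipeline outputs without re-simulation."""

    # haplotype dropping
    transmissions: dict[tuple[str, str], Transmission] = field(default_factory=dict)
    # mutation planting
    origin: str | None = None
    origin_mode: str | None = None
    cell_fraction: float | None = None
    true_carriers: set[str] = field(default_factory=set)
    variant_slots: dict[str, int] = field(default_factory=dict)
    background_sharers: set[str] = field(default_factory=set)
    true_states: dict[str, str] = field(default_factory=dict)
    # cohort screen
    cohort_variants: list[dict] = field(default_factory=list)
    cohort_samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "origin": self.origin,
            "origin_mode": self.origin_mode,
            "cell_fraction": self.cell_fraction,
            "true_carriers": sorted(self.true_carriers),
            "variant_slots": dict(sorted(self.variant_slots.items())),
            "background_sharers": sorted(self.background_sharers),
            "true_states": dict(sorted(self.true_states.items())),
            "transmissions": {
                f"{child}:{side}": {"start_slot": t.start_slot,
                                    "breakpoints": t.breakpoints}
                for (child, side), t in self.transmissions.items()
            },
            "cohort_variants": self.cohort_variants,
            "n_cohort_samples": len(self.cohort_samples),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# pedigree generation


def _roman_label(generation: int, index: int) -> str:
    return f"{_ROMAN[generation - 1]}-{index}"


def gen_pedigree(config: SimConfig) -> Pedigree:
    """Connected monogamous pedigree with Roman-numeral generation labels.

    Generation 1 is a single founder couple; every child in intermediate
    generations marries an unrelated spouse and has
    ``children_per_couple`` children.
    """
    if config.n_generations < 2:
        raise ValueError("need at least 2 generations")
    rng = config.rng("pedigree")
    members: dict[str, Individual] = {}
    counters = {g: 0 for g in range(1, config.n_generations + 1)}

    def add(generation: int, sex: Sex, father: str | None = None,
            mother: str | None = None) -> str:
        counters[generation] += 1
        label = _roman_label(generation, counters[generation])
        members[label] = Individual(
            id=label, sex=sex, father_id=father, mother_id=mother,
            generation_label=label)
        return label

    father = add(1, Sex.male)
    mother = add(1, Sex.female)
    couples = [(father, mother)]
    for generation in range(2, config.n_generations + 1):
        next_couples = []
        for f, m in couples:
            for _ in range(config.children_per_couple):
                sex = Sex.male if rng.random() < 0.5 else Sex.female
                child = add(generation, sex, father=f, mother=m)
                if generation < config.n_generations:
                    spouse_sex = Sex.female if sex is Sex.male else Sex.male
                    spouse = add(generation, spouse_sex)
                    if sex is Sex.male:
                        next_couples.append((child, spouse))
                    else:
                        next_couples.append((spouse, child))
        couples = next_couples
    return Pedigree(members)


# ---------------------------------------------------------------------------
# haplotype dropping


def _gamete(parent: HaplotypePair, marker_map: MarkerMap, config: SimConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, Transmission]:
    n_cross = int(rng.poisson(config.recomb_rate))
    breakpoints = sorted(
        int(b) for b in rng.uniform(1, config.chrom_length, size=n_cross))
    start_slot = int(rng.integers(0, 2))
    transmission = Transmission(start_slot, breakpoints)
    slots = np.fromiter(
        (transmission.source_slot_at(int(p)) for p in marker_map.positions),
        dtype=np.int8, count=len(marker_map))
    hap = parent.alleles[slots, np.arange(len(marker_map))].copy()
    return hap, transmission


def _topological_members(pedigree: Pedigree) -> list[str]:
    done: set[str] = set()
    order: list[str] = []
    pending = list(pedigree.members)
    while pending:
        progressed = False
        remaining = []
        for ind_id in pending:
            parents = pedigree.parents(ind_id)
            if all(p in done for p in parents):
                order.append(ind_id)
                done.add(ind_id)
                progressed = True
            else:
                remaining.append(ind_id)
        if not progressed:
            raise ValueError("pedigree has unresolvable parent links")
        pending = remaining
    return order


def drop_haplotypes(
    pedigree: Pedigree, config: SimConfig, stream: str = "drop",
) -> tuple[PhasedGenotypes, GroundTruthLedger]:
    """Gene-drop founder haplotypes through the pedigree.

    Founder haplotypes draw marker alleles independently at
    ``marker_allele_freq``; the focal site stays at the reference allele
    everywhere until :func:`plant_mutation`.  Each meiosis draws a
    Poisson(``recomb_rate``) crossover count with uniform positions; the
    ledger records every transmission's breakpoints.  Children's slot 0 is
    the paternal copy and slot 1 the maternal copy.
    """
    rng = config.rng(stream)
    marker_map = config.make_marker_map()
    ledger = GroundTruthLedger()
    data: dict[str, HaplotypePair] = {}

    for ind_id in _topological_members(pedigree):
        ind = pedigree.members[ind_id]
        if ind.father_id is None and ind.mother_id is None:
            alleles = (rng.random((2, len(marker_map)))
                       < config.marker_allele_freq).astype(np.int8)
            alleles[:, marker_map.focal_index] = 0
            data[ind_id] = HaplotypePair(alleles)
        else:
            hap_p, trans_p = _gamete(data[ind.father_id], marker_map, config, rng)
            hap_m, trans_m = _gamete(data[ind.mother_id], marker_map, config, rng)
            ledger.transmissions[(ind_id, "paternal")] = trans_p
            ledger.transmissions[(ind_id, "maternal")] = trans_m
            data[ind_id] = HaplotypePair(
                np.stack([hap_p, hap_m]),
                origins=(HapOrigin.paternal, HapOrigin.maternal))
    return PhasedGenotypes(marker_map, data), ledger


# ---------------------------------------------------------------------------
# mutation planting


def plant_mutation(
    phased: PhasedGenotypes,
    pedigree: Pedigree,
    origin: str,
    mode: str,
    config: SimConfig,
    ledger: GroundTruthLedger,
    origin_slot: int | None = None,
    stream: str = "plant",
) -> GroundTruthLedger:
    """Plant the focal variant on one haplotype of ``origin`` and propagate.

    A descendant inherits the variant when its parent carries it and the
    ledger's recorded meiosis transmitted the variant-bearing slot at the
    focal position — with probability ``germline_transmission_fraction``
    per transmission out of a mosaic origin (germline mosaicism thins
    transmission), probability 1 otherwise.  Haplotype alleles at the
    focal site are updated in place; descendants who inherited the
    background haplotype without the variant are recorded as background
    sharers.  Returns the updated ledger.
    """
    if origin not in pedigree.members:
        raise ValueError(f"origin {origin} not in pedigree")
    if mode not in ("heterozygous", "mosaic"):
        raise ValueError(f"unknown mutation mode {mode!r}")
    rng = config.rng(stream)
    marker_map = phased.marker_map
    focal_index = marker_map.focal_index
    focal_pos = marker_map.focal_pos

    pair = phased.data[origin]
    if origin_slot is None:
        labelled = [s for s in (0, 1) if pair.origins[s] is HapOrigin.maternal]
        origin_slot = labelled[0] if labelled else 0
    if focal_index >= pair.alleles.shape[1]:
        raise ValueError("origin haplotype lacks the focal marker")
    pair.alleles[origin_slot, focal_index] = 1

    ledger.origin = origin
    ledger.origin_mode = mode
    ledger.cell_fraction = (config.mosaic_cell_fraction
                            if mode == "mosaic" else 1.0)
    ledger.true_carriers = {origin}
    ledger.variant_slots = {origin: origin_slot}
    ledger.background_sharers = set()

    for ind_id in _topological_members(pedigree):
        ind = pedigree.members[ind_id]
        for side, parent_id in (("paternal", ind.father_id),
                                ("maternal", ind.mother_id)):
            if parent_id is None or parent_id not in ledger.true_carriers:
                continue
            transmission = ledger.transmissions[(ind_id, side)]
            if transmission.source_slot_at(focal_pos) != ledger.variant_slots[parent_id]:
                continue
            # the variant-bearing background haplotype was transmitted
            germline_hit = True
            if parent_id == origin and mode == "mosaic":
                germline_hit = rng.random() < config.germline_transmission_fraction
            child_slot = 0 if side == "paternal" else 1
            if germline_hit:
                phased.data[ind_id].alleles[child_slot, focal_index] = 1
                ledger.true_carriers.add(ind_id)
                ledger.variant_slots[ind_id] = child_slot
            else:
                ledger.background_sharers.add(ind_id)

    ledger.true_states = {}
    for ind_id in pedigree.members:
        if ind_id == origin:
            ledger.true_states[ind_id] = (
                "mosaic" if mode == "mosaic" else "heterozygous")
        elif ind_id in ledger.true_carriers:
            ledger.true_states[ind_id] = "heterozygous"
        else:
            ledger.true_states[ind_id] = "non_carrier"
    return ledger


# ---------------------------------------------------------------------------
# read simulation


def sim_reads(
    state: str,
    config: SimConfig,
    rng: np.random.Generator,
    individual: str = "",
) -> AllelicDepth:
    """Draw allelic depths for one individual at the focal site.

    ``state`` is ``non_carrier``, ``heterozygous`` or ``mosaic``; depth is
    Poisson(``depth_mean``), the alternate-read count binomial with success
    probability ``error_rate``, 0.5 or ``mosaic_cell_fraction / 2``.
    """
    q = {
        "non_carrier": config.error_rate,
        "heterozygous": 0.5,
        "mosaic": config.mosaic_cell_fraction / 2.0,
    }[state]
    depth = int(rng.poisson(config.depth_mean))
    alt = int(rng.binomial(depth, q)) if depth > 0 else 0
    return AllelicDepth(individual=individual, ref_reads=depth - alt,
                        alt_reads=alt)


def sim_family_reads(
    ledger: GroundTruthLedger,
    pedigree: Pedigree,
    config: SimConfig,
    stream: str = "reads",
) -> tuple[dict[str, AllelicDepth], dict[str, Genotype]]:
    """Reads for every pedigree member plus crude genotype calls.

    The genotype call is heterozygous when at least three alternate reads
    were observed, otherwise homozygous reference — the same presence
    threshold the carrier-state classifier uses.
    """
    rng = config.rng(stream)
    depths: dict[str, AllelicDepth] = {}
    genotypes: dict[str, Genotype] = {}
    for ind_id in sorted(pedigree.members):
        depth = sim_reads(ledger.true_states[ind_id], config, rng, ind_id)
        depths[ind_id] = depth
        genotypes[ind_id] = (Genotype.het if depth.alt_reads >= 3
                             else Genotype.hom_ref)
    return depths, genotypes


# ---------------------------------------------------------------------------
# the index-family fixture


def index_family_pedigree() -> Pedigree:
    """16-member four-generation-labelled pedigree of the index family.

    Carrier topology: the variant is mosaic in the grandmother II-5 and
    constitutionally heterozygous in her son III-5 and his two children
    IV-1 and IV-4 (paternal half-siblings); II-2 is II-5's sister and
    shares the grandmaternal haplotype without the variant.
    """
    spec = [
        # id, sex, father, mother
        ("I-1", Sex.male, None, None),
        ("I-2", Sex.female, None, None),
        ("II-1", Sex.male, None, None),          # married in (II-2)
        ("II-2", Sex.female, "I-1", "I-2"),      # sister of II-5
        ("II-4", Sex.male, None, None),          # married in (II-5)
        ("II-5", Sex.female, "I-1", "I-2"),      # grandmother, mosaic origin
        ("III-1", Sex.male, "II-1", "II-2"),
        ("III-2", Sex.female, "II-4", "II-5"),
        ("III-3", Sex.male, None, None),         # married in (III-2)
        ("III-4", Sex.female, None, None),       # first partner of III-5
        ("III-5", Sex.male, "II-4", "II-5"),     # father of the proband
        ("III-6", Sex.female, None, None),       # second partner of III-5
        ("IV-1", Sex.male, "III-5", "III-4"),    # paternal half-sibling
        ("IV-2", Sex.female, "III-3", "III-2"),
        ("IV-3", Sex.male, "III-3", "III-2"),
        ("IV-4", Sex.male, "III-5", "III-6"),    # proband
    ]
    return Pedigree({
        ind_id: Individual(ind_id, sex, father, mother, ind_id)
        for ind_id, sex, father, mother in spec
    })


@dataclass
class IndexFamily:
    pedigree: Pedigree
    phased: PhasedGenotypes
    depths: dict[str, AllelicDepth]
    genotypes: dict[str, Genotype]
    carriers: set[str]
    origin: str
    discordant_truth: set[str]


def index_family(config: SimConfig | None = None) -> IndexFamily:
    """Deterministic index-family fixture with phase, depths and genotypes.

    Transmissions are recombination-free and fixed so that the four
    carriers (II-5, III-5, IV-1, IV-4) share the grandmaternal haplotype
    carrying the variant across the whole marker panel, and II-2 shares
    the same background without the variant.  WGS depths reflect the
    observed case: balanced in the constitutional heterozygotes
    (e.g. 18 ref / 19 alt in the proband) and skewed (22 ref / 6 alt) in
    the mosaic grandmother.
    """
    config = config or SimConfig(seed=1, n_markers=61)
    pedigree = index_family_pedigree()
    marker_map = config.make_marker_map()
    n = len(marker_map)
    rng = config.rng("index-family")

    founders = ["I-1", "I-2", "II-1", "II-4", "III-3", "III-4", "III-6"]
    founder_haps = {
        f: (rng.random((2, n)) < config.marker_allele_freq).astype(np.int8)
        for f in founders
    }
    for haps in founder_haps.values():
        haps[:, marker_map.focal_index] = 0

    data: dict[str, HaplotypePair] = {
        f: HaplotypePair(founder_haps[f].copy()) for f in founders
    }

    def child(paternal: np.ndarray, maternal: np.ndarray) -> HaplotypePair:
        return HaplotypePair(
            np.stack([paternal.copy(), maternal.copy()]),
            origins=(HapOrigin.paternal, HapOrigin.maternal))

    h = founder_haps
    data["II-2"] = child(h["I-1"][0], h["I-2"][0])
    data["II-5"] = child(h["I-1"][1], h["I-2"][0])   # same maternal background
    data["III-1"] = child(h["II-1"][0], data["II-2"].alleles[0])
    data["III-2"] = child(h["II-4"][0], data["II-5"].alleles[0])
    data["III-5"] = child(h["II-4"][1], data["II-5"].alleles[1])
    data["IV-1"] = child(data["III-5"].alleles[1], h["III-4"][0])
    data["IV-2"] = child(h["III-3"][0], data["III-2"].alleles[1])
    data["IV-3"] = child(h["III-3"][1], data["III-2"].alleles[0])
    data["IV-4"] = child(data["III-5"].alleles[1], h["III-6"][0])

    # plant the de novo variant: on II-5's maternally inherited haplotype
    # and on every copy her carrier descendants received (II-2's copy of
    # the same grandmaternal background stays at the reference allele)
    focal = marker_map.focal_index
    for ind_id, slot in (("II-5", 1), ("III-5", 1), ("IV-1", 0), ("IV-4", 0)):
        data[ind_id].alleles[slot, focal] = 1

    # generation I is deceased and untyped: known from genealogy, no DNA
    del data["I-1"], data["I-2"]
    phased = PhasedGenotypes(marker_map, data)

    observed = {
        "II-5": (22, 6),    # mosaic grandmother
        "III-5": (15, 16),
        "IV-1": (14, 13),
        "IV-4": (18, 19),   # proband
    }
    depths: dict[str, AllelicDepth] = {}
    genotypes: dict[str, Genotype] = {}
    for ind_id in data:
        if ind_id in observed:
            ref, alt = observed[ind_id]
            genotypes[ind_id] = Genotype.het
        else:
            ref, alt = 28 + (zlib.crc32(ind_id.encode()) % 7), 0
            genotypes[ind_id] = Genotype.hom_ref
        depths[ind_id] = AllelicDepth(ind_id, ref, alt)

    return IndexFamily(
        pedigree=pedigree,
        phased=phased,
        depths=depths,
        genotypes=genotypes,
        carriers={"II-5", "III-5", "IV-1", "IV-4"},
        origin="II-5",
        discordant_truth={"II-2"},
    )


# ---------------------------------------------------------------------------
# population cohort generation


_CONSEQUENCE_CHOICES = [
    (Consequence.missense, 0.45),
    (Consequence.synonymous, 0.20),
    (Consequence.stop_gained, 0.10),
    (Consequence.splice_donor, 0.07),
    (Consequence.splice_acceptor, 0.07),
    (Consequence.other, 0.11),
]


@dataclass
class CohortSim:
    """A generated cohort: file contents plus the ground-truth ledger."""

    vcf_text: str
    classification_rows: pd.DataFrame
    annotation_rows: pd.DataFrame
    gene_regions: dict[str, tuple[str, int, int]]
    ledger: GroundTruthLedger

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write VCF, classification TSV, annotation TSV, regions BED, ledger JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "classifications": out / "classifications.tsv",
            "annotations": out / "annotations.tsv",
            "regions": out / "gene_regions.bed",
            "ledger": out / "ledger.json",
        }
        paths["vcf"].write_text(self.vcf_text)
        self.classification_rows.to_csv(paths["classifications"], sep="\t",
                                        index=False)
        self.annotation_rows.to_csv(paths["annotations"], sep="\t", index=False)
        bed_lines = [
            f"{chrom}\t{start - 1}\t{end}\t{gene}"
            for gene, (chrom, start, end) in self.gene_regions.items()
        ]
        paths["regions"].write_text("\n".join(bed_lines) + "\n")
        self.ledger.to_json(paths["ledger"])
        return paths


def _profile_verdicts(profile: Mapping[str, int]) -> tuple[str, str]:
    """Actionability truth for a planted tally profile, by rule arithmetic."""
    pathogenic_side = sum(profile.get(k, 0) for k in (
        "pathogenic", "likely_pathogenic", "drug_response_pathogenic"))
    benign_side = sum(profile.get(k, 0) for k in ("benign", "likely_benign"))
    uncertain = profile.get("uncertain", 0)
    if pathogenic_side >= 1 and pathogenic_side > benign_side:
        majority = "actionable"
    elif pathogenic_side >= 1:
        majority = "conflicting_excluded"
    else:
        majority = "not_actionable"
    if pathogenic_side >= 1 and benign_side == 0 and uncertain == 0:
        strict = "actionable"
    elif pathogenic_side >= 1:
        strict = "conflicting_excluded"
    else:
        strict = "not_actionable"
    return majority, strict


def gen_cohort(config: SimConfig, stream: str = "cohort") -> CohortSim:
    """Generate a cohort VCF, classification table and ground-truth ledger.

    Variants are planted in the two target gene regions with carrier sets
    drawn directly (mostly rare heterozygotes below the MAF threshold, a
    configurable fraction common), genotype missingness sprinkled over
    non-carriers only, and a classification profile from
    ``classification_mix`` cycled over a ``classified_fraction`` subset.
    The ledger records, per variant, the exact allele counts, carrier
    sets, the planted profile and its actionability truth under both
    conflict rules, plus whether the rare-coding filter keeps it.
    """
    rng = config.rng(stream)
    samples = [f"S{i:05d}" for i in range(1, config.cohort_size + 1)]
    genes = list(DEFAULT_GENE_REGIONS.items())

    n_variants = config.n_variants
    gene_assignment = [genes[0] if rng.random() < 0.8 else genes[1]
                       for _ in range(n_variants)]
    used_positions: dict[str, set[int]] = {}
    bases = np.array(list("ACGT"))

    variant_defs = []
    for gene, (chrom, start, end) in gene_assignment:
        taken = used_positions.setdefault(chrom, set())
        while True:
            pos = int(rng.integers(start, end + 1))
            if pos not in taken:
                taken.add(pos)
                break
        ref, alt = rng.choice(bases, size=2, replace=False)
        consequences, weights = zip(*_CONSEQUENCE_CHOICES)
        consequence = rng.choice(
            np.array([c.value for c in consequences]), p=np.array(weights))
        variant_defs.append((gene, chrom, pos, str(ref), str(alt),
                             Consequence(consequence)))
    variant_defs.sort(key=lambda v: (v[1], v[2]))

    max_rare_carriers = max(
        1, int(config.max_variant_maf * 2 * config.cohort_size) - 1)
    ledger = GroundTruthLedger(cohort_samples=samples)
    vcf_rows = []
    annotation_rows = []
    classification_records = []
    profile_cycle = 0

    for v_index, (gene, chrom, pos, ref, alt, consequence) in enumerate(variant_defs):
        if rng.random() < config.common_variant_fraction:
            n_carriers = int(config.cohort_size * rng.uniform(0.005, 0.05))
        else:
            n_carriers = int(rng.integers(1, max_rare_carriers + 1))
        carrier_idx = rng.choice(config.cohort_size, size=n_carriers,
                                 replace=False)
        genotype_codes = np.zeros(config.cohort_size, dtype=np.int8)
        genotype_codes[carrier_idx] = 1
        hom_idx = carrier_idx[rng.random(n_carriers) < 0.05]
        genotype_codes[hom_idx] = 2
        non_carrier_mask = genotype_codes == 0
        missing = non_carrier_mask & (
            rng.random(config.cohort_size) < config.missing_genotype_rate)
        genotype_codes[missing] = -1

        allele_number = int(2 * np.sum(genotype_codes >= 0))
        allele_count = int(np.sum(genotype_codes[genotype_codes > 0]))
        maf = min(allele_count, allele_number - allele_count) / allele_number
        carriers = sorted(samples[i] for i in carrier_idx)

        classified = rng.random() < config.classified_fraction
        profile = None
        verdicts = ("not_actionable", "not_actionable")
        if classified:
            profile = dict(config.classification_mix[
                profile_cycle % len(config.classification_mix)])
            profile_cycle += 1
            verdicts = _profile_verdicts(profile)

        kept_by_filter = (
            maf < 0.001
            and consequence not in (Consequence.synonymous, Consequence.other))
        ledger.cohort_variants.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": gene, "consequence": consequence.value,
            "allele_count": allele_count, "allele_number": allele_number,
            "maf": maf, "carriers": carriers,
            "profile": profile,
            "actionable_majority": verdicts[0] == "actionable",
            "actionable_strict": verdicts[1] == "actionable",
            "verdict_majority": verdicts[0], "verdict_strict": verdicts[1],
            "kept_by_filter": kept_by_filter,
        })
        gt_strings = np.array(["0/0"] * config.cohort_size, dtype=object)
        gt_strings[genotype_codes == 1] = "0/1"
        gt_strings[genotype_codes == 2] = "1/1"
        gt_strings[genotype_codes == -1] = "./."
        vcf_rows.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gt_strings))
        annotation_rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": gene, "consequence": consequence.value,
        })
        if classified:
            for label, count in profile.items():
                classification_records.append({
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "gene": gene, "hgvs_c": f"c.{1000 + v_index}{ref}>{alt}",
                    "hgvs_p": "p.?", "label": label.replace("_", " "),
                    "n_submissions": count, "phenotype": "synthetic phenotype",
                })

    # classification rows for variants absent from the cohort (routinely
    # present in real classification tables; the join must ignore them)
    region_gene, (chrom, start, end) = genes[0]
    for extra in range(3):
        taken = used_positions.setdefault(chrom, set())
        while True:
            pos = int(rng.integers(start, end + 1))
            if pos not in taken:
                taken.add(pos)
                break
        ref, alt = rng.choice(bases, size=2, replace=False)
        classification_records.append({
            "chrom": chrom, "pos": pos, "ref": str(ref), "alt": str(alt),
            "gene": region_gene, "hgvs_c": f"c.{9000 + extra}{ref}>{alt}",
            "hgvs_p": "p.?", "label": "pathogenic", "n_submissions": 1,
            "phenotype": "synthetic phenotype (absent from cohort)",
        })

    contigs = sorted({chrom for _, (chrom, _, _) in genes})
    header = "\n".join([
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ])
    vcf_text = header + "\n" + "\n".join(vcf_rows) + "\n"
    return CohortSim(
        vcf_text=vcf_text,
        classification_rows=pd.DataFrame(classification_records),
        annotation_rows=pd.DataFrame(annotation_rows),
        gene_regions=dict(DEFAULT_GENE_REGIONS),
        ledger=ledger,
    )
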