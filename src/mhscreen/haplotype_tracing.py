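"""Shared-haplotype tracing of a variant's origin through a pedigree.

Given phased, parent-of-origin-labelled haplotypes for family members and
per-individual carrier states at a focal variant, this module:

* finds the maximal haplotype segment around the focal site shared by all
  carriers (identity by descent among the variant-bearing haplotypes);
* traces each carrier haplotype's parental origin and the chain of
  parent-to-child transmissions linking the carriers;
* detects *discordant sharers* — relatives who carry the same haplotype
  background but not the variant;
* combines the evidence into an origin inference: a discordant sharer on
  the variant-bearing lineage means the haplotype predates the variant,
  so the variant arose de novo in the topmost carrier — as a germline +
  somatic mosaic if that carrier shows allelic imbalance, or as an
  ordinary constitutional de novo otherwise.

Positions are 1-based inclusive throughout, matching the usual genomic
coordinate style; BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mosaicism import CarrierState, State

MISSING = -1  # missing allele code in haplotype vectors


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class HapOrigin(str, Enum):
    paternal = "paternal"
    maternal = "maternal"
    unknown = "unknown"


@dataclass
class Individual:
    id: str
    sex: Sex = Sex.unknown
    father_id: str | None = None
    mother_id: str | None = None
    generation_label: str = ""


@dataclass
class Pedigree:
    """Family structure as a map id -> Individual with validated parent links."""

    members: dict[str, Individual]

    def __post_init__(self) -> None:
        for ind in self.members.values():
            for parent_id, want_sex in ((ind.father_id, Sex.male),
                                        (ind.mother_id, Sex.female)):
                if parent_id is None:
                    continue
                parent = self.members.get(parent_id)
                if parent is None:
                    raise ValueError(
                        f"{ind.id}: parent {parent_id} not in pedigree")
                if parent.sex is not Sex.unknown and parent.sex is not want_sex:
                    raise ValueError(
                        f"{ind.id}: parent {parent_id} has sex "
                        f"{parent.sex.value}, expected {want_sex.value}")
        # acyclicity: every individual must have a finite ancestor closure
        for ind_id in self.members:
            self.ancestors(ind_id)

    def parents(self, ind_id: str) -> list[str]:
        ind = self.members[ind_id]
        return [p for p in (ind.father_id, ind.mother_id) if p is not None]

    def children(self, ind_id: str) -> list[str]:
        return [i.id for i in self.members.values()
                if ind_id in (i.father_id, i.mother_id)]

    def ancestors(self, ind_id: str) -> set[str]:
        seen: set[str] = set()
        stack = list(self.parents(ind_id))
        while stack:
            p = stack.pop()
            if p == ind_id:
                raise ValueError(f"{ind_id} is its own ancestor")
            if p in seen:
                continue
            seen.add(p)
            stack.extend(self.parents(p))
        if ind_id in seen:
            raise ValueError(f"{ind_id} is its own ancestor")
        return seen

    def descendants(self, ind_id: str) -> set[str]:
        seen: set[str] = set()
        stack = self.children(ind_id)
        while stack:
            c = stack.pop()
            if c in seen:
                continue
            seen.add(c)
            stack.extend(self.children(c))
        return seen

    def related(self, a: str, b: str) -> bool:
        """True if a and b are connected through the pedigree graph."""
        seen = {a}
        stack = [a]
        while stack:
            cur = stack.pop()
            if cur == b:
                return True
            for nxt in self.parents(cur) + self.children(cur):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False


@dataclass
class MarkerMap:
    """Ascending marker positions on one chromosome with a focal-site index."""

    chrom: str
    positions: np.ndarray
    focal_index: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("marker positions must be strictly increasing")
        if not 0 <= self.focal_index < len(self.positions):
            raise ValueError("focal_index outside the marker map")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def focal_pos(self) -> int:
        return int(self.positions[self.focal_index])


@dataclass
class HaplotypePair:
    """An individual's two phased haplotypes with parental-origin labels.

    ``alleles`` has shape (2, n_markers) with entries 0/1 or -1 (missing);
    slot 0 and slot 1 carry the origin labels in ``origins``.
    """

    alleles: np.ndarray
    origins: tuple[HapOrigin, HapOrigin] = (HapOrigin.unknown, HapOrigin.unknown)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2:
            raise ValueError("alleles must have shape (2, n_markers)")
        self.origins = (HapOrigin(self.origins[0]), HapOrigin(self.origins[1]))
        if (self.origins[0] is not HapOrigin.unknown
                and self.origins[0] is self.origins[1]):
            raise ValueError("the two haplotypes cannot share a known origin")


@dataclass
class PhasedGenotypes:
    """Phased haplotypes for a set of individuals over one marker map."""

    marker_map: MarkerMap
    data: dict[str, HaplotypePair]

    def __post_init__(self) -> None:
        n = len(self.marker_map)
        for ind, pair in self.data.items():
            if pair.alleles.shape[1] != n:
                raise ValueError(
                    f"{ind}: haplotype length {pair.alleles.shape[1]} "
                    f"!= marker map length {n}")

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.data

    def haplotype(self, ind_id: str, slot: int) -> np.ndarray:
        return self.data[ind_id].alleles[slot]


@dataclass
class SharedSegment:
    """Maximal haplotype segment shared by the carrier haplotypes."""

    chrom: str
    start_pos: int
    end_pos: int
    members: frozenset[tuple[str, int]]  # (individual id, haplotype slot)
    start_index: int
    end_index: int
    focal_index: int

    def __post_init__(self) -> None:
        if not self.start_pos <= self.end_pos:
            raise ValueError("segment start must not exceed end")

    @property
    def length(self) -> int:
        return self.end_pos - self.start_pos + 1

    def to_bed_line(self, name: str = "shared_segment") -> str:
        """0-based half-open BED representation."""
        return f"{self.chrom}\t{self.start_pos - 1}\t{self.end_pos}\t{name}"


class OriginMode(str, Enum):
    de_novo_germline_mosaic = "de_novo_germline_mosaic"
    de_novo_full_heterozygote = "de_novo_full_heterozygote"
    inherited_unresolved = "inherited_unresolved"
    ambiguous = "ambiguous"


@dataclass
class OriginInference:
    originating_individual: str | None
    mode: OriginMode
    evidence: list[str]


@dataclass
class TransmissionPath:
    """Per-member haplotype origins and the parent->child transmission chain."""

    member_slots: dict[str, int]
    origins: dict[str, HapOrigin]
    edges: list[tuple[str, str]]
    topmost: str | None


# ---------------------------------------------------------------------------
# segment finding


def _member_slot(phased: PhasedGenotypes, ind_id: str) -> int:
    """Slot of the haplotype carrying the focal alternate allele."""
    focal = phased.marker_map.focal_index
    pair = phased.data[ind_id]
    slots = [s for s in (0, 1) if pair.alleles[s, focal] == 1]
    if not slots:
        raise ValueError(
            f"carrier {ind_id} has no haplotype with the focal alternate allele"
        )
    return slots[0]


def shared_segment(
    phased: PhasedGenotypes,
    carriers: Iterable[str],
    marker_map: MarkerMap | None = None,
    max_missing_run: int = 10,
) -> SharedSegment:
    """Maximal segment around the focal site shared by all carrier haplotypes.

    Starting from the focal marker, the segment is extended marker by
    marker while every member haplotype agrees.  Missing alleles act as
    wildcards, but a run of more than ``max_missing_run`` consecutive
    uninformative comparisons stops the extension at the last informative
    marker, so the segment never coasts through a no-call desert.  With a
    single carrier the segment spans the whole map.
    """
    marker_map = marker_map or phased.marker_map
    carriers = sorted(set(carriers))
    if not carriers:
        raise ValueError("carrier set is empty")
    members = frozenset((c, _member_slot(phased, c)) for c in carriers)
    haps = [phased.haplotype(c, s) for c, s in sorted(members)]
    n = len(marker_map)
    focal = marker_map.focal_index

    if len(haps) == 1:
        return SharedSegment(
            chrom=marker_map.chrom,
            start_pos=int(marker_map.positions[0]),
            end_pos=int(marker_map.positions[-1]),
            members=members,
            start_index=0,
            end_index=n - 1,
            focal_index=focal,
        )

    def agree(j: int) -> str:
        values = {int(h[j]) for h in haps if h[j] != MISSING}
        if len(values) > 1:
            return "mismatch"
        informative = sum(1 for h in haps if h[j] != MISSING)
        return "agree" if informative >= 2 else "wildcard"

    def extend(start: int, step: int) -> int:
        last_informative = start
        j = start + step
        missing_run = 0
        while 0 <= j < n:
            status = agree(j)
            if status == "mismatch":
                break
            if status == "agree":
                last_informative = j
                missing_run = 0
            else:
                missing_run += 1
                if missing_run > max_missing_run:
                    break
            j += step
        return last_informative

    if agree(focal) == "mismatch":
        raise ValueError("member haplotypes disagree at the focal marker")
    left = extend(focal, -1)
    right = extend(focal, +1)
    return SharedSegment(
        chrom=marker_map.chrom,
        start_pos=int(marker_map.positions[left]),
        end_pos=int(marker_map.positions[right]),
        members=members,
        start_index=left,
        end_index=right,
        focal_index=focal,
    )


def verify_segment(segment: SharedSegment, phased: PhasedGenotypes) -> bool:
    """Independent re-check that member haplotypes agree inside the segment."""
    haps = [phased.haplotype(c, s) for c, s in sorted(segment.members)]
    for j in range(segment.start_index, segment.end_index + 1):
        values = {int(h[j]) for h in haps if h[j] != MISSING}
        if len(values) > 1:
            return False
    return True


def segment_consensus(segment: SharedSegment, phased: PhasedGenotypes) -> np.ndarray:
    """Consensus allele per marker inside the segment (MISSING where uninformative)."""
    haps = [phased.haplotype(c, s) for c, s in sorted(segment.members)]
    width = segment.end_index - segment.start_index + 1
    consensus = np.full(width, MISSING, dtype=np.int8)
    for offset, j in enumerate(range(segment.start_index, segment.end_index + 1)):
        values = {int(h[j]) for h in haps if h[j] != MISSING}
        if len(values) == 1:
            consensus[offset] = values.pop()
    return consensus


# ---------------------------------------------------------------------------
# transmission tracing


def trace_parental_origin(
    segment: SharedSegment,
    pedigree: Pedigree,
    phased: PhasedGenotypes,
) -> TransmissionPath:
    """Parental origins of member haplotypes and the transmission chain.

    An edge parent -> child is recorded when both are segment members and
    the child's member haplotype is labelled as coming from that parent
    (or, with an unknown label, when exactly one parent is a member).
    Members must be connected through the pedigree; the *topmost* member
    is the single member with no member parent.  Two or more equally
    senior members leave the topmost undetermined (never guessed).
    """
    member_slots = {c: s for c, s in segment.members}
    member_ids = sorted(member_slots)
    origins = {
        c: phased.data[c].origins[member_slots[c]] for c in member_ids
    }
    # connectivity through the full pedigree graph
    disconnected = [
        b for b in member_ids[1:] if not pedigree.related(member_ids[0], b)
    ]
    if disconnected:
        raise ValueError(
            f"segment members not connected in the pedigree: "
            f"{{{member_ids[0]}}} vs {sorted(disconnected)}"
        )

    edges: list[tuple[str, str]] = []
    for child in member_ids:
        ind = pedigree.members[child]
        origin = origins[child]
        if origin is HapOrigin.paternal:
            candidates = [ind.father_id]
        elif origin is HapOrigin.maternal:
            candidates = [ind.mother_id]
        else:
            candidates = [p for p in (ind.father_id, ind.mother_id)
                          if p in member_slots]
        for parent in candidates:
            if parent is not None and parent in member_slots:
                edges.append((parent, child))

    children_with_member_parent = {child for _, child in edges}
    roots = [c for c in member_ids if c not in children_with_member_parent]
    topmost = roots[0] if len(roots) == 1 else None
    return TransmissionPath(
        member_slots=member_slots,
        origins=origins,
        edges=sorted(edges),
        topmost=topmost,
    )


def detect_discordant_sharers(
    segment: SharedSegment,
    phased: PhasedGenotypes,
    carrier_states: Mapping[str, CarrierState],
    relatives: Iterable[str],
) -> set[str]:
    """Non-carrier relatives sharing the segment's haplotype background.

    A relative is a discordant sharer when one of their haplotypes matches
    the segment consensus at every informative marker inside the segment
    *except the focal variant site itself* (which a discordant sharer by
    definition lacks) and their carrier state is non-carrier.
    """
    consensus = segment_consensus(segment, phased)
    member_ids = {c for c, _ in segment.members}
    discordant: set[str] = set()
    for rel in relatives:
        if rel in member_ids or rel not in phased:
            continue
        state = carrier_states.get(rel)
        if state is None or state.state is not State.non_carrier:
            continue
        for slot in (0, 1):
            hap = phased.haplotype(rel, slot)
            ok = True
            for offset, j in enumerate(
                    range(segment.start_index, segment.end_index + 1)):
                if j == segment.focal_index:
                    continue
                a, b = int(consensus[offset]), int(hap[j])
                if a != MISSING and b != MISSING and a != b:
                    ok = False
                    break
            if ok:
                discordant.add(rel)
                break
    return discordant


# ---------------------------------------------------------------------------
# origin inference


def _lineage_of(pedigree: Pedigree, topmost: str, origin: HapOrigin) -> set[str] | None:
    """Individuals on the grandparental lineage of the topmost carrier's
    variant-bearing haplotype: the labelled parent plus that parent's
    ancestors and descendants.  None when the origin label is unknown."""
    ind = pedigree.members[topmost]
    if origin is HapOrigin.maternal:
        parent = ind.mother_id
    elif origin is HapOrigin.paternal:
        parent = ind.father_id
    else:
        return None
    if parent is None or parent not in pedigree.members:
        return None
    lineage = {parent}
    lineage |= pedigree.ancestors(parent)
    lineage |= pedigree.descendants(parent)
    lineage.discard(topmost)
    return lineage


def infer_origin(
    pedigree: Pedigree,
    carrier_states: Mapping[str, CarrierState],
    segment: SharedSegment,
    discordant: set[str],
    path: TransmissionPath,
) -> OriginInference:
    """Infer the variant's originating individual and mode.

    Decision rules, evaluated in order for the topmost carrier T:

    1. T is a mosaic candidate and a discordant sharer lies on the
       lineage of T's variant-bearing haplotype -> the haplotype predates
       the variant: de novo germline+somatic mosaic in T.
    2. T is an ordinary heterozygote and a discordant sharer exists ->
       de novo constitutional mutation in T.
    3. T is heterozygous, no discordant sharer, and T's parents are
       untyped -> inherited or arising at/above T, unresolved.
    4. Otherwise ambiguous.
    """
    evidence: list[str] = []
    T = path.topmost
    if T is None:
        evidence.append(
            "no single topmost carrier: members do not form one lineage")
        return OriginInference(None, OriginMode.ambiguous, evidence)

    t_state = carrier_states.get(T)
    t_state_value = t_state.state if t_state is not None else None
    evidence.append(f"topmost carrier {T} with state "
                    f"{t_state_value.value if t_state_value else 'untyped'}")
    origin_label = path.origins.get(T, HapOrigin.unknown)
    evidence.append(f"{T}'s variant haplotype origin: {origin_label.value}")

    lineage = _lineage_of(pedigree, T, origin_label)
    if lineage is None:
        # unknown label or untyped parent: fall back to pedigree relatedness
        lineage_sharers = {d for d in discordant if pedigree.related(T, d)}
    else:
        lineage_sharers = discordant & lineage
    if discordant:
        evidence.append(f"discordant sharers: {sorted(discordant)}; "
                        f"on the variant lineage: {sorted(lineage_sharers)}")
    else:
        evidence.append("no discordant sharers detected")

    # rule 1
    if t_state_value is State.mosaic_candidate and lineage_sharers:
        evidence.append(
            f"rule 1: haplotype predates the variant (shared without it by "
            f"{sorted(lineage_sharers)}) and {T} shows allelic imbalance "
            f"-> early de novo mutation, germline+somatic mosaic in {T}")
        return OriginInference(T, OriginMode.de_novo_germline_mosaic, evidence)
    evidence.append("rule 1 not met")

    # rule 2
    if t_state_value is State.heterozygous and discordant:
        evidence.append(
            f"rule 2: haplotype shared without the variant, {T} fully "
            f"heterozygous -> constitutional de novo mutation in {T}")
        return OriginInference(T, OriginMode.de_novo_full_heterozygote, evidence)
    evidence.append("rule 2 not met")

    # rule 3
    parents = pedigree.parents(T)
    parents_untyped = all(p not in carrier_states for p in parents) or not parents
    if t_state_value is State.heterozygous and not discordant and parents_untyped:
        evidence.append(
            f"rule 3: no discordant sharer and {T}'s parents untyped -> "
            f"variant inherited or arising at/above {T}, unresolved")
        return OriginInference(T, OriginMode.inherited_unresolved, evidence)
    evidence.append("rule 3 not met; inference ambiguous")
    return OriginInference(None, OriginMode.ambiguous, evidence)


# ---------------------------------------------------------------------------
# file formats


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (family, id, father, mother, sex, phenotype)."""
    members: dict[str, Individual] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{path}:{i}: PED line needs 6 columns")
        _, ind_id, father, mother, sex, _ = fields[:6]
        members[ind_id] = Individual(
            id=ind_id,
            sex={"1": Sex.male, "2": Sex.female}.get(sex, Sex.unknown),
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            generation_label=ind_id,
        )
    return Pedigree(members)


def write_ped(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    lines = []
    for ind in pedigree.members.values():
        sex = {Sex.male: "1", Sex.female: "2"}.get(ind.sex, "0")
        lines.append("\t".join([
            family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
            sex, "0",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_haplotypes_tsv(phased: PhasedGenotypes, path: str | Path) -> None:
    """Write phased haplotypes: individual, slot, origin, then one column per marker."""
    marker_cols = [f"m{p}" for p in phased.marker_map.positions]
    rows = []
    for ind, pair in phased.data.items():
        for slot in (0, 1):
            row = {"individual": ind, "haplotype_slot": slot,
                   "parental_origin": pair.origins[slot].value}
            row.update(zip(marker_cols, pair.alleles[slot].tolist()))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_haplotypes_tsv(path: str | Path, chrom: str, focal_pos: int) -> PhasedGenotypes:
    """Re-read a haplotype TSV written by :func:`write_haplotypes_tsv`."""
    df = pd.read_csv(path, sep="\t")
    marker_cols = [c for c in df.columns if c.startswith("m") and c[1:].isdigit()]
    positions = np.array([int(c[1:]) for c in marker_cols])
    order = np.argsort(positions)
    positions = positions[order]
    marker_cols = [marker_cols[i] for i in order]
    focal_index = int(np.searchsorted(positions, focal_pos))
    if focal_index >= len(positions) or positions[focal_index] != focal_pos:
        raise ValueError(f"focal position {focal_pos} is not a marker")
    marker_map = MarkerMap(chrom, positions, focal_index)
    data: dict[str, HaplotypePair] = {}
    for ind, group in df.groupby("individual", sort=False):
        group = group.sort_values("haplotype_slot")
        alleles = group[marker_cols].to_numpy(dtype=np.int8)
        origins = tuple(HapOrigin(o) for o in group["parental_origin"])
        data[str(ind)] = HaplotypePair(alleles, origins)  # type: ignore[arg-type]
    return PhasedGenotypes(marker_map, data)
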