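"""Shared-segment finding, transmission tracing and origin inference."""

import numpy as np
import pytest

from mhscreen.haplotype_tracing import (
    HapOrigin,
    HaplotypePair,
    Individual,
    MarkerMap,
    OriginMode,
    Pedigree,
    PhasedGenotypes,
    Sex,
    detect_discordant_sharers,
    infer_origin,
    read_ped,
    segment_consensus,
    shared_segment,
    trace_parental_origin,
    verify_segment,
    write_ped,
)
from mhscreen.mosaicism import (
    AllelicDepth,
    CarrierState,
    Genotype,
    State,
    classify_carrier_state,
)
from mhscreen.synthetic_data import SimConfig, drop_haplotypes, plant_mutation


def tiny_map(n=9, focal=4):
    return MarkerMap("chr19", np.arange(1, n + 1) * 1000, focal)


def pair(hap0, hap1, origins=(HapOrigin.unknown, HapOrigin.unknown)):
    return HaplotypePair(np.array([hap0, hap1], dtype=np.int8), origins)


def phased_from(haps, marker_map=None):
    return PhasedGenotypes(marker_map or tiny_map(), haps)


def carrier_hap(marker_map, background=0):
    hap = np.full(len(marker_map), background, dtype=np.int8)
    hap[marker_map.focal_index] = 1
    return hap


class TestSharedSegment:
    def test_identical_haplotypes_span_full_map(self):
        m = tiny_map()
        hap = carrier_hap(m)
        phased = phased_from({
            "A": pair(hap, np.zeros(9)), "B": pair(np.zeros(9), hap)}, m)
        seg = shared_segment(phased, {"A", "B"})
        assert (seg.start_pos, seg.end_pos) == (1000, 9000)
        assert seg.members == {("A", 0), ("B", 1)}

    def test_disagreement_at_flanks_gives_minimal_segment(self):
        m = tiny_map()
        a = carrier_hap(m)
        b = carrier_hap(m)
        for j in (m.focal_index - 1, m.focal_index + 1):
            b[j] = 1 - b[j]
        phased = phased_from({"A": pair(a, np.zeros(9)),
                              "B": pair(b, np.zeros(9))}, m)
        seg = shared_segment(phased, {"A", "B"})
        assert (seg.start_pos, seg.end_pos) == (m.focal_pos, m.focal_pos)

    def test_single_carrier_spans_full_map(self):
        m = tiny_map()
        phased = phased_from({"A": pair(carrier_hap(m), np.zeros(9))}, m)
        seg = shared_segment(phased, {"A"})
        assert (seg.start_pos, seg.end_pos) == (1000, 9000)

    def test_carrier_without_focal_alt_allele_rejected(self):
        m = tiny_map()
        phased = phased_from({"A": pair(np.zeros(9), np.zeros(9))}, m)
        with pytest.raises(ValueError, match="A"):
            shared_segment(phased, {"A"})

    def test_missing_run_bounds_extension(self):
        m = tiny_map()
        a = carrier_hap(m)
        b = carrier_hap(m).astype(np.int8)
        b[: m.focal_index] = -1  # one haplotype unobserved left of the site
        phased = phased_from({"A": pair(a, np.zeros(9)),
                              "B": pair(b, np.zeros(9))}, m)
        seg = shared_segment(phased, {"A", "B"}, max_missing_run=2)
        # extension left stops at the last informative marker: the focal one
        assert seg.start_pos == m.focal_pos
        assert seg.end_pos == 9000

    def test_planted_transmission_recovered_and_maximal(self, sim_config):
        pedigree = Pedigree({
            "F": Individual("F", Sex.male), "M": Individual("M", Sex.female),
            "C": Individual("C", Sex.male, "F", "M")})
        phased, ledger = drop_haplotypes(pedigree, sim_config)
        plant_mutation(phased, pedigree, "F", "heterozygous", sim_config,
                       ledger, origin_slot=0)
        if "C" not in ledger.true_carriers:
            pytest.skip("variant haplotype not transmitted under this seed")
        seg = shared_segment(phased, {"F", "C"})
        assert verify_segment(seg, phased)
        assert seg.start_pos <= phased.marker_map.focal_pos <= seg.end_pos
        # maximality: one marker beyond either bound breaks agreement
        haps = [phased.haplotype(c, s) for c, s in sorted(seg.members)]
        for j, edge in ((seg.start_index - 1, 0),
                        (seg.end_index + 1, len(phased.marker_map) - 1)):
            if 0 <= j < len(phased.marker_map):
                values = {int(h[j]) for h in haps if h[j] != -1}
                assert len(values) > 1

    def test_adding_member_never_lengthens_segment(self, sim_config):
        m = tiny_map()
        a = carrier_hap(m)
        b = carrier_hap(m)
        c = carrier_hap(m)
        c[0] = 1 - c[0]
        c[-1] = 1 - c[-1]
        phased = phased_from({
            "A": pair(a, np.zeros(9)), "B": pair(b, np.zeros(9)),
            "C": pair(c, np.zeros(9))}, m)
        seg_two = shared_segment(phased, {"A", "B"})
        seg_three = shared_segment(phased, {"A", "B", "C"})
        assert seg_three.length <= seg_two.length


def index_family_states(fam):
    return {i: classify_carrier_state(fam.genotypes[i], fam.depths[i])
            for i in fam.depths}


class TestTraceAndInfer:
    def test_index_family_chain_and_origins(self, index_family):
        seg = shared_segment(index_family.phased, index_family.carriers)
        path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
        assert path.topmost == "II-5"
        assert path.origins["II-5"] is HapOrigin.maternal
        assert sorted(path.edges) == [
            ("II-5", "III-5"), ("III-5", "IV-1"), ("III-5", "IV-4")]

    def test_single_carrier_path(self, index_family):
        seg = shared_segment(index_family.phased, {"IV-4"})
        path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
        assert path.topmost == "IV-4"
        assert path.edges == []
        assert path.origins["IV-4"] is HapOrigin.paternal

    def test_unrelated_member_raises(self, index_family):
        m = index_family.phased.marker_map
        hap = carrier_hap(m)
        data = dict(index_family.phased.data)
        data["STRANGER"] = pair(hap, np.zeros(len(m)))
        phased = PhasedGenotypes(m, data)
        pedigree = Pedigree({**index_family.pedigree.members,
                             "STRANGER": Individual("STRANGER")})
        seg = shared_segment(phased, index_family.carriers | {"STRANGER"})
        with pytest.raises(ValueError, match="not connected"):
            trace_parental_origin(seg, pedigree, phased)

    def test_index_family_discordant_sharer(self, index_family):
        seg = shared_segment(index_family.phased, index_family.carriers)
        states = index_family_states(index_family)
        relatives = set(index_family.depths) - index_family.carriers
        assert detect_discordant_sharers(
            seg, index_family.phased, states, relatives) == {"II-2"}

    def test_no_discordant_sharers_when_none_share(self, index_family):
        seg = shared_segment(index_family.phased, index_family.carriers)
        states = index_family_states(index_family)
        assert detect_discordant_sharers(
            seg, index_family.phased, states, {"III-4", "III-6"}) == set()

    def test_index_family_origin_inference(self, index_family):
        seg = shared_segment(index_family.phased, index_family.carriers)
        states = index_family_states(index_family)
        path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
        discordant = detect_discordant_sharers(
            seg, index_family.phased, states, set(index_family.depths) - index_family.carriers)
        inference = infer_origin(index_family.pedigree, states, seg, discordant, path)
        assert inference.originating_individual == "II-5"
        assert inference.mode is OriginMode.de_novo_germline_mosaic
        assert any("rule 1" in e for e in inference.evidence)

    def test_balanced_topmost_with_untyped_sister_unresolved(self, index_family):
        seg = shared_segment(index_family.phased, index_family.carriers)
        states = index_family_states(index_family)
        # counterfactual: II-5 balanced heterozygous, II-2 untyped
        states["II-5"] = classify_carrier_state(
            Genotype.het, AllelicDepth("II-5", 15, 14))
        del states["II-2"]
        path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
        inference = infer_origin(index_family.pedigree, states, seg, set(), path)
        assert inference.mode is OriginMode.inherited_unresolved

    def test_sibling_carriers_without_parent_are_ambiguous(self, index_family):
        # only the two half-siblings typed as carriers: no single lineage top
        seg = shared_segment(index_family.phased, {"IV-1", "IV-4"})
        states = index_family_states(index_family)
        path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
        assert path.topmost is None
        inference = infer_origin(index_family.pedigree, states, seg, set(), path)
        assert inference.mode is OriginMode.ambiguous

    def test_inference_deterministic_under_member_permutation(self, index_family):
        states = index_family_states(index_family)
        results = []
        for carriers in (sorted(index_family.carriers), sorted(index_family.carriers)[::-1]):
            seg = shared_segment(index_family.phased, carriers)
            path = trace_parental_origin(seg, index_family.pedigree, index_family.phased)
            discordant = detect_discordant_sharers(
                seg, index_family.phased, states, set(index_family.depths) - index_family.carriers)
            inference = infer_origin(index_family.pedigree, states, seg, discordant, path)
            results.append((inference.originating_individual, inference.mode,
                            seg.start_pos, seg.end_pos))
        assert results[0] == results[1]


class TestPedigreeValidation:
    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="ancestor"):
            Pedigree({
                "A": Individual("A", Sex.male, father_id="B"),
                "B": Individual("B", Sex.male, father_id="A"),
            })

    def test_parent_sex_checked(self):
        with pytest.raises(ValueError, match="sex"):
            Pedigree({
                "A": Individual("A", Sex.female),
                "B": Individual("B", Sex.male, father_id="A"),
            })

    def test_ped_round_trip(self, index_family, tmp_path):
        path = tmp_path / "fam.ped"
        write_ped(index_family.pedigree, path)
        back = read_ped(path)
        assert set(back.members) == set(index_family.pedigree.members)
        for ind_id, ind in index_family.pedigree.members.items():
            assert back.members[ind_id].father_id == ind.father_id
            assert back.members[ind_id].mother_id == ind.mother_id
            assert back.members[ind_id].sex == ind.sex


def test_segment_consensus_marks_uninformative_markers(index_family):
    seg = shared_segment(index_family.phased, index_family.carriers)
    consensus = segment_consensus(seg, index_family.phased)
    assert consensus[seg.focal_index - seg.start_index] == 1
    assert set(np.unique(consensus)) <= {-1, 0, 1}
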