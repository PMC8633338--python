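"""Determinism, conservation and sampling-model checks for the generator."""

import numpy as np
import pytest

from mhscreen.haplotype_tracing import HapOrigin
from mhscreen.synthetic_data import (
    SimConfig,
    Transmission,
    drop_haplotypes,
    index_family,
    index_family_pedigree,
    gen_cohort,
    gen_pedigree,
    plant_mutation,
    sim_reads,
)


class TestGenPedigree:
    def test_two_generations_one_child_is_a_trio(self):
        pedigree = gen_pedigree(SimConfig(seed=1, n_generations=2,
                                          children_per_couple=1))
        assert len(pedigree.members) == 3
        child = [m for m in pedigree.members.values()
                 if m.father_id is not None]
        assert len(child) == 1

    def test_fixed_seed_reproducible(self):
        a = gen_pedigree(SimConfig(seed=3))
        b = gen_pedigree(SimConfig(seed=3))
        assert {(m.id, m.sex, m.father_id, m.mother_id)
                for m in a.members.values()} == \
               {(m.id, m.sex, m.father_id, m.mother_id)
                for m in b.members.values()}

    def test_index_family_preset_topology(self):
        pedigree = index_family_pedigree()
        assert len(pedigree.members) == 16
        for required in ("II-2", "II-5", "III-5", "IV-1", "IV-4"):
            assert required in pedigree.members
        # II-2 and II-5 are sisters; IV-1 and IV-4 are paternal half-siblings
        assert pedigree.members["II-2"].mother_id == \
            pedigree.members["II-5"].mother_id
        assert pedigree.members["IV-1"].father_id == "III-5"
        assert pedigree.members["IV-4"].father_id == "III-5"
        assert pedigree.members["IV-1"].mother_id != \
            pedigree.members["IV-4"].mother_id


class TestDropHaplotypes:
    def test_no_recombination_transmits_intact_haplotypes(self):
        config = SimConfig(seed=2, recomb_rate=0.0, n_generations=2,
                           children_per_couple=2)
        pedigree = gen_pedigree(config)
        phased, ledger = drop_haplotypes(pedigree, config)
        for (child, side), trans in ledger.transmissions.items():
            assert trans.breakpoints == []
            parent_id = (pedigree.members[child].father_id if side == "paternal"
                         else pedigree.members[child].mother_id)
            slot = 0 if side == "paternal" else 1
            parent_hap = phased.data[parent_id].alleles[trans.start_slot]
            np.testing.assert_array_equal(
                phased.data[child].alleles[slot], parent_hap)

    def test_child_haplotype_is_parental_mosaic_at_ledger_breakpoints(self):
        config = SimConfig(seed=4, recomb_rate=3.0, n_generations=2)
        pedigree = gen_pedigree(config)
        phased, ledger = drop_haplotypes(pedigree, config)
        positions = phased.marker_map.positions
        for (child, side), trans in ledger.transmissions.items():
            parent_id = (pedigree.members[child].father_id if side == "paternal"
                         else pedigree.members[child].mother_id)
            slot = 0 if side == "paternal" else 1
            expected = np.array([
                phased.data[parent_id].alleles[trans.source_slot_at(int(p)), j]
                for j, p in enumerate(positions)])
            np.testing.assert_array_equal(
                phased.data[child].alleles[slot], expected)

    def test_crossover_count_mean_matches_rate(self):
        config = SimConfig(seed=6, recomb_rate=1.0, n_generations=2,
                           children_per_couple=500)
        pedigree = gen_pedigree(config)
        _, ledger = drop_haplotypes(pedigree, config)
        counts = [len(t.breakpoints) for t in ledger.transmissions.values()]
        assert len(counts) == 1000
        se = np.sqrt(1.0 / len(counts))
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_everyone_has_two_haplotypes_with_origin_labels(self):
        config = SimConfig(seed=8)
        pedigree = gen_pedigree(config)
        phased, _ = drop_haplotypes(pedigree, config)
        assert set(phased.data) == set(pedigree.members)
        for ind_id, hap_pair in phased.data.items():
            assert hap_pair.alleles.shape[0] == 2
            if pedigree.members[ind_id].father_id is not None:
                assert hap_pair.origins == (HapOrigin.paternal,
                                            HapOrigin.maternal)

    def test_fixed_seed_byte_identical(self):
        config = SimConfig(seed=9)
        pedigree = gen_pedigree(config)
        a, _ = drop_haplotypes(pedigree, config)
        b, _ = drop_haplotypes(pedigree, config)
        for ind in a.data:
            np.testing.assert_array_equal(a.data[ind].alleles,
                                          b.data[ind].alleles)


class TestPlantMutation:
    def family(self, seed, **kwargs):
        config = SimConfig(seed=seed, n_generations=3,
                           children_per_couple=2, **kwargs)
        pedigree = gen_pedigree(config)
        phased, ledger = drop_haplotypes(pedigree, config)
        return config, pedigree, phased, ledger

    def test_heterozygous_origin_every_inheritor_carries(self):
        config, pedigree, phased, ledger = self.family(10)
        plant_mutation(phased, pedigree, "I-2", "heterozygous", config, ledger,
                       origin_slot=0)
        assert ledger.background_sharers == set()
        focal = phased.marker_map.focal_index
        for ind_id in pedigree.members:
            has_alt = bool(np.any(phased.data[ind_id].alleles[:, focal] == 1))
            assert has_alt == (ind_id in ledger.true_carriers)

    def test_mosaic_with_zero_germline_fraction_never_transmits(self):
        config, pedigree, phased, ledger = self.family(
            11, germline_transmission_fraction=0.0)
        plant_mutation(phased, pedigree, "I-2", "mosaic", config, ledger,
                       origin_slot=0)
        assert ledger.true_carriers == {"I-2"}

    def test_germline_transmission_fraction_calibrated(self):
        # many replicate families: carrier fraction among background
        # inheritors of a mosaic origin ~ germline_transmission_fraction
        transmitted = inherited = 0
        for rep in range(400):
            config, pedigree, phased, ledger = self.family(
                20_000 + rep, germline_transmission_fraction=0.5)
            plant_mutation(phased, pedigree, "I-2", "mosaic", config, ledger,
                           origin_slot=0)
            children = pedigree.children("I-2")
            hits = [c for c in children if c in ledger.true_carriers]
            misses = [c for c in children if c in ledger.background_sharers]
            transmitted += len(hits)
            inherited += len(hits) + len(misses)
        assert inherited > 100
        se = np.sqrt(0.25 / inherited)
        assert abs(transmitted / inherited - 0.5) < 3 * se

    def test_origin_not_in_pedigree_rejected(self):
        config, pedigree, phased, ledger = self.family(12)
        with pytest.raises(ValueError):
            plant_mutation(phased, pedigree, "nobody", "mosaic", config, ledger)


class TestSimReads:
    def test_zero_depth_mean(self):
        config = SimConfig(seed=1, depth_mean=0.0)
        depth = sim_reads("heterozygous", config, config.rng("t"))
        assert (depth.ref_reads, depth.alt_reads) == (0, 0)

    def test_heterozygous_ratio_centred_at_half(self):
        config = SimConfig(seed=2, depth_mean=30.0)
        rng = config.rng("het-mc")
        ratios = []
        for _ in range(10_000):
            d = sim_reads("heterozygous", config, rng)
            if d.total:
                ratios.append(d.alt_reads / d.total)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.5) < 3 * se

    def test_mosaic_ratio_matches_half_cell_fraction(self):
        # m = 0.42 reproduces the skewed-carrier regime (expected ratio 0.21)
        config = SimConfig(seed=3, depth_mean=30.0, mosaic_cell_fraction=0.42)
        rng = config.rng("mosaic-mc")
        ratios = []
        for _ in range(10_000):
            d = sim_reads("mosaic", config, rng)
            if d.total:
                ratios.append(d.alt_reads / d.total)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.21) < 3 * se


class TestGenCohort:
    def test_fixed_seed_byte_identical_outputs(self):
        config = SimConfig(seed=13, cohort_size=150, n_variants=25)
        a = gen_cohort(config)
        b = gen_cohort(config)
        assert a.vcf_text == b.vcf_text
        assert a.classification_rows.equals(b.classification_rows)

    def test_vcf_allele_counts_match_ledger(self):
        config = SimConfig(seed=14, cohort_size=150, n_variants=25)
        sim = gen_cohort(config)
        body = [l for l in sim.vcf_text.splitlines() if not l.startswith("#")]
        assert len(body) == 25
        by_pos = {int(l.split("\t")[1]): l.split("\t")[9:] for l in body}
        for v in sim.ledger.cohort_variants:
            gts = by_pos[v["pos"]]
            ac = sum(g.count("1") for g in gts)
            an = sum(2 - g.count(".") for g in gts)
            assert ac == v["allele_count"]
            assert an == v["allele_number"]

    def test_ground_truth_not_leaked_into_files(self):
        sim = gen_cohort(SimConfig(seed=15, cohort_size=50, n_variants=10))
        for text in (sim.vcf_text,
                     sim.classification_rows.to_csv(sep="\t")):
            assert "actionable" not in text
            assert "ledger" not in text

    def test_vus_only_mix_yields_empty_actionable_sets(self):
        config = SimConfig(seed=16, cohort_size=50, n_variants=10,
                           classification_mix=({"uncertain": 2},))
        sim = gen_cohort(config)
        assert not any(v["actionable_majority"] or v["actionable_strict"]
                       for v in sim.ledger.cohort_variants)

    def test_majority_conflict_profile_truth(self):
        config = SimConfig(seed=17, cohort_size=50, n_variants=16,
                           classified_fraction=1.0)
        sim = gen_cohort(config)
        profiles = {str(v["profile"]): v for v in sim.ledger.cohort_variants}
        v = profiles[str({"pathogenic": 10, "likely_benign": 1})]
        assert v["actionable_majority"] and not v["actionable_strict"]
        assert v["verdict_strict"] == "conflicting_excluded"


def test_index_family_deterministic_and_consistent():
    a = index_family()
    b = index_family()
    for ind in a.phased.data:
        np.testing.assert_array_equal(a.phased.data[ind].alleles,
                                      b.phased.data[ind].alleles)
    focal = a.phased.marker_map.focal_index
    for ind, hap_pair in a.phased.data.items():
        has_alt = bool(np.any(hap_pair.alleles[:, focal] == 1))
        assert has_alt == (ind in a.carriers)
    assert a.phased.marker_map.focal_pos == 38_496_455
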