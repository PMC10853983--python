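"""Synthetic-genome generators: determinism, planted structure, truth consistency."""

import numpy as np
import pytest

from cassfinder.seqtypes import Interval
from cassfinder.simulate import (
    CassandraSpec,
    FiveSUnitSpec,
    PlacementError,
    RdnaArraySpec,
    SpecError,
    make_5s_unit,
    make_cassandra,
    make_cassandra_like_trim,
    make_rdna_array,
    mutate,
    plant_elements,
    rdna_references,
    simulate_reads,
)


class TestFiveSUnit:
    @pytest.mark.parametrize(
        "variant,motif",
        [
            ("canonical", "AGGATGGGTG"),
            ("anthemideae_rdna", "GGCTTGGGTG"),
            ("anthemideae_cassandra", "GGCCTGGGTG"),
        ],
    )
    def test_cbox_slice_matches_variant(self, variant, motif):
        spec = FiveSUnitSpec(cbox_variant=variant)
        unit, _ = make_5s_unit(spec, 3)
        assert unit.residues[spec.cbox.start : spec.cbox.end] == motif

    def test_boxes_at_configured_offsets(self, unit_spec):
        unit, truth = make_5s_unit(unit_spec, 3)
        assert unit.residues[unit_spec.abox.start : unit_spec.abox.end] == unit_spec.abox_seq
        assert unit.residues[unit_spec.ie.start : unit_spec.ie.end] == unit_spec.ie_seq

    def test_deterministic(self, unit_spec):
        a, _ = make_5s_unit(unit_spec, 9)
        b, _ = make_5s_unit(unit_spec, 9)
        assert a.residues == b.residues

    def test_bad_offsets_rejected(self):
        with pytest.raises(SpecError):
            FiveSUnitSpec(gene_length=80)  # C-Box would exceed the gene


class TestCassandra:
    def test_zero_divergence_ltrs_identical(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        iv5 = el.truth[1].interval
        iv3 = el.truth[2].interval
        assert el.record.residues[iv5.start : iv5.end] == el.record.residues[iv3.start : iv3.end]

    def test_core_length_default_70(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        core = next(t for t in el.truth if t.feature_type == "region")
        assert core.interval.length() == 70

    def test_core_not_touching_termini(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        core = next(t for t in el.truth if t.feature_type == "region")
        ltr5 = el.truth[1].interval
        assert core.interval.start > ltr5.start
        assert core.interval.end < ltr5.end

    def test_mimicry_variant_cbox(self, shifted_gene):
        spec = CassandraSpec(cbox_variant="anthemideae_cassandra")
        el = make_cassandra(spec, shifted_gene, 5)
        assert "GGCCTGGGTG" in el.record.residues

    def test_core_touching_terminus_rejected(self, gene):
        spec = CassandraSpec(ltr_length=70, core_offset_fraction=0.5)
        with pytest.raises(SpecError, match="terminus"):
            make_cassandra(spec, gene, 1)

    def test_pbs_ppt_positions(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        pbs = next(t for t in el.truth if t.feature_type == "primer_binding_site")
        ltr5 = el.truth[1].interval
        assert pbs.interval.start == ltr5.end
        ppt = next(t for t in el.truth if t.feature_type == "RR_tract")
        ltr3 = el.truth[2].interval
        assert ppt.interval.end == ltr3.start


class TestCassandraLikeTrim:
    def test_tata_at_48(self):
        el = make_cassandra_like_trim(CassandraSpec(ltr_length=100), 3)
        assert el.record.residues[48:54] == "TATAAA"

    def test_short_ltr_rejected(self):
        with pytest.raises(SpecError, match="TATA"):
            make_cassandra_like_trim(CassandraSpec(ltr_length=50), 3)

    def test_no_5s_similarity(self, gene):
        from cassfinder.align import local_align

        el = make_cassandra_like_trim(CassandraSpec(ltr_length=200), 3)
        ltr = el.record.residues[:200]
        assert local_align(ltr, gene, min_score=40) is None

    def test_zero_divergence_ltr_identity(self):
        el = make_cassandra_like_trim(CassandraSpec(ltr_length=120, internal_length=60), 3)
        iv5, iv3 = el.truth[1].interval, el.truth[2].interval
        assert el.record.residues[iv5.start : iv5.end] == el.record.residues[iv3.start : iv3.end]


class TestPlantElements:
    def test_tsd_duplicated_flanks(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        genome, truth = plant_elements(10000, [el], 13)
        element = next(t for t in truth if t.feature_type == "LTR_retrotransposon")
        t = el.tsd_length
        s, e = element.interval.start, element.interval.end
        assert genome.residues[s - t : s] == genome.residues[e : e + t]

    def test_truth_extraction_reproduces_element(self, cassandra_spec, gene):
        el = make_cassandra(cassandra_spec, gene, 7)
        genome, truth = plant_elements(10000, [el], 13)
        element = next(t for t in truth if t.feature_type == "LTR_retrotransposon")
        assert genome.residues[element.interval.start : element.interval.end] == el.record.residues

    def test_zero_elements_pure_background(self):
        genome, truth = plant_elements(2000, [], 99)
        assert len(genome.residues) == 2000
        assert truth == []

    def test_two_elements_disjoint_truth(self, cassandra_spec, gene):
        els = [make_cassandra(cassandra_spec, gene, s, element_id=f"e{s}") for s in (1, 2)]
        genome, truth = plant_elements(12000, els, 17)
        spans = [t.interval for t in truth if t.feature_type == "LTR_retrotransposon"]
        assert len(spans) == 2
        assert spans[0].overlap(spans[1]) == 0

    def test_overfull_background_rejected(self, cassandra_spec, gene):
        els = [make_cassandra(cassandra_spec, gene, s, element_id=f"e{s}") for s in range(4)]
        with pytest.raises(PlacementError):
            plant_elements(4000, els, 3)


class TestMutate:
    def test_rate_zero_identity(self):
        seq = "ACGT" * 100
        assert mutate(seq, 0.0, 0.0, 5).residues == seq

    def test_substitution_rate_within_binomial_bound(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
        out = mutate(seq, 0.05, 0.0, 12).residues
        mismatches = sum(a != b for a, b in zip(seq, out))
        sd = (0.05 * 0.95 * 10000) ** 0.5
        assert abs(mismatches - 500) <= 3 * sd

    def test_deterministic(self):
        seq = "ACGT" * 50
        assert mutate(seq, 0.1, 0.02, 7).residues == mutate(seq, 0.1, 0.02, 7).residues

    def test_protected_intervals_untouched(self):
        seq = "A" * 200
        out = mutate(seq, 0.5, 0.0, 3, protect=[Interval(50, 60)]).residues
        assert out[50:60] == "A" * 10


class TestSimulateReads:
    def test_read_count_arithmetic(self):
        genome, _ = plant_elements(10000, [], 1)
        reads = simulate_reads(genome, 100, 10, 5)
        assert len(reads) == 1000

    def test_reads_are_exact_substrings(self):
        genome, _ = plant_elements(5000, [], 2)
        for read in simulate_reads(genome, 80, 2, 9):
            assert read.residues in genome.residues

    def test_zero_coverage_empty(self):
        genome, _ = plant_elements(1000, [], 3)
        assert simulate_reads(genome, 100, 0, 4) == []


class TestRdnaArray:
    SPEC = RdnaArraySpec(len_18s=400, len_58s=80, len_26s=600, spacer_length=300)

    def test_linked_5s_inside_monomers(self):
        records, truth = make_rdna_array(self.SPEC, 5, True, 21)
        assert len(records) == 1
        monomers = [t.interval for t in truth if t.feature_type == "rDNA_monomer"]
        genes = [t.interval for t in truth if t.feature_type == "gene"]
        assert len(genes) == 5
        for g in genes:
            assert any(m.contains(g) for m in monomers)

    def test_separated_no_5s_in_monomers(self):
        records, truth = make_rdna_array(self.SPEC, 5, False, 21)
        assert len(records) == 2
        by_contig = {}
        for t in truth:
            by_contig.setdefault(t.contig_id, []).append(t)
        genes = [t for t in truth if t.feature_type == "gene"]
        monomers = [t for t in truth if t.feature_type == "rDNA_monomer"]
        assert {g.contig_id for g in genes}.isdisjoint({m.contig_id for m in monomers})

    def test_total_length_multiple_of_monomer(self):
        records, truth = make_rdna_array(self.SPEC, 4, True, 21)
        monomer = next(t.interval for t in truth if t.feature_type == "rDNA_monomer")
        assert len(records[0].residues) == 4 * monomer.length()

    def test_single_copy_rejected(self):
        with pytest.raises(SpecError):
            make_rdna_array(self.SPEC, 1, True, 21)

    def test_references_match_array_content(self):
        records, _ = make_rdna_array(self.SPEC, 3, True, 33)
        refs = rdna_references(self.SPEC, 33)
        for name in ("18S", "5.8S", "26S", "5S"):
            assert refs[name].residues in records[0].residues
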