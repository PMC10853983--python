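"""Structural TRIM detector: planted truth, brute-force oracle, evidence motifs."""

import numpy as np
import pytest

from cassfinder.detect import DetectorConfig, detect_pbs, detect_ppt, detect_tsd, find_ltr_pairs
from cassfinder.seqtypes import Interval, SequenceRecord
from cassfinder.simulate import CassandraSpec, make_cassandra, plant_elements, random_dna

from oracles import oracle_ltr_pairs, oracle_resolve


def _random_record(length, seed, name="r"):
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=name, residues=random_dna(length, rng))


class TestFindLtrPairs:
    def test_planted_element_recovered_exactly(self, gene):
        spec = CassandraSpec(ltr_length=200, internal_length=100, divergence=0.0)
        el = make_cassandra(spec, gene, 7)
        genome, truth = plant_elements(3000, [el], 13, min_separation=0)
        cands = find_ltr_pairs(genome)
        truth_el = next(t for t in truth if t.feature_type == "LTR_retrotransposon")
        assert len(cands) == 1
        assert cands[0].element == truth_el.interval
        assert cands[0].ltr_identity_pct == 100.0

    def test_short_repeats_not_reported(self):
        """25 bp repeat copies sit below the 30 bp LTR minimum."""
        rng = np.random.default_rng(4)
        repeat = random_dna(25, rng)
        seq = random_dna(300, rng) + repeat + random_dna(100, rng) + repeat + random_dna(300, rng)
        cands = find_ltr_pairs(SequenceRecord(id="x", residues=seq))
        assert cands == []

    def test_low_identity_pair_not_reported(self, gene):
        """Copies at ~40% identity fall far below the 70% threshold."""
        rng = np.random.default_rng(8)
        a = random_dna(120, rng)
        b = random_dna(120, rng)  # unrelated: expected identity ~ 25-45%
        seq = random_dna(200, rng) + a + random_dna(100, rng) + b + random_dna(200, rng)
        cands = find_ltr_pairs(SequenceRecord(id="x", residues=seq))
        assert cands == []

    def test_empty_background(self):
        assert find_ltr_pairs(_random_record(2000, 99)) == []

    def test_too_short_sequence_empty(self):
        assert find_ltr_pairs(_random_record(50, 1)) == []

    def test_all_bounds_respected(self, gene):
        """Every reported candidate independently satisfies the config bounds."""
        cfg = DetectorConfig()
        els = [
            make_cassandra(CassandraSpec(ltr_length=100 + 60 * i, internal_length=40 + 20 * i), gene, 50 + i, element_id=f"e{i}")
            for i in range(3)
        ]
        genome, _ = plant_elements(20000, els, 31)
        for c in find_ltr_pairs(genome, cfg):
            assert cfg.min_ltr <= c.ltr5.length() <= cfg.max_ltr
            assert cfg.min_ltr <= c.ltr3.length() <= cfg.max_ltr
            assert cfg.min_between <= c.internal.length() <= cfg.max_between
            assert c.ltr_identity_pct >= cfg.min_ltr_identity
            assert c.ltr5.end <= c.internal.start <= c.internal.end <= c.ltr3.start


ORACLE_CFG = DetectorConfig(max_ltr=150, max_between=400)


class TestOracleEquivalence:
    """Detector output equals the exhaustive all-pair enumeration, after the
    same overlap-resolution rule, on small seeded inputs."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_elements_agree(self, gene, seed):
        spec = CassandraSpec(ltr_length=100, internal_length=80, divergence=0.0)
        el = make_cassandra(spec, gene, 100 + seed)
        genome, _ = plant_elements(1200, [el], 7000 + seed, min_separation=0)
        oracle_spans = oracle_resolve(oracle_ltr_pairs(genome.residues, ORACLE_CFG))
        detected = sorted((c.element.start, c.element.end) for c in find_ltr_pairs(genome, ORACLE_CFG))
        assert detected == oracle_spans

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_plain_background_agrees(self, seed):
        genome = _random_record(1500, seed)
        oracle_spans = oracle_resolve(oracle_ltr_pairs(genome.residues, ORACLE_CFG))
        detected = sorted((c.element.start, c.element.end) for c in find_ltr_pairs(genome, ORACLE_CFG))
        assert detected == oracle_spans == []


class TestSeedSweep:
    def test_perfect_recall_precision_zero_divergence(self, gene):
        """Planted zero-divergence elements are found with no false positives
        across seeded genomes with 0-3 elements each."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_el = int(rng.integers(0, 4))
            els = [
                make_cassandra(
                    CassandraSpec(ltr_length=int(rng.integers(90, 300)), internal_length=int(rng.integers(40, 200))),
                    gene,
                    int(rng.integers(0, 2**31)),
                    element_id=f"e{i}",
                )
                for i in range(n_el)
            ]
            genome, truth = plant_elements(18000, els, seed + 1000)
            cands = find_ltr_pairs(genome)
            spans = [t.interval for t in truth if t.feature_type == "LTR_retrotransposon"]
            assert len(cands) == len(spans)
            for c, s in zip(cands, spans):
                ov = c.element.overlap(s)
                assert min(ov / c.element.length(), ov / s.length()) >= 0.5


class TestEvidenceMotifs:
    def _candidate(self, seq, e_start, ltr_len, internal_len):
        e_end = e_start + 2 * ltr_len + internal_len
        return type(
            "C",
            (),
            {
                "element": Interval(e_start, e_end),
                "ltr5": Interval(e_start, e_start + ltr_len),
                "ltr3": Interval(e_end - ltr_len, e_end),
                "internal": Interval(e_start + ltr_len, e_end - ltr_len),
            },
        )()

    def test_tsd_detected_and_longest_wins(self):
        cfg = DetectorConfig()
        flank = "ACGTA"
        core = "G" * 40 + "C" * 30 + "G" * 40
        seq = SequenceRecord(id="x", residues="TTTTT" + flank + core + flank + "TTTTT")
        cand = self._candidate(seq.residues, 10, 40, 30)
        assert detect_tsd(seq, cand, cfg) == flank

    def test_tsd_absent_for_differing_flanks(self):
        cfg = DetectorConfig()
        core = "G" * 40 + "C" * 30 + "G" * 40
        seq = SequenceRecord(id="x", residues="AAAAAA" + core + "TTTTTT")
        cand = self._candidate(seq.residues, 6, 40, 30)
        assert detect_tsd(seq, cand, cfg) is None

    def test_tsd_six_over_four(self):
        """When both a 6 bp and a 4 bp duplication fit, the longer is reported."""
        cfg = DetectorConfig()
        flank6 = "ACGTAC"
        core = "G" * 40 + "C" * 30 + "G" * 40
        seq = SequenceRecord(id="x", residues="TT" + flank6 + core + flank6 + "TT")
        cand = self._candidate(seq.residues, 8, 40, 30)
        assert detect_tsd(seq, cand, cfg) == flank6

    def test_pbs_at_offset(self):
        cfg = DetectorConfig()
        seq = SequenceRecord(
            id="x",
            residues="G" * 50 + "CCC" + cfg.pbs_motif + "C" * 20 + "G" * 50,
        )
        cand = self._candidate(seq.residues, 0, 50, len(seq.residues) - 100)
        assert detect_pbs(seq, cand, cfg) == (3, 0)

    def test_pbs_absent(self):
        cfg = DetectorConfig()
        seq = SequenceRecord(id="x", residues="G" * 50 + "C" * 40 + "G" * 50)
        cand = self._candidate(seq.residues, 0, 50, 40)
        assert detect_pbs(seq, cand, cfg) is None

    def test_pbs_too_many_mismatches(self):
        cfg = DetectorConfig(pbs_max_mm=2)
        motif = list(cfg.pbs_motif)
        motif[0], motif[3], motif[6] = "C", "C", "T"  # 3 mismatches vs TGGTATCAGAGC
        assert "".join(motif) != cfg.pbs_motif
        seq = SequenceRecord(id="x", residues="G" * 50 + "".join(motif) + "C" * 30 + "G" * 50)
        cand = self._candidate(seq.residues, 0, 50, len(seq.residues) - 100)
        assert detect_pbs(seq, cand, cfg) is None

    def test_ppt_detected(self):
        """A pure purine run at the start of the search region scores 10/10."""
        cfg = DetectorConfig()
        seq = SequenceRecord(id="x", residues="C" * 50 + "GGGAGAGAGG" + "T" * 10 + "C" * 50)
        cand = self._candidate(seq.residues, 0, 50, 20)
        hit = detect_ppt(seq, cand, cfg)
        assert hit == (20, 10)

    def test_ppt_absent_in_pyrimidine_flank(self):
        cfg = DetectorConfig()
        seq = SequenceRecord(id="x", residues="G" * 50 + "CTCTCTCTCTCTCTCTCTCTCTCTCTCTCT" + "G" * 50)
        cand = self._candidate(seq.residues, 0, 50, 30)
        assert detect_ppt(seq, cand, cfg) is None

    def test_ppt_boundary_eight_of_ten(self):
        cfg = DetectorConfig()
        window = "GAGAGAGACT"  # exactly 8 purines in 10
        assert sum(c in "AG" for c in window) == 8
        seq = SequenceRecord(id="x", residues="C" * 50 + "C" * 20 + window + "C" * 50)
        cand = self._candidate(seq.residues, 0, 50, 30)
        hit = detect_ppt(seq, cand, cfg)
        assert hit is not None and hit[1] == 8
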