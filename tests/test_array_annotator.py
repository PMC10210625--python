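import numpy as np
import pytest

from censcan.io_core import Interval, revcomp, encode_seq, decode_codes
from censcan.array_annotator import (MonomerFamily, classify_centromere,
                                     detect_expansions, map_monomers,
                                     orientation_blocks, segment_arrays,
                                     RepeatArray)
from censcan.synthetic_genome import (mutate_codes,
                                      random_primitive_monomer)


@pytest.fixture
def families(rng):
    a = MonomerFamily("A", "TTAGGG")
    c = MonomerFamily("C", random_primitive_monomer(
        127, rng, avoid=[]))
    b = MonomerFamily("B", random_primitive_monomer(37, rng))
    return {"A": a, "B": b, "C": c}


class TestMapMonomers:
    def test_exact_array_fully_tiled(self, families):
        cons = families["C"].consensus
        hits = map_monomers(cons * 50, [families["C"]])
        assert len(hits) == 50
        assert all(h.strand == "+" and h.divergence == 0 for h in hits)

    def test_reverse_complement_strand(self, families):
        cons = families["C"].consensus
        hits = map_monomers(revcomp(cons * 50), [families["C"]])
        assert len(hits) == 50
        assert all(h.strand == "-" for h in hits)

    def test_mutated_copies_recovered_with_divergence(self, rng, families):
        cons = families["C"].consensus
        for seed in range(5):
            r = np.random.default_rng(seed)
            codes = np.tile(encode_seq(cons), 50)
            seq = decode_codes(mutate_codes(codes, 0.10, r))
            hits = map_monomers(seq, [families["C"]])
            assert len(hits) >= 48
            mean_div = np.mean([h.divergence for h in hits])
            assert 0.06 <= mean_div <= 0.14

    def test_hits_never_overlap_and_respect_divergence_cap(self, rng,
                                                           families,
                                                           make_seq):
        cons = families["B"].consensus
        codes = np.tile(encode_seq(cons), 300)
        seq = (make_seq(5000, rng)
               + decode_codes(mutate_codes(codes, 0.08, rng))
               + make_seq(5000, rng))
        hits = map_monomers(seq, list(families.values()))
        for h in hits:
            assert h.divergence <= 0.2
        for h1, h2 in zip(hits[:-1], hits[1:]):
            assert h1.interval.end <= h2.interval.start


class TestSegmentArrays:
    def test_alternating_runs_become_one_ac_array(self, families):
        a, c = families["A"].consensus, families["C"].consensus
        seq = (a * 20 + c * 7) * 10
        hits = map_monomers(seq, [families["A"], families["C"]])
        arrays = segment_arrays(hits, [families["A"], families["C"]])
        assert len(arrays) == 1
        assert arrays[0].array_type == "AC"
        assert arrays[0].copy_count == 270

    def test_homogeneous_run_typed_by_family(self, families):
        seq = families["B"].consensus * 100
        hits = map_monomers(seq, [families["B"]])
        arrays = segment_arrays(hits, [families["B"]])
        assert len(arrays) == 1
        assert arrays[0].array_type == "B" and arrays[0].copy_count == 100

    def test_short_run_below_min_copies_dropped(self, families):
        seq = families["B"].consensus * 5
        hits = map_monomers(seq, [families["B"]])
        assert segment_arrays(hits, [families["B"]], min_copies=10) == []

    def test_unmappable_copies_counted_from_span(self, rng, families):
        # corrupt two interior copies beyond max_divergence; span arithmetic
        # still counts them
        cons = families["B"].consensus
        codes = np.tile(encode_seq(cons), 100)
        for at in (40, 41):
            sl = slice(at * 37, (at + 1) * 37)
            codes[sl] = mutate_codes(codes[sl], 0.5, rng)
        hits = map_monomers(decode_codes(codes), [families["B"]])
        arrays = segment_arrays(hits, [families["B"]])
        assert len(arrays) == 1
        assert arrays[0].copy_count == 100
        assert arrays[0].n_hits < 100


class TestOrientationBlocks:
    def _array_from(self, seq, fam):
        hits = map_monomers(seq, [fam])
        (arr,) = segment_arrays(hits, [fam])
        return arr

    def test_uniform_orientation_single_block(self, families):
        arr = self._array_from(families["B"].consensus * 60, families["B"])
        blocks, n_sw, mean_bp = orientation_blocks(arr)
        assert len(blocks) == 1 and n_sw == 0
        assert mean_bp == arr.interval.length

    def test_two_halves_one_switch(self, families):
        cons = families["B"].consensus
        seq = cons * 30 + revcomp(cons * 30)
        arr = self._array_from(seq, families["B"])
        blocks, n_sw, mean_bp = orientation_blocks(arr)
        assert n_sw == 1
        assert [b[0] for b in blocks] == ["+", "-"]
        assert mean_bp == pytest.approx(len(seq) / 2)

    def test_many_planted_blocks_recovered(self, families):
        cons = families["B"].consensus
        parts = []
        for i in range(10):
            block = cons * 20
            parts.append(block if i % 2 == 0 else revcomp(block))
        arr = self._array_from("".join(parts), families["B"])
        blocks, n_sw, mean_bp = orientation_blocks(arr)
        assert n_sw == 9
        assert mean_bp == pytest.approx(len("".join(parts)) / 10)


class TestClassification:
    def _arr(self, t, start, end):
        return RepeatArray(Interval("c", start, end), t, [t], 100, 100)

    def test_single_array_simple(self):
        model = classify_centromere(Interval("c", 0, 1000),
                                    [self._arr("AC", 0, 900)])
        assert model.centromere_class == "simple"

    def test_two_arrays_asymmetric(self):
        model = classify_centromere(
            Interval("c", 0, 2000),
            [self._arr("AC", 0, 900), self._arr("B", 1000, 1900)])
        assert model.centromere_class == "asymmetric"

    def test_sandwich_symmetric(self):
        model = classify_centromere(
            Interval("c", 0, 3000),
            [self._arr("AC", 0, 900), self._arr("B", 1000, 1900),
             self._arr("AC", 2000, 2900)])
        assert model.centromere_class == "symmetric"

    def test_empty_and_odd_compositions_unclassified(self):
        assert classify_centromere(Interval("c", 0, 100),
                                   []).centromere_class == "unclassified"
        model = classify_centromere(
            Interval("c", 0, 2000),
            [self._arr("B", 0, 900), self._arr("B", 1000, 1900)])
        assert model.centromere_class == "unclassified"

    def test_arrays_outside_interval_ignored(self):
        model = classify_centromere(
            Interval("c", 0, 1000),
            [self._arr("AC", 0, 900), self._arr("B", 5000, 6000)])
        assert model.centromere_class == "simple"


class TestExpansions:
    def _arr(self, t, start, end):
        return RepeatArray(Interval("c", start, end), t, [t], 100, 100)

    def test_large_external_array_reported_with_distance(self):
        cen = Interval("c", 1_000_000, 1_400_000)
        exp = self._arr("B", 3_000_000, 5_500_000)
        out = detect_expansions([exp, self._arr("AC", 1_000_000, 1_350_000)],
                                cen, min_expansion_bp=1_000_000)
        assert out == [exp]
        assert exp.distance_to_centromere == 1_600_000

    def test_small_or_internal_arrays_not_reported(self):
        cen = Interval("c", 1_000_000, 1_400_000)
        small = self._arr("B", 3_000_000, 3_500_000)
        inside = self._arr("B", 1_050_000, 1_380_000)
        assert detect_expansions([small, inside], cen,
                                 min_expansion_bp=1_000_000) == []
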