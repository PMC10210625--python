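from collections import defaultdict

import numpy as np
import pytest

from censcan.io_core import Chromosome, revcomp, encode_seq, decode_codes
from censcan.repeat_spectrum import (dominant_period, interval_spectrum,
                                     monomer_consensus, telomere_arrays,
                                     top_periods)
from censcan.synthetic_genome import (mutate_codes,
                                      random_primitive_monomer)


def brute_spectrum(seq: str, k: int = 8, max_lag: int = 3000,
                   min_kmer_count: int = 3) -> np.ndarray:
    """Independent dictionary-based occurrence-gap tally."""
    occ = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            occ[kmer].append(i)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    for positions in occ.values():
        if len(positions) < min_kmer_count:
            continue
        for a, b in zip(positions[:-1], positions[1:]):
            if 1 <= b - a <= max_lag:
                counts[b - a] += 1
    return counts


def is_rotation(a: str, b: str) -> bool:
    return len(a) == len(b) and a in b + b


class TestIntervalSpectrum:
    def test_matches_brute_force_oracle(self, rng, make_seq):
        for trial in range(10):
            seq = make_seq(int(rng.integers(100, 2000)), rng)
            if trial % 2:
                mono = make_seq(int(rng.integers(5, 60)), rng)
                seq = seq[:100] + mono * 20 + seq[100:]
            got = interval_spectrum(seq, max_lag=500).counts
            assert np.array_equal(got, brute_spectrum(seq, max_lag=500))

    def test_telomere_array_concentrates_at_lag_six(self):
        sp = interval_spectrum("TTAGGG" * 500)
        assert sp.counts[6] > 0.99 * sp.total

    def test_poly_a_concentrates_at_lag_one(self):
        sp = interval_spectrum("A" * 1000)
        assert sp.counts[1] == sp.total > 0

    def test_random_sequence_has_no_strong_lag(self, rng, make_seq):
        sp = interval_spectrum(make_seq(10_000, rng))
        if sp.total:
            assert sp.counts.max() < 0.05 * max(sp.total, 1) + 1

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            interval_spectrum("ACGT", k=8)


class TestDominantPeriod:
    def test_telomere_motif_period(self):
        assert dominant_period(interval_spectrum("TTAGGG" * 500)) == 6

    def test_monomer_length_recovered_not_harmonic(self, rng):
        for length in (37, 127):
            mono = random_primitive_monomer(length, rng)
            sp = interval_spectrum(mono * 500)
            assert dominant_period(sp) == length

    def test_long_monomer_within_max_lag(self, rng):
        mono = random_primitive_monomer(1747, rng)
        sp = interval_spectrum(mono * 50, max_lag=3000)
        assert dominant_period(sp) == 1747

    def test_random_sequence_returns_none(self, rng, make_seq):
        assert dominant_period(interval_spectrum(make_seq(10_000, rng))) is (
            None)

    def test_invariant_to_k_on_exact_arrays(self, rng):
        mono = random_primitive_monomer(37, rng)
        seq = mono * 300
        for k in (6, 8, 12, 16):
            assert dominant_period(interval_spectrum(seq, k=k)) == 37

    def test_mutated_array_recovers_period(self, rng):
        for length in (6, 37, 127):
            mono = (("TTAGGG" if length == 6
                     else random_primitive_monomer(length, rng)))
            codes = np.tile(encode_seq(mono), 3000 // length + 200)
            seq = decode_codes(mutate_codes(codes, 0.05, rng))
            assert dominant_period(interval_spectrum(seq)) == length


class TestTopPeriods:
    def test_composite_array_shows_both_periods(self, rng):
        a = "TTAGGG"
        c = random_primitive_monomer(127, rng, avoid=[])
        seq = (a * 20 + c * 7) * 30
        tops = [lag for lag, _ in top_periods(interval_spectrum(seq), 5)]
        assert 6 in tops
        assert any(100 <= lag <= 140 for lag in tops)

    def test_lightly_mutated_array_has_harmonic_second_peak(self, rng):
        mono = random_primitive_monomer(37, rng)
        codes = np.tile(encode_seq(mono), 1000)
        seq = decode_codes(mutate_codes(codes, 0.02, rng))
        tops = [lag for lag, _ in top_periods(interval_spectrum(seq), 3)]
        assert tops[0] == 37 and 74 in tops

    def test_empty_spectrum(self, rng, make_seq):
        sp = interval_spectrum(make_seq(50, rng))
        sp.counts[:] = 0
        assert top_periods(sp, 5) == []


class TestMonomerConsensus:
    def test_exact_array_recovers_rotation(self, rng, make_seq):
        mono = random_primitive_monomer(50, rng)
        cons = monomer_consensus(mono * 200, 50)
        assert is_rotation(cons, mono)

    def test_mutated_array_near_rotation(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            mono = random_primitive_monomer(50, r)
            codes = np.tile(encode_seq(mono), 200)
            seq = decode_codes(mutate_codes(codes, 0.02, r))
            cons = monomer_consensus(seq, 50)
            best = min(sum(a != b for a, b in zip(cons, (mono + mono)[i:i + 50]))
                       for i in range(50))
            assert best <= 2

    def test_doubled_period_gives_doubled_rotation(self, rng):
        mono = random_primitive_monomer(50, rng)
        cons = monomer_consensus(mono * 200, 100)
        assert is_rotation(cons, mono + mono)

    def test_too_few_slices_rejected(self, rng):
        mono = random_primitive_monomer(50, rng)
        with pytest.raises(ValueError):
            monomer_consensus(mono * 2, 50)


class TestTelomereArrays:
    def _chrom(self, rng, make_seq, copies, at=200_000, length=500_000):
        run = "TTAGGG" * copies
        seq = make_seq(at, rng) + run + make_seq(length - at - len(run),
                                                 rng)
        return Chromosome("c", seq)

    def test_seventy_copies_reported_interstitial(self, rng, make_seq):
        chrom = self._chrom(rng, make_seq, 70)
        arrays = [t for t in telomere_arrays(chrom)
                  if t.kind == "interstitial"]
        assert len(arrays) == 1 and arrays[0].copy_count == 70

    def test_sixty_nine_copies_rejected(self, rng, make_seq):
        chrom = self._chrom(rng, make_seq, 69)
        assert not [t for t in telomere_arrays(chrom)
                    if t.kind == "interstitial"]

    def test_terminal_run_and_strand(self, rng, make_seq):
        seq = "TTAGGG" * 300 + make_seq(100_000, rng) + revcomp(
            "TTAGGG") * 90
        arrays = telomere_arrays(Chromosome("c", seq))
        kinds = {(t.kind, t.strand) for t in arrays}
        assert ("terminal", "+") in kinds
        # the reverse-complement run sits at the right end
        assert any(t.strand == "-" for t in arrays)

    def test_variant_copy_tolerance_merges_runs(self, rng, make_seq):
        run = "TTAGGG" * 40 + "TTAGCG" + "TTAGGG" * 40
        seq = make_seq(50_000, rng) + run + make_seq(50_000, rng)
        chrom = Chromosome("c", seq)
        strict = [t for t in telomere_arrays(chrom)
                  if t.kind == "interstitial"]
        lax = [t for t in telomere_arrays(chrom, tolerate_variant_copy=True)
               if t.kind == "interstitial"]
        assert not strict
        assert len(lax) == 1 and lax[0].copy_count == 81
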