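import numpy as np
import pytest

from censcan.io_core import revcomp
from censcan.synthetic_genome import (ArraySpec, MonomerSpec,
                                      default_genome, build_array,
                                      grow_bfb_chromosome, is_primitive,
                                      place_genes,
                                      random_primitive_monomer,
                                      simulate_genetic_map)


@pytest.fixture
def monomers(rng):
    a = MonomerSpec("A", "TTAGGG", 0.0)
    c = MonomerSpec("C", random_primitive_monomer(127, rng, avoid=[a]), 0.0)
    b = MonomerSpec("B", random_primitive_monomer(37, rng, avoid=[a, c]),
                    0.0)
    return [a, b, c]


class TestBuildArray:
    def test_ac_array_length_is_exact_arithmetic(self, monomers):
        spec = ArraySpec("AC", ("A", "C"), {"A": 10, "C": 5},
                         n_alternations=3)
        seq, runs, blocks = build_array(spec, monomers, 1)
        assert len(seq) == 3 * (10 * 6 + 5 * 127) == 2085
        assert [r.copies for r in runs] == [10, 5] * 3

    def test_homogeneous_array(self, monomers):
        spec = ArraySpec("homogeneous", ("B",), {"B": 100})
        seq, runs, blocks = build_array(spec, monomers, 1)
        assert len(seq) == 3700
        assert len(runs) == 1 and runs[0].copies == 100

    def test_orientation_blocks_reverse_complement(self, monomers):
        spec = ArraySpec("homogeneous", ("B",), {"B": 200},
                         orientation_blocks=[("+", 1), ("-", 1)])
        seq, runs, blocks = build_array(spec, monomers, 1)
        half = len(seq) // 2
        assert seq[half:] == revcomp(seq[:half])
        assert [b[0] for b in blocks] == ["+", "-"]

    def test_alternation_count_validated(self):
        with pytest.raises(ValueError):
            ArraySpec("AC", ("A", "C"), {}, n_alternations=0)

    def test_unknown_family_rejected(self, monomers):
        spec = ArraySpec("homogeneous", ("Z",), {"Z": 10})
        with pytest.raises(ValueError, match="unknown monomer family"):
            build_array(spec, monomers, 1)


class TestPrimitiveMonomers:
    def test_primitivity(self):
        assert is_primitive("ACGT")
        assert not is_primitive("ACAC")
        assert not is_primitive("AAAA")

    def test_random_monomer_is_primitive_and_disjoint(self, rng):
        a = MonomerSpec("A", "TTAGGG")
        m = random_primitive_monomer(127, rng, avoid=[a])
        assert len(m) == 127 and is_primitive(m)


class TestGeneticMapSimulation:
    def test_zero_noise_no_hotspots_is_linear(self):
        ms, _ = simulate_genetic_map(1_000_000, 2.0, [], 50, 0.0, 3)
        bp = np.array([m.bp for m in ms], float)
        cm = np.array([m.cM for m in ms], float)
        assert np.allclose(cm, bp * 2.0 / 1e6)

    def test_hotspot_integral_sets_map_length(self):
        L, base = 1_000_000, 1.0
        hs = [(400_000, 450_000, 10.0)]  # 10x over 5% of the chromosome
        ms, truth = simulate_genetic_map(L, base, hs, 500, 0.0, 3)
        expected_total = base * L * (0.95 + 0.05 * 10) / 1e6
        span = ms[-1].cM - ms[0].cM
        # markers don't sit exactly at 0 and L; allow edge slack
        assert span == pytest.approx(expected_total, rel=0.02)
        assert truth[0].fold == 10.0

    def test_noise_still_monotone(self):
        ms, _ = simulate_genetic_map(1_000_000, 1.0, [], 100, 5.0, 3)
        cm = [m.cM for m in ms]
        assert all(b >= a for a, b in zip(cm, cm[1:]))
        assert all(m.cM >= 0 for m in ms)

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError):
            simulate_genetic_map(1000, 1.0, [], 1, 0.0, 3)

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_genetic_map(1000, 1.0, [(0, 100, 0.5)], 10, 0.0, 3)


class TestPlaceGenes:
    def test_uniform_flag_counts(self):
        genes = place_genes({"c1": 1_000_000}, 100, 10, seed=3)
        assert sum(g.is_gc_outlier for g in genes) == 10
        assert len(genes) == 100

    def test_no_outliers(self):
        genes = place_genes({"c1": 1_000_000}, 50, 0, seed=3)
        assert not any(g.is_gc_outlier for g in genes)

    def test_laplace_decay_sets_mean_distance(self):
        from censcan.io_core import Interval
        from censcan.synthetic_genome import HotspotTruth
        hs = [HotspotTruth(Interval("c1", 40_000_000, 40_010_000), 10.0)]
        genes = place_genes({"c1": 80_000_000}, 4000, 4000,
                            clustering="near_hotspots", hotspots=hs,
                            decay_bp=100_000, seed=3)
        center = 40_005_000
        d = np.abs([g.interval.midpoint - center for g in genes])
        assert np.mean(d) == pytest.approx(100_000, rel=0.1)

    def test_too_many_outliers_rejected(self):
        with pytest.raises(ValueError):
            place_genes({"c1": 1000_000}, 10, 11, seed=1)


class TestBfbGrowth:
    def test_single_full_suffix_cycle(self, rng):
        seq, truth = grow_bfb_chromosome(5000, 1, 0.0, rng,
                                         suffix_fraction_range=(1.0, 1.0))
        assert seq[5000:] == revcomp(seq[:5000])
        assert truth[0].template == (0, 5000)
        assert truth[0].copy == (5000, 10000)

    def test_zero_cycles_rejected(self, rng):
        with pytest.raises(ValueError):
            grow_bfb_chromosome(1000, 0, 0.0, rng)

    def test_length_bounded_by_doubling(self, rng):
        seq, _ = grow_bfb_chromosome(10_000, 3, 0.0, rng)
        assert len(seq) <= 10_000 * 2 ** 3


class TestDefaultGenome:
    def test_reproducible_and_truth_in_bounds(self):
        g1 = default_genome(3)
        g2 = default_genome(3)
        assert [c.seq for c in g1.chromosomes] == [
            c.seq for c in g2.chromosomes]
        assert [(m.chrom, m.bp, m.cM) for m in g1.markers] == [
            (m.chrom, m.bp, m.cM) for m in g2.markers]
        lengths = g1.chrom_lengths()
        for a in g1.truth.arrays:
            assert 0 <= a.start < a.end <= lengths[a.chrom]
        for t in g1.truth.telomeres:
            assert t.interval.end <= lengths[t.interval.chrom]
        classes = {c.interval.chrom: c.centromere_class
                   for c in g1.truth.centromeres}
        assert classes == {"chr1": "simple", "chr2": "asymmetric",
                           "chr3": "symmetric", "chr4": "simple"}

    def test_planted_telomere_runs_are_maximal(self):
        g = default_genome(4)
        for t in g.truth.telomeres:
            chrom = g.chromosome(t.interval.chrom)
            motif = "TTAGGG" if t.strand == "+" else revcomp("TTAGGG")
            run = chrom.seq[t.interval.start:t.interval.end]
            assert run == motif * t.copies
            before = chrom.seq[max(t.interval.start - 6, 0):
                               t.interval.start]
            after = chrom.seq[t.interval.end:t.interval.end + 6]
            assert before != motif and after != motif

    def test_genome_and_truth_serialize(self, tmp_path):
        g = default_genome(5)
        g.write(tmp_path / "g")
        assert (tmp_path / "g" / "genome.fasta").exists()
        assert (tmp_path / "g" / "truth" / "arrays.bed").exists()
        assert (tmp_path / "g" / "markers.tsv").exists()
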