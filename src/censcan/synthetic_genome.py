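"""Desk-scale synthetic genomes with planted, machine-readable ground truth.

The generator emulates the repeat architecture of a rodent genome whose
centromeres are built from four satellite monomer families:

* family A: the 6-bp telomere motif TTAGGG,
* family B: a 37-bp monomer,
* family C: a 127-bp monomer,
* family D: a 1747-bp monomer,

arranged either as A-C arrays (runs of 10-50 A copies alternating with runs
of 5-10 C copies) or as homogeneous B, C or D arrays, optionally split into
orientation blocks (whole blocks reverse-complemented).  Centromeres are
one to three such arrays separated by short non-repetitive spacers and are
classed simple / asymmetric / symmetric by their array composition.

The default genome has four chromosomes:

* ``chr1`` -- simple centromere (one A-C array), a 70-copy interstitial
  telomere array and a 10x recombination hotspot;
* ``chr2`` -- asymmetric centromere (A-C + B), a 69-copy interstitial
  telomere array (just below the >=70 reporting threshold) and an 8x
  hotspot;
* ``chr3`` -- symmetric centromere (A-C + B + A-C, flanks in opposite
  orientation) plus a 2-Mb intra-arm B-array expansion broken into ~20
  orientation blocks;
* ``chr4`` -- a chromosome grown by iterated breakage-fusion-bridge-style
  inverted suffix duplication from a ~0.8-Mb seed, carrying a simple
  D-array centromere.

All chromosomes carry exact terminal telomere arrays (200-500 copies).
Background sequence is i.i.d. at GC 0.42.  Mutations are substitutions
only by default, so planted copy counts and coordinates are exact.
Every planted feature is recorded in a :class:`TruthSet` that serializes
to BED/TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_core import (Chromosome, GeneRecord, GeneticMarker, Interval,
                      decode_codes, encode_seq, intervals_to_bed, revcomp,
                      write_bed, write_fasta, write_genes_tsv, write_markers)

TELOMERE_MOTIF = "TTAGGG"
DEFAULT_GC = 0.42

# analysis parameters matched to the desk-scale genome (centromeres are
# ~300-550 kb here vs 1-10 Mb on real chromosomes; bounds scale with them)
DESK_CEN_MIN_LEN = 100_000
DESK_CEN_MAX_LEN = 1_500_000
DESK_MIN_EXPANSION = 1_000_000


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))


def random_codes(n: int, rng: np.random.Generator,
                 gc: float = DEFAULT_GC) -> np.ndarray:
    """i.i.d. nucleotide codes at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    u = rng.random(n)
    return np.searchsorted(np.cumsum(p), u).astype(np.int8)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.int8)


def mutate_codes(codes: np.ndarray, rate: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Substitution-only mutation: each base changes with probability
    ``rate``, always to a different base."""
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hit = np.where(rng.random(len(codes)) < rate)[0]
    out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def is_primitive(seq: str) -> bool:
    """True if the sequence has no proper divisor period."""
    L = len(seq)
    for d in range(1, L):
        if L % d == 0 and seq == seq[:d] * (L // d):
            return False
    return True


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


@dataclass
class MonomerSpec:
    """A satellite monomer family."""

    family_id: str
    seq: str
    per_copy_substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not is_primitive(self.seq):
            raise ValueError(
                f"monomer {self.family_id} is not primitive: {self.seq}")
        if not 0 <= self.per_copy_substitution_rate <= 0.3:
            raise ValueError("per_copy_substitution_rate outside [0, 0.3]")

    @property
    def length(self) -> int:
        return len(self.seq)


def random_primitive_monomer(length: int, rng: np.random.Generator,
                             avoid: Sequence[MonomerSpec] = (),
                             overlap_k: int = 15,
                             max_tries: int = 1000) -> str:
    """Draw a random primitive monomer sharing no >=15-bp substring (either
    strand) with any monomer in ``avoid``; keeps family calls unambiguous."""
    forbidden: set[str] = set()
    for m in avoid:
        doubled = m.seq * 2  # tandem context, including the wrap-around
        forbidden |= _kmer_set(doubled, overlap_k)
        forbidden |= _kmer_set(revcomp(doubled), overlap_k)
    for _ in range(max_tries):
        cand = decode_codes(random_codes(length, rng, gc=0.5))
        if not is_primitive(cand):
            continue
        if length >= overlap_k and (_kmer_set(cand * 2, overlap_k)
                                    & forbidden):
            continue
        return cand
    raise RuntimeError("failed to draw a primitive monomer")


# ---------------------------------------------------------------------------
# satellite arrays
# ---------------------------------------------------------------------------

@dataclass
class ArrayRunTruth:
    """One same-family monomer run inside an array (coords array-relative
    until offset by the chromosome assembler)."""

    family: str
    start: int
    end: int
    copies: int
    strand: str


@dataclass
class ArrayTruth:
    chrom: str
    kind: str                      # AC | B | C | D | homogeneous_other
    start: int
    end: int
    runs: list[ArrayRunTruth]
    blocks: list[tuple[str, int, int]]   # (strand, start, end)

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def n_switches(self) -> int:
        return len(self.blocks) - 1

    def copies_of(self, family: str) -> int:
        return sum(r.copies for r in self.runs if r.family == family)

    @property
    def total_copies(self) -> int:
        return sum(r.copies for r in self.runs)


@dataclass
class ArraySpec:
    """Recipe for one satellite array.

    ``copy_counts`` maps family id to either an exact per-run copy count or
    an inclusive (lo, hi) range.  For AC arrays, ``families`` is
    (short_family, long_family) and ``n_alternations`` counts short+long
    run pairs.  ``orientation_blocks`` is a list of (strand, approx_bp)
    that tiles the array; None means a single forward block.
    """

    kind: str                       # "AC" | "homogeneous"
    families: tuple[str, ...]
    copy_counts: dict
    n_alternations: int = 0
    orientation_blocks: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("AC", "homogeneous"):
            raise ValueError(f"unknown array kind {self.kind}")
        if self.kind == "AC":
            if len(self.families) != 2:
                raise ValueError("AC arrays reference exactly two families")
            if self.n_alternations < 1:
                raise ValueError("n_alternations must be >= 1")
        elif len(self.families) != 1:
            raise ValueError("homogeneous arrays reference one family")


def _draw_copies(spec_counts, family: str, rng: np.random.Generator,
                 default: tuple[int, int]) -> int:
    val = spec_counts.get(family, default)
    if isinstance(val, (tuple, list)):
        lo, hi = val
        return int(rng.integers(lo, hi + 1))
    return int(val)


def build_array(spec: ArraySpec, monomers: Sequence[MonomerSpec],
                seed) -> tuple[str, list[ArrayRunTruth],
                               list[tuple[str, int, int]]]:
    """Realize an array: returns (sequence, run truth, orientation blocks).

    Run lengths for AC arrays default to 10-50 copies of the short family
    alternating with 5-10 copies of the long family.  Each monomer copy is
    mutated independently at its family's substitution rate; orientation
    blocks are realized by reverse-complementing whole blocks.
    """
    rng = _rng(seed)
    fam = {m.family_id: m for m in monomers}
    for f in spec.families:
        if f not in fam:
            raise ValueError(f"unknown monomer family {f}")

    # 1. forward-orientation run list: (family, copies)
    runs_fwd: list[tuple[str, int]] = []
    if spec.kind == "AC":
        short_f, long_f = spec.families
        for _ in range(spec.n_alternations):
            runs_fwd.append((short_f,
                             _draw_copies(spec.copy_counts, short_f, rng,
                                          (10, 50))))
            runs_fwd.append((long_f,
                             _draw_copies(spec.copy_counts, long_f, rng,
                                          (5, 10))))
    else:
        f = spec.families[0]
        total = _draw_copies(spec.copy_counts, f, rng, (100, 1000))
        if spec.orientation_blocks and len(spec.orientation_blocks) > 1:
            # one run per orientation block, copies split by block weight
            w = np.array([bp for _, bp in spec.orientation_blocks], float)
            alloc = np.floor(total * w / w.sum()).astype(int)
            alloc[-1] = total - alloc[:-1].sum()
            runs_fwd.extend((f, int(c)) for c in alloc)
        else:
            runs_fwd.append((f, total))

    run_bp = [fam[f].length * c for f, c in runs_fwd]
    total_bp = sum(run_bp)

    # 2. partition runs into orientation blocks by cumulative length
    blocks_spec = spec.orientation_blocks or [("+", total_bp)]
    target = np.cumsum([bp for _, bp in blocks_spec]).astype(float)
    target *= total_bp / target[-1]
    cum = np.cumsum(run_bp)
    block_of = np.searchsorted(target + 1e-6, cum)   # run ends <= target
    block_of = np.minimum(block_of, len(blocks_spec) - 1)

    # 3. emit sequence block by block; '-' blocks reversed + revcomp'd
    parts: list[np.ndarray] = []
    run_truth: list[ArrayRunTruth] = []
    block_truth: list[tuple[str, int, int]] = []
    pos = 0
    for b, (strand, _) in enumerate(blocks_spec):
        members = [i for i in range(len(runs_fwd)) if block_of[i] == b]
        if not members:
            continue
        if strand == "-":
            members = members[::-1]
        bstart = pos
        for i in members:
            f, copies = runs_fwd[i]
            mono = encode_seq(fam[f].seq)
            tiled = np.tile(mono, copies)
            tiled = mutate_codes(tiled, fam[f].per_copy_substitution_rate,
                                 rng)
            if strand == "-":
                tiled = revcomp_codes(tiled)
            run_truth.append(ArrayRunTruth(f, pos, pos + len(tiled), copies,
                                           strand))
            parts.append(tiled)
            pos += len(tiled)
        block_truth.append((strand, bstart, pos))
    seq = decode_codes(np.concatenate(parts))
    return seq, run_truth, block_truth


def telomere_codes(n_copies: int, strand: str = "+") -> np.ndarray:
    motif = TELOMERE_MOTIF if strand == "+" else revcomp(TELOMERE_MOTIF)
    return np.tile(encode_seq(motif), n_copies)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotTruth:
    interval: Interval
    fold: float


def simulate_genetic_map(chrom_length: int, base_rate_cM_per_Mb: float,
                         hotspot_spec: Sequence[tuple[int, int, float]],
                         n_markers: int, cM_noise_sd: float, seed,
                         chrom_name: str = "chr"
                         ) -> tuple[list[GeneticMarker], list[HotspotTruth]]:
    """Markers from a piecewise-constant recombination map.

    Marker bp positions are uniform; cM positions are the integral of the
    rate map plus Gaussian noise, then sorted so cM is non-decreasing.
    ``hotspot_spec`` rows are (start, end, fold) with fold >= 1.
    """
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    for s, e, fold in hotspot_spec:
        if fold < 1:
            raise ValueError("hotspot fold multipliers must be >= 1")
        if not 0 <= s < e <= chrom_length:
            raise ValueError("hotspot outside chromosome")
    rng = _rng(seed)
    bp = np.empty(0, dtype=np.int64)
    while len(bp) < n_markers:          # cheap unique-uniform positions
        bp = np.unique(rng.integers(0, chrom_length,
                                    size=2 * n_markers + 16))
    bp = np.sort(rng.choice(bp, size=n_markers, replace=False))

    cm = bp.astype(float) * base_rate_cM_per_Mb / 1e6
    for s, e, fold in hotspot_spec:
        overlap = np.clip(bp, s, e) - s
        cm += overlap * (fold - 1) * base_rate_cM_per_Mb / 1e6
    if cM_noise_sd > 0:
        cm = cm + rng.normal(0, cM_noise_sd, size=n_markers)
    cm = np.sort(cm)
    cm -= min(cm[0], 0.0)           # keep genetic positions non-negative
    markers = [GeneticMarker(chrom_name, int(b), float(c))
               for b, c in zip(bp, cm)]
    truth = [HotspotTruth(Interval(chrom_name, s, e), fold)
             for s, e, fold in hotspot_spec]
    return markers, truth


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def place_genes(chrom_lengths: dict[str, int], n_genes: int, n_outliers: int,
                clustering: str = "uniform",
                hotspots: Sequence[HotspotTruth] = (),
                decay_bp: float = 100_000, gene_length: int = 5000,
                seed=None) -> list[GeneRecord]:
    """Place genes uniformly; optionally cluster the GC-outlier subset near
    hotspot centers with Laplace-distributed offsets (mean |offset| equals
    ``decay_bp``)."""
    if n_outliers > n_genes:
        raise ValueError("n_outliers > n_genes")
    if clustering not in ("uniform", "near_hotspots"):
        raise ValueError(f"unknown clustering mode {clustering}")
    if clustering == "near_hotspots" and not hotspots:
        raise ValueError("near_hotspots clustering requires hotspot truth")
    rng = _rng(seed)
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()

    genes: list[GeneRecord] = []

    def _add(gid: str, chrom: str, mid: float, outlier: bool) -> None:
        L = chrom_lengths[chrom]
        start = int(np.clip(mid - gene_length / 2, 0, L - gene_length))
        genes.append(GeneRecord(gid, Interval(chrom, start,
                                              start + gene_length), outlier))

    n_background = n_genes - n_outliers
    chroms = rng.choice(len(names), size=n_background, p=probs)
    for i, ci in enumerate(chroms):
        chrom = names[ci]
        mid = rng.uniform(0, chrom_lengths[chrom])
        _add(f"gene{i:05d}", chrom, mid, False)

    for i in range(n_outliers):
        gid = f"gcout{i:05d}"
        if clustering == "uniform":
            ci = rng.choice(len(names), p=probs)
            chrom = names[ci]
            mid = rng.uniform(0, chrom_lengths[chrom])
        else:
            hs = hotspots[rng.integers(len(hotspots))]
            chrom = hs.interval.chrom
            mid = hs.interval.midpoint + rng.laplace(0, decay_bp)
            mid = float(np.clip(mid, 0, chrom_lengths[chrom]))
        _add(gid, chrom, mid, True)
    return genes


# ---------------------------------------------------------------------------
# breakage-fusion-bridge chromosome growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicationTruth:
    """One inverted duplication event: ``template`` was copied (reverse
    complemented) to ``copy``."""

    template: tuple[int, int]
    copy: tuple[int, int]
    orientation: str = "inverted"


def grow_bfb_chromosome(seed_segment_length: int, n_cycles: int,
                        per_cycle_substitution_rate: float, seed,
                        suffix_fraction_range: tuple[float, float] = (0.6,
                                                                      1.0),
                        gc: float = DEFAULT_GC
                        ) -> tuple[str, list[DuplicationTruth]]:
    """Grow a chromosome by iterated inverted suffix duplication.

    Each cycle appends the reverse complement of a random-length suffix of
    the current sequence (fraction drawn uniformly from
    ``suffix_fraction_range``), mimicking fusion of telomere-free chromatid
    ends followed by anaphase breakage.  Returns the sequence and every
    duplicated interval pair.  Final length <= seed * 2**n_cycles.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    lo, hi = suffix_fraction_range
    if not 0 < lo <= hi <= 1:
        raise ValueError("suffix fractions must lie in (0, 1]")
    rng = _rng(seed)
    seq = random_codes(seed_segment_length, rng, gc=gc)
    truth: list[DuplicationTruth] = []
    for _ in range(n_cycles):
        n = len(seq)
        frac = rng.uniform(lo, hi)
        sl = max(1, int(round(frac * n)))
        appended = mutate_codes(revcomp_codes(seq[n - sl:]),
                                per_cycle_substitution_rate, rng)
        truth.append(DuplicationTruth((n - sl, n), (n, n + sl)))
        seq = np.concatenate([seq, appended])
    return decode_codes(seq), truth


# ---------------------------------------------------------------------------
# whole-genome assembly with truth
# ---------------------------------------------------------------------------

@dataclass
class TelomereTruth:
    interval: Interval
    copies: int
    strand: str
    kind: str                      # terminal | interstitial


@dataclass
class CentromereTruth:
    interval: Interval
    centromere_class: str          # simple | asymmetric | symmetric


@dataclass
class TruthSet:
    """Machine-readable record of everything planted in a genome."""

    centromeres: list[CentromereTruth] = field(default_factory=list)
    arrays: list[ArrayTruth] = field(default_factory=list)
    telomeres: list[TelomereTruth] = field(default_factory=list)
    hotspots: list[HotspotTruth] = field(default_factory=list)
    outlier_gene_ids: list[str] = field(default_factory=list)
    duplications: list[tuple[str, DuplicationTruth]] = field(
        default_factory=list)

    def arrays_on(self, chrom: str) -> list[ArrayTruth]:
        return [a for a in self.arrays if a.chrom == chrom]

    def centromere_on(self, chrom: str) -> CentromereTruth | None:
        for c in self.centromeres:
            if c.interval.chrom == chrom:
                return c
        return None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        intervals_to_bed(outdir / "centromeres.bed",
                         [c.interval for c in self.centromeres],
                         names=[c.centromere_class for c in self.centromeres])
        write_bed(outdir / "arrays.bed", [
            (a.chrom, a.start, a.end,
             f"{a.kind}:{'+'.join(sorted(set(r.family for r in a.runs)))}",
             a.total_copies, a.blocks[0][0] if a.blocks else ".")
            for a in self.arrays
        ])
        write_bed(outdir / "telomeres.bed", [
            (t.interval.chrom, t.interval.start, t.interval.end, t.kind,
             t.copies, t.strand) for t in self.telomeres
        ])
        write_bed(outdir / "hotspots.bed", [
            (h.interval.chrom, h.interval.start, h.interval.end, "hotspot",
             h.fold, ".") for h in self.hotspots
        ])
        write_bed(outdir / "duplications.bed", [
            (chrom, d.template[0], d.template[1],
             f"copy:{d.copy[0]}-{d.copy[1]}", 0, "-")
            for chrom, d in self.duplications
        ])
        with open(outdir / "outlier_genes.txt", "w") as fh:
            fh.write("\n".join(self.outlier_gene_ids) + "\n")


class _ChromBuilder:
    """Accumulates sequence parts and converts part-relative truth
    coordinates to chromosome coordinates."""

    def __init__(self, name: str):
        self.name = name
        self.parts: list[np.ndarray] = []
        self.pos = 0

    def add(self, codes: np.ndarray) -> int:
        start = self.pos
        self.parts.append(codes)
        self.pos += len(codes)
        return start

    def add_background(self, n: int, rng: np.random.Generator,
                       gc: float = DEFAULT_GC) -> int:
        return self.add(random_codes(n, rng, gc=gc))

    def finish(self) -> Chromosome:
        return Chromosome(self.name, decode_codes(np.concatenate(self.parts)))


def _guard_motif_flanks(codes: np.ndarray, start: int, end: int,
                        motif_codes: np.ndarray,
                        rng: np.random.Generator) -> None:
    """Ensure a planted tandem motif run is maximal: redraw the flanking
    motif-length windows until neither equals an adjacent full copy (in the
    run's own phase), so the planted copy count is exactly the run length."""
    L = len(motif_codes)
    left = slice(max(start - L, 0), start)
    if start - L >= 0:
        while np.array_equal(codes[left], motif_codes):
            codes[left] = random_codes(L, rng)
    right = slice(end, min(end + L, len(codes)))
    if end + L <= len(codes):
        while np.array_equal(codes[right], motif_codes):
            codes[right] = random_codes(L, rng)


@dataclass
class SyntheticGenome:
    chromosomes: list[Chromosome]
    truth: TruthSet
    genes: list[GeneRecord]
    markers: list[GeneticMarker]
    monomers: list[MonomerSpec]
    config: dict

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fasta", self.chromosomes)
        write_genes_tsv(outdir / "genes.tsv", self.genes)
        write_markers(outdir / "markers.tsv", self.markers)
        with open(outdir / "monomers.fasta", "w") as fh:
            for m in self.monomers:
                fh.write(f">{m.family_id}\n{m.seq}\n")
        self.truth.write(outdir / "truth")


def default_monomers(rng: np.random.Generator,
                     divergence: float = 0.02) -> list[MonomerSpec]:
    """Family A is the telomere motif; B/C/D are random primitive monomers
    of 37, 127 and 1747 bp with no >=15-bp cross-family overlap."""
    fams = [MonomerSpec("A", TELOMERE_MOTIF, divergence)]
    for fid, length in (("B", 37), ("C", 127), ("D", 1747)):
        seq = random_primitive_monomer(length, rng, avoid=fams)
        fams.append(MonomerSpec(fid, seq, divergence))
    return fams


def default_genome(seed: int, satellite_divergence: float = 0.02,
                   cM_noise_sd: float = 0.05,
                   n_genes: int = 400, n_outliers: int = 40,
                   outlier_decay_bp: float = 100_000,
                   n_markers_per_chrom: int = 400,
                   base_rate_cM_per_Mb: float = 0.5) -> SyntheticGenome:
    """The default four-chromosome desk-scale genome (see module docstring).

    Reproducible: identical seed and parameters give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    monomers = default_monomers(rng, divergence=satellite_divergence)
    fam = {m.family_id: m for m in monomers}
    motif = encode_seq(TELOMERE_MOTIF)
    motif_rc = encode_seq(revcomp(TELOMERE_MOTIF))

    truth = TruthSet()
    chroms: list[Chromosome] = []
    hotspot_spec_by_chrom: dict[str, list[tuple[int, int, float]]] = {}

    def _terminal_tel(b: _ChromBuilder, strand: str) -> None:
        copies = int(rng.integers(200, 501))
        start = b.add(telomere_codes(copies, strand))
        truth.telomeres.append(TelomereTruth(
            Interval(b.name, start, start + copies * 6), copies, strand,
            "terminal"))

    def _interstitial_tel(b: _ChromBuilder, copies: int,
                          strand: str = "+") -> None:
        start = b.add(telomere_codes(copies, strand))
        truth.telomeres.append(TelomereTruth(
            Interval(b.name, start, start + copies * 6), copies, strand,
            "interstitial"))

    def _array(b: _ChromBuilder, spec: ArraySpec) -> ArrayTruth:
        seq, runs, blocks = build_array(spec, monomers, rng)
        start = b.add(encode_seq(seq))
        at = ArrayTruth(
            chrom=b.name,
            kind=(spec.kind if spec.kind == "AC" else spec.families[0]),
            start=start, end=start + len(seq),
            runs=[ArrayRunTruth(r.family, r.start + start, r.end + start,
                                r.copies, r.strand) for r in runs],
            blocks=[(s, bs + start, be + start) for s, bs, be in blocks],
        )
        truth.arrays.append(at)
        return at

    spacer = lambda b: b.add_background(int(rng.integers(6000, 8001)), rng)

    def _centromere(b: _ChromBuilder, specs: list[ArraySpec],
                    cen_class: str) -> None:
        arrays = []
        for i, sp in enumerate(specs):
            if i:
                spacer(b)
            arrays.append(_array(b, sp))
        truth.centromeres.append(CentromereTruth(
            Interval(b.name, arrays[0].start, arrays[-1].end), cen_class))

    ac = lambda n_alt, blocks=None: ArraySpec(
        "AC", ("A", "C"), {}, n_alternations=n_alt,
        orientation_blocks=blocks)
    hom = lambda famid, copies, blocks=None: ArraySpec(
        "homogeneous", (famid,), {famid: copies},
        orientation_blocks=blocks)

    # --- chr1: simple centromere, 70-copy interstitial telomere, 10x hotspot
    b = _ChromBuilder("chr1")
    _terminal_tel(b, "-")
    b.add_background(3_600_000 - b.pos, rng)
    _centromere(b, [ac(265)], "simple")
    b.add_background(6_000_000 - b.pos, rng)
    _interstitial_tel(b, 70)
    b.add_background(8_000_000 - b.pos - 2000, rng)
    _terminal_tel(b, "+")
    chroms.append(b.finish())
    hotspot_spec_by_chrom["chr1"] = [(5_000_000, 5_500_000, 10.0)]

    # --- chr2: asymmetric centromere, 69-copy interstitial, 8x hotspot
    b = _ChromBuilder("chr2")
    _terminal_tel(b, "-")
    b.add_background(1_400_000 - b.pos, rng)
    _centromere(b, [ac(141), hom("B", 4324, blocks=[("+", 80_000),
                                                    ("-", 80_000)])],
                "asymmetric")
    b.add_background(4_000_000 - b.pos, rng)
    _interstitial_tel(b, 69)
    b.add_background(7_000_000 - b.pos - 2000, rng)
    _terminal_tel(b, "+")
    chroms.append(b.finish())
    hotspot_spec_by_chrom["chr2"] = [(4_500_000, 5_000_000, 8.0)]

    # --- chr3: symmetric centromere + 2-Mb intra-arm B expansion
    b = _ChromBuilder("chr3")
    _terminal_tel(b, "-")
    b.add_background(4_200_000 - b.pos, rng)
    _centromere(b, [ac(106), hom("B", 3514), ac(106, blocks=[("-", 1)])],
                "symmetric")
    b.add_background(6_300_000 - b.pos, rng)
    exp_blocks = [("+" if i % 2 == 0 else "-", 100_000) for i in range(20)]
    _array(b, hom("B", 54_054, blocks=exp_blocks))
    b.add_background(9_000_000 - b.pos - 2000, rng)
    _terminal_tel(b, "+")
    chroms.append(b.finish())
    hotspot_spec_by_chrom["chr3"] = []

    # --- chr4: D-array centromere + BFB-grown bulk
    b = _ChromBuilder("chr4")
    _terminal_tel(b, "-")
    b.add_background(1_500_000 - b.pos, rng)
    _centromere(b, [hom("D", 300)], "simple")
    b.add_background(40_000, rng)
    bfb_seq, bfb_truth = grow_bfb_chromosome(
        800_000, 4, 0.0, rng, suffix_fraction_range=(0.7, 0.95))
    off = b.add(encode_seq(bfb_seq))
    for d in bfb_truth:
        truth.duplications.append(("chr4", DuplicationTruth(
            (d.template[0] + off, d.template[1] + off),
            (d.copy[0] + off, d.copy[1] + off))))
    _terminal_tel(b, "+")
    chroms.append(b.finish())
    hotspot_spec_by_chrom["chr4"] = []

    # guard planted telomere runs so their copy counts are exactly maximal
    by_name = {c.name: encode_seq(c.seq) for c in chroms}
    for t in truth.telomeres:
        codes = by_name[t.interval.chrom]
        _guard_motif_flanks(codes, t.interval.start, t.interval.end,
                            motif if t.strand == "+" else motif_rc, rng)
    chroms = [Chromosome(n, decode_codes(c)) for n, c in by_name.items()]

    # genetic map + hotspot truth
    markers: list[GeneticMarker] = []
    for c in chroms:
        spec = hotspot_spec_by_chrom[c.name]
        mk, hs = simulate_genetic_map(
            c.length, base_rate_cM_per_Mb, spec, n_markers_per_chrom,
            cM_noise_sd, rng, chrom_name=c.name)
        markers.extend(mk)
        truth.hotspots.extend(hs)

    # genes: GC-outliers cluster near hotspots
    genes = place_genes({c.name: c.length for c in chroms}, n_genes,
                        n_outliers, clustering="near_hotspots",
                        hotspots=truth.hotspots,
                        decay_bp=outlier_decay_bp, seed=rng)
    truth.outlier_gene_ids = [g.gene_id for g in genes if g.is_gc_outlier]

    config = dict(seed=seed, satellite_divergence=satellite_divergence,
                  cM_noise_sd=cM_noise_sd, n_genes=n_genes,
                  n_outliers=n_outliers, outlier_decay_bp=outlier_decay_bp,
                  n_markers_per_chrom=n_markers_per_chrom,
                  base_rate_cM_per_Mb=base_rate_cM_per_Mb)
    return SyntheticGenome(chroms, truth, genes, markers, monomers, config)
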