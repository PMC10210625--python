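# Methods

`censcan` analyses chromosome-scale sequences for satellite-DNA
architecture, centromere location and class, recombination hotspots,
telomere-repeat arrays, the spatial placement of a flagged gene subset,
and large-scale self-similarity.  A paired simulator generates desk-scale
genomes with planted, machine-readable truth so that every estimator can
be validated end to end.  This note records the models, the parameters
that matter, and the design choices made where the design was open.

## Sequence complexity tracks

Four metrics are computed on a regular window grid (window `w`, step `s`):

* **GC content** — (G+C)/(A+C+G+T); default 1-kb non-overlapping windows.
* **Gene density** — count of gene midpoints per window; default 1-Mb
  windows stepping 1 kb.
* **Shannon entropy** — −Σ f_b log₂ f_b over base frequencies among non-N
  positions; 10-kb windows stepping 1 kb; range [0, 2] bits.
* **Linguistic complexity (LC)** — Σₖ V_k / Σₖ min(4ᵏ, L−k+1) for
  k = 1..k_max, where V_k is the number of distinct k-mers observed at
  N-free positions in the window of length L.  k_max defaults to the
  smallest k with 4ᵏ ≥ w (7 for 10-kb windows), the smallest order at
  which the window cannot saturate the vocabulary.  LC is 1 for maximally
  diverse sequence; tandem satellite drops it by an order of magnitude.

Published complexity browsers do not print their exact formula; we use the
standard vocabulary-usage ratio above and rely only on *relative* (trough)
behaviour downstream, which is robust to the particular normalization.
N policy everywhere: windows over 50% N are undefined; k-mers touching an
N are skipped.  Truncated terminal windows are emitted and flagged so that
troughs abutting chromosome ends remain visible.

The sliding distinct-k-mer count is computed in O(n) per k: for each
position the previous occurrence of the same k-mer code is tracked, and a
position contributes a new word exactly to windows starting after that
previous occurrence — accumulated with a difference array (numba kernel).

## Centromere localization

A centromere is called as the trough of the LC track:

1. median-smooth over `smooth_windows` (5) windows;
2. mark windows below `max(quantile(values, 0.05), median − min_depth)`
   with `min_depth = 0.1`.  The quantile adapts to baseline shifts; the
   absolute-depth floor keeps marking correct on chromosomes whose
   repetitive fraction exceeds the quantile (with a chromosome-arm-scale
   satellite expansion the 5% quantile falls *inside* the satellite value
   distribution, and a pure-quantile rule would mark only the deepest
   array);
3. merge marked windows separated by ≤ `merge_gap_windows` (10) steps;
4. refine region edges outward/inward to the outermost window below
   `median − edge_depth` (`edge_depth` 0.02, i.e. just below background),
   which places edges within about one window step of the repeat body;
5. inset interior boundaries by one window length — a marked window only
   proves repetitive content somewhere inside it — except at chromosome
   ends;
6. keep regions with length in `[min_len, max_len]` (defaults 500 kb /
   12 Mb at full scale, 100 kb / 1.5 Mb for the desk-scale simulator whose
   centromeres are ~10× smaller) and depth ≥ `min_depth`; return the
   region with the lowest mean LC (ties: larger, then leftmost).

Boundary resolution of the LC trough itself is limited by the window and
by the monomer length (a window must contain roughly one full monomer
before repetition depresses the vocabulary), so for long monomers
(~1.7 kb) trough edges can be off by a few window steps.  The pipeline
therefore refines centromere boundaries from the annotated monomer
arrays, which localize to base-pair precision.

## Periodicity spectrum and monomer consensus

For every k-mer (default k = 8) occurring ≥ 3 times in a region, the
spacings between consecutive occurrences are tallied (lags 1..max_lag,
default 3000).  In a tandem array of period p every k-mer recurs at
spacing p, so the tally concentrates at p regardless of k; the dominant
period is the arg-max lag ≥ 2.  We aggregate over k-mers rather than
keeping the per-k-mer spectral matrix: the pipeline needs dominant and
co-dominant lags only, and the aggregate is oracle-testable by direct
enumeration.

The dominant-period call abstains (returns none) when the in-range tally
is below 50 **or** when the best lag holds under 10% of it.  The second
condition is needed because chance k-mer recurrences in ~10-kb windows of
non-repetitive sequence can exceed a fixed count floor while remaining
thinly scattered across lags; a genuine array concentrates the tally.

Monomer consensus: the most frequent k-mer whose modal spacing equals (or
exactly divides, for doubled periods) the requested period anchors the
array; slices of one period, taken in a single rotation phase from the
first anchor, are column-majority-voted.  The consensus is a rotation of
the underlying monomer; comparisons are rotation-invariant.

## Monomer mapping and array segmentation

Monomer consensi are tiled greedily: candidate placements (both strands)
come from a dense scan for monomers ≤ 16 bp and from exact seed 8-mers at
~L/6 offsets for longer ones; candidates are scored by Hamming divergence
and accepted without overlap in order of matching bases L·(1−d), then
divergence, then position.  Substitution-only scoring reflects the
simulator's mutation model and the crisp register of young satellites; an
edit-distance mode is intentionally out of scope.  Monomers ≤ 12 bp must
match exactly: at megabase scale a 6-bp motif with one tolerated mismatch
matches ~1% of random positions and would flood the annotation.

Hits merge into same-family runs when separated by at most `gap_bp`
(500 bp) *and* by a small whole number (≤ 12) of monomer lengths — gaps
left by copies too diverged to map keep exact register under
substitution-only divergence, so off-register neighbours are not the same
run.  Run copy counts are span-derived (hits plus register-implied
copies); at zero divergence this equals the hit count exactly, and at 5%
per-base divergence it stays within 2% of truth.  Isolated short-motif
runs sandwiched inside a same-family run pair in register are chance
matches inside unmappable copies and are dropped.

Arrays: chains of ≥ 3 family alternations between two families form one
A-C-type array (the alternation is definitional; published copy-count
ranges are generator defaults, not classifier filters); weakly supported
terminal runs not flush with the chain are trimmed.  Remaining runs with
≥ 10 copies and ≥ 3 real hits become homogeneous arrays typed by family.
Orientation blocks are maximal same-strand hit runs tiling the array;
`n_switches = blocks − 1`.

Centromere class from arrays overlapping the called interval: one array →
simple; two of different type → asymmetric; three with matching outer
type and different middle → symmetric; else unclassified.  Arrays outside
the centromere longer than `min_expansion_bp` (1 Mb) are reported as
expansions with their distance to the centromere.

## Marey-map hotspots

Local recombination rate is the OLS slope of genetic position (cM) on
physical position (Mb) over a sliding window of 8 consecutive markers
stepping one marker.  The genome average is pooled (total cM over total
marker-span Mb) rather than a mean of window slopes, making it robust to
marker-density variation.  Hotspots are merged runs of windows with slope
≥ 5× the genome average; the region fold is the peak window slope over
the average.  Negative slopes (map noise) are retained in output but are
never hotspot-eligible.  Non-recombining chromosomes can be excluded by
name.  Note the planted hotspots in the default genome use folds of 8×
and 10× over background: hotspots themselves inflate the pooled genome
average, so folds barely above the calling threshold would sit at the
boundary of detectability — a property of the definition, not of the
implementation.

## Telomere arrays

Maximal runs of exact tandem copies of TTAGGG (each strand separately)
with ≥ 70 copies are reported; runs starting or ending within 10 kb of a
chromosome end are terminal, the rest interstitial.  Exact counting makes
the published 70-copy threshold crisp (a 69-copy array is rejected); a
mismatch-tolerant mode merging runs interrupted by one variant copy is
available behind a flag.  The threshold is inclusive (≥ 70).

## Spatial statistics and permutation tests

Genes are located by midpoint (symmetric under strand; the alternative
start-based convention changes distances by ~half a gene length, well
below the Mb-scale signals of interest).  All distance statistics are
same-chromosome; genes a statistic cannot score (alone on their
chromosome, on a feature-free chromosome, inside the centromere) are
excluded from the mean and counted in `n_genes_used`.

* nearest-neighbour distance within the subset (alternative: less);
* distance to the nearest feature interval, 0 inside (less);
* arm position, percent from centromere edge (0) to telomere end (100)
  (greater).

The permutation null redraws subsets of the observed size from the full
gene universe without replacement, recomputes the statistic with the same
exclusion rules, and reports the one-sided pseudocount p-value
p = (1 + #extreme)/(n_perm + 1), whose floor 1/(n_perm+1) is attained
when the observed value beats every draw.  Null computation is vectorized
(per-gene value gathers for feature/arm statistics; batched sorted-
midpoint scans for the nearest-neighbour statistic).

## Self-alignment

Maximal exact matches (MEMs) ≥ min_len (default 1000 bp, the length
filter used in dot-plot presentations) are enumerated between the
sequence and itself and between the sequence and its reverse complement,
from a suffix array (numpy prefix doubling) and Kasai LCP over the
concatenation seq·#·revcomp(seq)·$: a suffix pair with longest common
prefix v ≥ min_len and differing preceding characters is exactly one MEM
of length v.  Reverse-complement-half pairs that duplicate forward pairs
are skipped; minus-strand MEMs appear in two mirror forms and are
deduplicated canonically.  The enumerator is exactly equivalent to a
brute-force diagonal-scan oracle (tested on sequences to 2 kb, including
tandem and palindromic cases).

The duplicated-base fraction is the fraction of positions covered by
either coordinate range of any MEM at the length cutoff — both copies of
a duplication count, since "occurring in multiple copies" is a property
of positions.  Exact matching (no gapped alignment) is sufficient for the
coverage statistic on young duplications; sensitivity to diverged copies
is handled by lowering min_len, not by alignment scoring.

## The synthetic genome

The default genome (seeded, byte-reproducible) has four chromosomes of
~8–12 Mb emulating, at roughly one-tenth scale, the repeat architecture
the analyses target: satellite monomer families A (TTAGGG, 6 bp), B
(37 bp), C (127 bp) and D (1747 bp), drawn primitive and with no ≥ 15-bp
cross-family substring; A-C arrays of 10–50 A copies alternating with
5–10 C copies; homogeneous B and D arrays; centromeres of one to three
arrays (simple / asymmetric / symmetric) separated by 6–8-kb
non-repetitive spacers; a 2-Mb intra-arm B expansion in ~20 orientation
blocks (~100-kb mean block, the scaled analogue of a 29-Mb expansion with
~140-kb blocks); a chromosome grown from an ~0.8-Mb seed by four
inverted-suffix-duplication cycles (suffix fraction 0.7–0.95); exact
terminal telomere arrays of 200–500 copies; interstitial telomere arrays
of 70 and 69 copies straddling the reporting threshold; 400 genes of
which 40 GC-outliers cluster at hotspot centers with 100-kb Laplace
decay; and 400 markers per chromosome from a piecewise-constant
recombination map (base 0.5 cM/Mb; hotspots of 500 kb at 10× and 8×).

Defaults: background GC 0.42 (i.i.d.), satellite per-base substitution
rate 0.02 (a young-satellite divergence level; 0 and 0.05 are exercised
in tests), cM noise SD 0.05 (0 for exact-recovery checks).  Planted
telomere runs are flank-guarded so the recorded copy count is exactly the
maximal run.  Mutations are substitutions only by default so copy counts
and coordinates are exact; indel realism is out of scope.

What the simulator does **not** emulate: transposable-element landscapes,
GC isochores, gene structure, transition/transversion bias, indels,
assembly gaps and collapsed duplications.  Passing tests therefore
demonstrate correctness of the estimators under a clean satellite/
duplication model, not robustness to every artefact of real assemblies.

## Problem sizes and determinism

The desk-scale genome (~35 Mb over four chromosomes) analyses end to end
in well under a minute per genome; validation sweeps use 20 generator
seeds.  Oracle-equivalence checks run on sequences to 2 kb over 100
seeds, where brute-force enumeration is exact and fast.  All randomness
flows through explicit numpy Generators; identical seeds give identical
output everywhere, including the permutation engine.

## Known limitations

* Hamming-only monomer scoring misassigns monomers in satellites with
  frequent indels; copy counts rely on substitutional register.
* LC-trough boundaries blur by about one monomer length for very long
  monomers; array-refined boundaries should be preferred.
* MEM enumeration within a suffix-array group is pairwise; sequences that
  are one giant homogeneous tandem array produce quadratically many
  left-maximality checks (satellite arrays are better characterized by
  the spectrum; the self-alignment module targets segmental duplication).
* The permutation engine materializes draw-index chunks; a full
  10⁶-permutation run at several hundred genes takes minutes, not
  seconds.
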