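"""Monomer mapping, array segmentation and centromere classification.

Monomer families (consensus sequences) are tiled greedily onto sequence:
candidate placements on both strands are scored by Hamming divergence
(mutation in these satellites is overwhelmingly substitutional, so
placements stay in register and no gapped alignment is needed), then
accepted best-score-first without overlap.  Hits merge into same-family
runs, runs into arrays:

* alternating short/long two-family run chains (>= 3 alternations) form an
  "AC" array — the defining property is the alternation itself, not the
  particular copy-count ranges seen in any one genome;
* leftover runs with enough copies form homogeneous arrays typed by
  family.

Array copy counts are derived from run spans (``round(span / monomer
length)`` accumulated over runs): with substitution-only divergence the
register is exact, so span arithmetic also counts the occasional copy too
diverged to place as a hit.  At zero divergence this equals the hit count.

Centromere classes follow the array composition: one array = simple, two
arrays of different type = asymmetric, three arrays with matching outer
type and a different middle = symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io_core import Chromosome, Interval, encode_seq, revcomp


@dataclass
class MonomerFamily:
    family_id: str
    consensus: str

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class MonomerHit:
    interval: Interval
    family_id: str
    strand: str
    divergence: float


@dataclass
class _Run:
    family: str
    start: int
    end: int
    hits: list[MonomerHit]
    copy_count: int


@dataclass
class RepeatArray:
    interval: Interval
    array_type: str                 # AC | B | C | D | homogeneous_other
    families: list[str]
    copy_count: int
    n_hits: int
    orientation_blocks: list[tuple[str, int, int]] = field(
        default_factory=list)
    n_orientation_switches: int = 0
    distance_to_centromere: int | None = None
    hits: list[MonomerHit] = field(default_factory=list, repr=False)


@dataclass
class CentromereModel:
    chrom: str
    interval: Interval
    arrays: list[RepeatArray]
    centromere_class: str           # simple | asymmetric | symmetric |
                                    # unclassified


# ---------------------------------------------------------------------------
# monomer mapping
# ---------------------------------------------------------------------------

@njit(cache=True)
def _greedy_tile(starts, lengths, order, n):
    occupied = np.zeros(n, dtype=np.bool_)
    accepted = np.zeros(len(starts), dtype=np.bool_)
    for oi in range(len(order)):
        i = order[oi]
        s = starts[i]
        e = s + lengths[i]
        free = True
        for p in range(s, e):
            if occupied[p]:
                free = False
                break
        if free:
            for p in range(s, e):
                occupied[p] = True
            accepted[i] = True
    return accepted


def _seed_candidates(codes: np.ndarray, cons: np.ndarray, seed_k: int,
                     n_seeds: int) -> np.ndarray:
    """Candidate start positions via exact seed k-mer matches at several
    offsets within the consensus."""
    n, L = len(codes), len(cons)
    if n < L:
        return np.empty(0, dtype=np.int64)
    offsets = np.unique(np.linspace(0, L - seed_k, n_seeds).astype(int))
    cands = []
    c64 = codes.astype(np.int64)
    bad = c64 < 0
    cc = np.where(bad, 0, c64)
    m = n - seed_k + 1
    km = np.zeros(m, dtype=np.int64)
    for j in range(seed_k):
        km = km * 4 + cc[j:j + m]
    for off in offsets:
        target = 0
        for j in range(seed_k):
            target = target * 4 + int(cons[off + j])
        pos = np.nonzero(km == target)[0] - off
        cands.append(pos)
    out = np.unique(np.concatenate(cands))
    return out[(out >= 0) & (out <= n - L)]


def _divergences(codes: np.ndarray, cons: np.ndarray,
                 starts: np.ndarray) -> np.ndarray:
    L = len(cons)
    div = np.empty(len(starts), dtype=np.float64)
    chunk = max(1, int(4e6 // max(L, 1)))
    for c0 in range(0, len(starts), chunk):
        s = starts[c0:c0 + chunk]
        mat = codes[s[:, None] + np.arange(L)]
        div[c0:c0 + chunk] = (mat != cons).mean(axis=1)
    return div


def map_monomers(seq: str | Chromosome, families: list[MonomerFamily],
                 max_divergence: float = 0.2, chrom_name: str | None = None,
                 offset: int = 0, seed_k: int = 8, n_seeds: int = 4,
                 dense_length_cutoff: int = 16,
                 short_exact_cutoff: int = 12) -> list[MonomerHit]:
    """Greedy non-overlapping tiling of monomer consensi onto sequence.

    Candidates come from a dense scan for short monomers and from exact
    seed k-mers for long ones; each candidate is scored by Hamming
    divergence against the consensus (both strands).  Monomers at or below
    ``short_exact_cutoff`` bp must match exactly: even one tolerated
    mismatch makes a ~6-bp motif unspecific at megabase scale.  Accepted
    candidates are placed by descending matching-base count (so a long
    slightly divergent placement outranks a short perfect one embedded
    within it), then by divergence, then leftmost.
    """
    if isinstance(seq, Chromosome):
        chrom_name = chrom_name or seq.name
        codes = seq.codes()
    else:
        chrom_name = chrom_name or "chrom"
        codes = encode_seq(seq)
    if not families:
        raise ValueError("no monomer families")
    n = len(codes)

    starts_all, lens_all, divs_all = [], [], []
    meta: list[tuple[str, str]] = []
    fam_idx_all = []
    for fi, fam in enumerate(families):
        for strand in "+-":
            cons_seq = fam.consensus if strand == "+" else revcomp(
                fam.consensus)
            cons = encode_seq(cons_seq)
            L = len(cons)
            if L <= dense_length_cutoff or L <= seed_k:
                cand = np.arange(0, max(n - L + 1, 0), dtype=np.int64)
            else:
                # long monomers get proportionally more seeds so a copy at
                # high divergence still leaves one exact seed k-mer
                ns = max(n_seeds, min(32, L // 6))
                cand = _seed_candidates(codes, cons, seed_k, ns)
            if len(cand) == 0:
                continue
            div = _divergences(codes, cons, cand)
            thr = 0.0 if L <= short_exact_cutoff else max_divergence
            keep = div <= thr
            cand, div = cand[keep], div[keep]
            starts_all.append(cand)
            lens_all.append(np.full(len(cand), L, dtype=np.int64))
            divs_all.append(div)
            fam_idx_all.append(np.full(len(cand), len(meta), dtype=np.int64))
            meta.append((fam.family_id, strand))

    if not starts_all:
        return []
    starts = np.concatenate(starts_all)
    lengths = np.concatenate(lens_all)
    divs = np.concatenate(divs_all)
    fidx = np.concatenate(fam_idx_all)

    score = lengths * (1.0 - divs)          # matching bases
    order = np.lexsort((starts, divs, -score))
    accepted = _greedy_tile(starts, lengths, order, n)

    hits = []
    for i in np.nonzero(accepted)[0]:
        family_id, strand = meta[fidx[i]]
        hits.append(MonomerHit(
            Interval(chrom_name, int(starts[i]) + offset,
                     int(starts[i] + lengths[i]) + offset, strand),
            family_id, strand, float(divs[i])))
    hits.sort(key=lambda h: h.interval.start)
    return hits


# ---------------------------------------------------------------------------
# run / array segmentation
# ---------------------------------------------------------------------------

MAX_GAP_FILL_COPIES = 12
MIN_RUN_HITS = 3                    # real-hit support for homogeneous arrays


def _gap_fill(gap: int, L: int) -> int | None:
    """Copies implied by an internal run gap, or None when the gap is not
    a small whole number of monomer lengths (mutation in these satellites
    is substitutional, so gaps left by unmappably diverged copies keep
    exact register; anything else is not the same run)."""
    if gap == 0:
        return 0
    k = int(round(gap / L))
    if 1 <= k <= MAX_GAP_FILL_COPIES and abs(gap - k * L) <= max(
            1, int(0.1 * L)):
        return k
    return None


def _runs_from_hits(hits: list[MonomerHit], fam_len: dict[str, int],
                    gap_bp: int) -> list[_Run]:
    runs: list[_Run] = []
    for h in hits:
        merged = False
        if (runs and runs[-1].family == h.family_id
                and h.interval.start - runs[-1].end <= gap_bp):
            fill = _gap_fill(h.interval.start - runs[-1].end,
                             fam_len[h.family_id])
            if fill is not None:
                runs[-1].hits.append(h)
                runs[-1].end = h.interval.end
                runs[-1].copy_count += 1 + fill
                merged = True
        if not merged:
            runs.append(_Run(h.family_id, h.interval.start, h.interval.end,
                             [h], 1))
    return _drop_sandwiched(runs, fam_len)


def _drop_sandwiched(runs: list[_Run], fam_len: dict[str, int]
                     ) -> list[_Run]:
    """Drop weakly supported runs sandwiched inside a same-family run pair
    whose gap is a whole number of that family's monomers: these are
    chance short-motif matches inside copies too diverged to map."""
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            prev, cur, nxt = runs[i - 1], runs[i], runs[i + 1]
            if (len(cur.hits) < MIN_RUN_HITS
                    and prev.family == nxt.family != cur.family):
                fill = _gap_fill(nxt.start - prev.end,
                                 fam_len[prev.family])
                if fill is not None:
                    prev.hits.extend(nxt.hits)
                    prev.end = nxt.end
                    prev.copy_count += fill + nxt.copy_count
                    del runs[i:i + 2]
                    changed = True
                    break
    return runs


def segment_arrays(hits: list[MonomerHit], families: list[MonomerFamily],
                   gap_bp: int = 500, min_copies: int = 10,
                   ac_min_alternations: int = 3) -> list[RepeatArray]:
    """Merge hits into runs and runs into arrays.

    Chains of >= ``ac_min_alternations`` family alternations between two
    families become a single AC array; remaining runs with
    >= ``min_copies`` copies become homogeneous arrays typed by family.
    """
    if not hits:
        return []
    fam_len = {f.family_id: f.length for f in families}
    hits = sorted(hits, key=lambda h: h.interval.start)
    chrom = hits[0].interval.chrom
    runs = _runs_from_hits(hits, fam_len, gap_bp)

    arrays: list[RepeatArray] = []
    used = np.zeros(len(runs), dtype=bool)
    i = 0
    while i < len(runs):
        # try to grow an alternating two-family chain from run i
        j = i
        fams = {runs[i].family}
        while j + 1 < len(runs):
            cur, nxt = runs[j], runs[j + 1]
            gap = nxt.start - cur.end
            if gap > gap_bp:
                break
            if nxt.family != cur.family and (nxt.family in fams
                                             or len(fams) < 2):
                fams.add(nxt.family)
            elif (nxt.family == cur.family
                  and gap < fam_len[cur.family]):
                pass        # sub-monomer gap: a phase shift, same run
            else:
                break
            j += 1
        chain = runs[i:j + 1]
        # trim weakly supported terminal runs not flush with the chain:
        # stray short-motif matches near (not in) the array
        while (len(chain) > 1 and len(chain[0].hits) < MIN_RUN_HITS
               and chain[1].start - chain[0].end > 0):
            chain = chain[1:]
        while (len(chain) > 1 and len(chain[-1].hits) < MIN_RUN_HITS
               and chain[-1].start - chain[-2].end > 0):
            chain = chain[:-1]
        n_alt = sum(a.family != b.family
                    for a, b in zip(chain[:-1], chain[1:]))
        if len({r.family for r in chain}) == 2 and n_alt >= (
                ac_min_alternations):
            # junction gaps are copies of one family too diverged to map;
            # credit them to the adjacent run of the matching family
            for a, b in zip(chain[:-1], chain[1:]):
                gap = b.start - a.end
                if gap <= 0:
                    continue
                for r in sorted((a, b), key=lambda r: fam_len[r.family]):
                    fill = _gap_fill(gap, fam_len[r.family])
                    if fill and fill <= 3:
                        r.copy_count += fill
                        break
            chain_hits = [h for r in chain for h in r.hits]
            arrays.append(_make_array(chrom, "AC", chain, chain_hits))
            kept = {id(r) for r in chain}
            for k in range(i, j + 1):
                if id(runs[k]) in kept:
                    used[k] = True
            i = j + 1
        else:
            i += 1

    for i, r in enumerate(runs):
        if (used[i] or r.copy_count < min_copies
                or len(r.hits) < MIN_RUN_HITS):
            continue
        kind = r.family if r.family in ("B", "C", "D") else (
            "homogeneous_other")
        arrays.append(_make_array(chrom, kind, [r], r.hits))
    arrays.sort(key=lambda a: a.interval.start)
    return arrays


def _make_array(chrom: str, kind: str, runs: list[_Run],
                hits: list[MonomerHit]) -> RepeatArray:
    interval = Interval(chrom, runs[0].start, runs[-1].end)
    arr = RepeatArray(
        interval=interval, array_type=kind,
        families=sorted({r.family for r in runs}),
        copy_count=sum(r.copy_count for r in runs),
        n_hits=len(hits), hits=sorted(hits,
                                      key=lambda h: h.interval.start))
    blocks, n_sw, _ = orientation_blocks(arr, arr.hits)
    arr.orientation_blocks = blocks
    arr.n_orientation_switches = n_sw
    return arr


def orientation_blocks(array: RepeatArray, hits: list[MonomerHit] | None
                       = None) -> tuple[list[tuple[str, int, int]], int,
                                        float]:
    """Maximal same-strand hit runs as (strand, start, end) blocks tiling
    the array interval; returns (blocks, n_switches, mean_block_bp)."""
    hits = hits if hits is not None else array.hits
    hits = sorted(hits, key=lambda h: h.interval.start)
    if not hits:
        return [], 0, float(array.interval.length)
    blocks: list[list] = []
    for h in hits:
        if blocks and blocks[-1][0] == h.strand:
            continue
        blocks.append([h.strand, h.interval.start])
    out = []
    for bi, (strand, hstart) in enumerate(blocks):
        start = array.interval.start if bi == 0 else hstart
        end = (array.interval.end if bi == len(blocks) - 1
               else blocks[bi + 1][1])
        out.append((strand, int(start), int(end)))
    n_switches = len(out) - 1
    return out, n_switches, array.interval.length / len(out)


# ---------------------------------------------------------------------------
# centromere classification & expansions
# ---------------------------------------------------------------------------

def classify_centromere(centromere_interval: Interval,
                        arrays: list[RepeatArray]) -> CentromereModel:
    """Class from the ordered array composition inside the centromere."""
    inside = sorted((a for a in arrays
                     if a.interval.overlaps(centromere_interval)),
                    key=lambda a: a.interval.start)
    types = [a.array_type for a in inside]
    if len(types) == 1:
        cls = "simple"
    elif len(types) == 2 and types[0] != types[1]:
        cls = "asymmetric"
    elif (len(types) == 3 and types[0] == types[2]
          and types[1] != types[0]):
        cls = "symmetric"
    else:
        cls = "unclassified"
    return CentromereModel(centromere_interval.chrom, centromere_interval,
                           inside, cls)


def detect_expansions(arrays: list[RepeatArray],
                      centromere_interval: Interval,
                      min_expansion_bp: int = 1_000_000
                      ) -> list[RepeatArray]:
    """Large arrays outside the centromere (e.g. an intra-arm satellite
    expansion), annotated with their distance to the centromere."""
    out = []
    for a in arrays:
        if a.interval.overlaps(centromere_interval):
            continue
        if a.interval.length <= min_expansion_bp:
            continue
        if a.interval.end <= centromere_interval.start:
            d = centromere_interval.start - a.interval.end
        else:
            d = a.interval.start - centromere_interval.end
        a.distance_to_centromere = int(max(d, 0))
        out.append(a)
    return out


def annotate_regions(chrom: Chromosome, regions: list[Interval],
                     families: list[MonomerFamily],
                     max_divergence: float = 0.2, margin: int = 10_000,
                     gap_bp: int = 500, min_copies: int = 10,
                     ac_min_alternations: int = 3
                     ) -> tuple[list[MonomerHit], list[RepeatArray]]:
    """Map monomers within candidate regions (± margin) of one chromosome
    and segment the combined hits into arrays."""
    spans: list[list[int]] = []
    for reg in sorted(regions, key=lambda r: r.start):
        s = max(reg.start - margin, 0)
        e = min(reg.end + margin, chrom.length)
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    hits: list[MonomerHit] = []
    for s, e in spans:
        sub = chrom.seq[s:e]
        hits.extend(map_monomers(sub, families,
                                 max_divergence=max_divergence,
                                 chrom_name=chrom.name, offset=s))
    arrays = segment_arrays(hits, families, gap_bp=gap_bp,
                            min_copies=min_copies,
                            ac_min_alternations=ac_min_alternations)
    return hits, arrays
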