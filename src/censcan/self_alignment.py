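"""Self-alignment via maximal exact matches (MEMs) and the duplicated-base
fraction.

A MEM is an exact match between two sequence positions that cannot be
extended in either direction.  We enumerate all MEMs of length >=
``min_len`` between a chromosome and itself (excluding the identity
diagonal) and between the chromosome and its reverse complement, from a
suffix array + LCP structure over the concatenation of the sequence and
its reverse complement:

* every suffix pair whose longest common prefix is ``v >= min_len`` and
  whose preceding characters differ is exactly one MEM of length ``v``
  (the LCP gives right-maximality for free, the preceding-character test
  left-maximality);
* pairs where both suffixes fall in the reverse-complement half duplicate
  forward-forward MEMs and are skipped; reverse-strand MEMs appear in two
  mirror representations and are deduplicated canonically.

The duplicated-base fraction is the fraction of positions covered by
either coordinate range of any MEM at or above the length cutoff — the
statistic behind "X% of bases occur in multiple copies" summaries of
dot-plot self-alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .io_core import Chromosome, encode_seq


@dataclass(frozen=True)
class MatchSegment:
    """One MEM; ``a`` <= ``b`` canonically, both 0-based half-open."""

    chrom: str
    a: tuple[int, int]
    b: tuple[int, int]
    strand: str
    length: int


def suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    n = len(t)
    ranks = np.asarray(t, dtype=np.int64)
    sa = np.argsort(ranks, kind="stable")
    r = np.empty(n, dtype=np.int64)
    rs = ranks[sa]
    changed = np.empty(n, dtype=np.int64)
    changed[0] = 0
    changed[1:] = rs[1:] != rs[:-1]
    r[sa] = np.cumsum(changed)
    ranks = r
    k = 1
    while ranks[sa[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:n - k] = ranks[k:]
        sa = np.lexsort((key2, ranks))
        r1 = ranks[sa]
        r2 = key2[sa]
        changed[0] = 0
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        newr = np.cumsum(changed)
        ranks = np.empty(n, dtype=np.int64)
        ranks[sa] = newr
        k *= 2
        if k >= n:
            break
    return sa


@njit(cache=True)
def _kasai_lcp(t, sa):
    n = len(t)
    rank = np.empty(n, dtype=np.int64)
    for i in range(n):
        rank[sa[i]] = i
    lcp = np.zeros(n, dtype=np.int64)      # lcp[i] = lcp(sa[i-1], sa[i])
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and t[i + h] == t[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=True)
def _enumerate_mem_pairs(sa, lcp, prevchar, is_rc, min_len, out_p, out_q,
                         out_len, count_only):
    """All left-maximal suffix pairs with pairwise LCP >= min_len.

    Maximal SA intervals with LCP >= min_len are split recursively at
    their minimum-LCP position: every pair crossing the split has pairwise
    LCP equal to that minimum.  rc/rc pairs are skipped.
    """
    N = len(sa)
    total = 0
    stack_a = np.empty(N + 2, dtype=np.int64)
    stack_b = np.empty(N + 2, dtype=np.int64)
    i = 1
    while i < N:
        if lcp[i] < min_len:
            i += 1
            continue
        lo = i - 1
        j = i
        while j < N and lcp[j] >= min_len:
            j += 1
        hi = j - 1                        # group: suffixes sa[lo..hi]
        sp = 0
        stack_a[sp] = lo
        stack_b[sp] = hi
        sp += 1
        while sp > 0:
            sp -= 1
            a = stack_a[sp]
            b = stack_b[sp]
            if a >= b:
                continue
            mpos = a + 1
            v = lcp[a + 1]
            for tpos in range(a + 2, b + 1):
                if lcp[tpos] < v:
                    v = lcp[tpos]
                    mpos = tpos
            for p in range(a, mpos):
                pp = sa[p]
                rc_p = is_rc[pp]
                pc_p = prevchar[pp]
                for q in range(mpos, b + 1):
                    qq = sa[q]
                    if rc_p and is_rc[qq]:
                        continue
                    if pc_p == prevchar[qq]:
                        continue
                    if not count_only:
                        out_p[total] = pp
                        out_q[total] = qq
                        out_len[total] = v
                    total += 1
            stack_a[sp] = a
            stack_b[sp] = mpos - 1
            sp += 1
            stack_a[sp] = mpos
            stack_b[sp] = b
            sp += 1
        i = j + 1
    return total


def find_self_matches(seq: str | Chromosome, min_len: int = 1000,
                      chrom_name: str | None = None) -> list[MatchSegment]:
    """All MEMs of length >= min_len within a sequence and between the
    sequence and its reverse complement.

    Each unordered pair is reported once, in canonical (a <= b) order; the
    identity diagonal is excluded.  N characters are made unique so
    matches never run through assembly gaps.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if isinstance(seq, Chromosome):
        chrom_name = chrom_name or seq.name
        codes = seq.codes().astype(np.int64)
    else:
        chrom_name = chrom_name or "chrom"
        codes = encode_seq(seq).astype(np.int64)
    n = len(codes)
    if n < min_len:
        return []

    fwd = codes.copy()
    rc = 3 - codes[::-1]
    # make each N unique so it matches nothing (not even another N)
    for arr, base in ((fwd, 10), (rc, 10 + n)):
        bad = np.nonzero((arr < 0) | (arr > 3))[0]
        arr[bad] = base + np.arange(len(bad))
    t = np.concatenate((fwd, [4], rc, [5]))
    N = len(t)

    sa = suffix_array(t)
    lcp = _kasai_lcp(t, sa)
    prevchar = np.empty(N, dtype=np.int64)
    prevchar[0] = -2
    prevchar[1:] = t[:-1]
    is_rc = np.zeros(N, dtype=np.bool_)
    is_rc[n + 1:] = True

    n_pairs = _enumerate_mem_pairs(sa, lcp, prevchar, is_rc, min_len,
                                   np.empty(0, np.int64),
                                   np.empty(0, np.int64),
                                   np.empty(0, np.int64), True)
    out_p = np.empty(n_pairs, dtype=np.int64)
    out_q = np.empty(n_pairs, dtype=np.int64)
    out_len = np.empty(n_pairs, dtype=np.int64)
    _enumerate_mem_pairs(sa, lcp, prevchar, is_rc, min_len, out_p, out_q,
                         out_len, False)

    segments: set[tuple] = set()
    for p, q, v in zip(out_p, out_q, out_len):
        p, q, v = int(p), int(q), int(v)
        p_rc, q_rc = p > n, q > n
        if p_rc:
            p, q = q, p
            p_rc, q_rc = q_rc, p_rc
        if not q_rc:                       # forward / forward
            a = (p, p + v)
            b = (q, q + v)
            strand = "+"
            if a == b:
                continue
        else:                              # forward / reverse-complement
            r = q - n - 1
            a = (p, p + v)
            b = (n - r - v, n - r)
            strand = "-"
        if b < a:
            a, b = b, a
        segments.add((a, b, strand, v))
    return [MatchSegment(chrom_name, a, b, s, v)
            for a, b, s, v in sorted(segments)]


def duplicated_fraction(segments: list[MatchSegment], seq_len: int,
                        min_len: int = 1000) -> float:
    """Fraction of positions covered by either side of any MEM with
    length >= min_len."""
    if seq_len <= 0:
        raise ValueError("seq_len must be positive")
    diff = np.zeros(seq_len + 1, dtype=np.int32)
    for seg in segments:
        if seg.length < min_len:
            continue
        for s, e in (seg.a, seg.b):
            diff[max(s, 0)] += 1
            diff[min(e, seq_len)] -= 1
    covered = int((np.cumsum(diff[:seq_len]) > 0).sum())
    return covered / seq_len


def segments_frame(segments: list[MatchSegment]) -> pd.DataFrame:
    """Paired-interval table suitable for dot-plot rendering."""
    return pd.DataFrame({
        "chrom": [s.chrom for s in segments],
        "a_start": [s.a[0] for s in segments],
        "a_end": [s.a[1] for s in segments],
        "b_start": [s.b[0] for s in segments],
        "b_end": [s.b[1] for s in segments],
        "strand": [s.strand for s in segments],
        "length": [s.length for s in segments],
    })


def write_segments(path: str | Path, segments: list[MatchSegment]) -> None:
    segments_frame(segments).to_csv(path, sep="\t", index=False)
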