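"""Sliding-window sequence tracks.

Four per-chromosome metrics over a regular window grid:

* GC content (default 1-kb non-overlapping windows),
* gene density (1-Mb windows stepping 1 kb; count of gene midpoints),
* Shannon entropy of base composition (10-kb windows stepping 1 kb),
* linguistic complexity (10-kb windows stepping 1 kb).

Linguistic complexity of a window of length L is the vocabulary-usage ratio

    LC = ( sum_{k=1..k_max} V_k ) / ( sum_{k=1..k_max} min(4^k, L-k+1) )

where V_k is the number of distinct k-mers observed at N-free positions and
k_max defaults to the smallest k with 4^k >= window length (7 for 10-kb
windows).  LC is 1 for a maximally diverse window and approaches 0 for
highly repetitive sequence; satellite arrays appear as deep troughs.

N policy: windows with more than 50% N are undefined (NaN); k-mers touching
an N are skipped.  Truncated terminal windows are emitted, not dropped, so
troughs abutting chromosome ends stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .io_core import Chromosome, GeneRecord

MAX_N_FRACTION = 0.5


@dataclass
class WindowTrack:
    """Per-window metric values on a regular (window_bp, step_bp) grid."""

    chrom: str
    metric: str
    window_bp: int
    step_bp: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def truncated(self) -> np.ndarray:
        return (self.ends - self.starts) < self.window_bp

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.starts, "end": self.ends,
             "value": self.values}
        )

    def write_tsv(self, path: str | Path) -> None:
        """4-column bedGraph-style TSV (undefined values as NA)."""
        self.to_dataframe().to_csv(path, sep="\t", index=False, header=False,
                                   na_rep="NA")


def window_grid(length: int, window_bp: int,
                step_bp: int) -> tuple[np.ndarray, np.ndarray]:
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window_bp and step_bp must be >= 1")
    starts = np.arange(0, max(length, 1), step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return starts, ends


def _base_cumsums(codes: np.ndarray) -> np.ndarray:
    """(5, n+1) cumulative counts of A,C,G,T,N."""
    n = len(codes)
    cs = np.zeros((5, n + 1), dtype=np.int64)
    for b in range(4):
        cs[b, 1:] = np.cumsum(codes == b)
    cs[4, 1:] = np.cumsum(codes < 0)
    return cs


def gc_track(chrom: Chromosome, window_bp: int = 1000,
             step_bp: int = 1000) -> WindowTrack:
    """Fraction (G+C)/(A+C+G+T) per window; NaN where >50% N."""
    codes = chrom.codes()
    starts, ends = window_grid(chrom.length, window_bp, step_bp)
    cs = _base_cumsums(codes)
    cnt = cs[:, ends] - cs[:, starts]          # (5, n_windows)
    acgt = cnt[:4].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (cnt[1] + cnt[2]) / acgt
    length = (ends - starts).astype(float)
    vals[cnt[4] > MAX_N_FRACTION * length] = np.nan
    vals[acgt == 0] = np.nan
    return WindowTrack(chrom.name, "gc", window_bp, step_bp, starts, ends,
                       vals)


def entropy_track(chrom: Chromosome, window_bp: int = 10_000,
                  step_bp: int = 1000) -> WindowTrack:
    """Shannon entropy (bits) of base frequencies among non-N positions."""
    codes = chrom.codes()
    starts, ends = window_grid(chrom.length, window_bp, step_bp)
    cs = _base_cumsums(codes)
    cnt = cs[:, ends] - cs[:, starts]
    acgt = cnt[:4].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = cnt[:4] / acgt
        h = np.where(f > 0, -f * np.log2(f), 0.0).sum(axis=0)
    length = (ends - starts).astype(float)
    h[cnt[4] > MAX_N_FRACTION * length] = np.nan
    h[acgt == 0] = np.nan
    return WindowTrack(chrom.name, "entropy", window_bp, step_bp, starts,
                       ends, h)


def gene_density_track(chrom_length: int, genes: Sequence[GeneRecord],
                       window_bp: int = 1_000_000, step_bp: int = 1000,
                       chrom_name: str | None = None) -> WindowTrack:
    """Count of gene midpoints per window (half-open containment)."""
    if chrom_name is None:
        chrom_name = genes[0].interval.chrom if genes else "chrom"
    mids = np.sort([g.interval.midpoint for g in genes
                    if g.interval.chrom == chrom_name])
    starts, ends = window_grid(chrom_length, window_bp, step_bp)
    counts = (np.searchsorted(mids, ends, side="left")
              - np.searchsorted(mids, starts, side="left")).astype(float)
    return WindowTrack(chrom_name, "gene_density", window_bp, step_bp,
                       starts, ends, counts)


# ---------------------------------------------------------------------------
# linguistic complexity
# ---------------------------------------------------------------------------

def default_k_max(window_bp: int) -> int:
    """Smallest k with 4**k >= window_bp (7 for 10-kb windows)."""
    k = 1
    while 4 ** k < window_bp:
        k += 1
    return k


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes (base-4); -1 where the k-mer touches N."""
    n = len(codes)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    bad = (c < 0).astype(np.int64)
    cc = np.where(c < 0, 0, c)
    out = np.zeros(m, dtype=np.int64)
    for j in range(k):
        out = out * 4 + cc[j:j + m]
    cs = np.concatenate(([0], np.cumsum(bad)))
    any_n = (cs[k:] - cs[:-k]) > 0
    out[any_n] = -1
    return out


@njit(cache=True)
def _window_distinct(kmers, code_space, window_bp, step_bp, k, n_windows):
    """Distinct valid k-mers per window over the regular start grid.

    For each k-mer position i, let prev(i) be the previous position with
    the same code.  Position i contributes a *new* k-mer to exactly the
    windows starting in (prev(i), i] that also cover i, a contiguous range
    of grid indices accumulated with a difference array.
    """
    m = kmers.shape[0]
    last = np.full(code_space, -1, dtype=np.int64)
    diff = np.zeros(n_windows + 1, dtype=np.int64)
    span = window_bp - k
    for i in range(m):
        c = kmers[i]
        if c < 0:
            continue
        prev = last[c]
        last[c] = i
        lo = i - span
        if prev + 1 > lo:
            lo = prev + 1
        if lo < 0:
            lo = 0
        lo_idx = (lo + step_bp - 1) // step_bp
        hi_idx = i // step_bp
        if hi_idx > n_windows - 1:
            hi_idx = n_windows - 1
        if lo_idx <= hi_idx:
            diff[lo_idx] += 1
            diff[hi_idx + 1] -= 1
    out = np.empty(n_windows, dtype=np.int64)
    acc = 0
    for w in range(n_windows):
        acc += diff[w]
        out[w] = acc
    return out


def linguistic_complexity_track(chrom: Chromosome, window_bp: int = 10_000,
                                step_bp: int = 1000,
                                k_max: int | None = None) -> WindowTrack:
    """Vocabulary-usage ratio per window, in (0, 1]."""
    if k_max is None:
        k_max = default_k_max(window_bp)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    codes = chrom.codes()
    starts, ends = window_grid(chrom.length, window_bp, step_bp)
    n_windows = len(starts)
    lengths = ends - starts

    num = np.zeros(n_windows, dtype=np.int64)
    den = np.zeros(n_windows, dtype=np.int64)
    for k in range(1, k_max + 1):
        km = kmer_codes(codes, k)
        if len(km):
            num += _window_distinct(km, 4 ** k, window_bp, step_bp, k,
                                    n_windows)
        den += np.minimum(4 ** k, np.maximum(lengths - k + 1, 0))

    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / den.astype(float)
    n_cnt = np.cumsum(np.concatenate(([0], (codes < 0).astype(np.int64))))
    n_in_win = n_cnt[ends] - n_cnt[starts]
    vals[n_in_win > MAX_N_FRACTION * lengths] = np.nan
    vals[den == 0] = np.nan
    return WindowTrack(chrom.name, "linguistic_complexity", window_bp,
                       step_bp, starts, ends, vals)


def linguistic_complexity_of(seq: str, k_max: int | None = None) -> float:
    """LC of a whole sequence treated as a single window (test/debug aid)."""
    track = linguistic_complexity_track(
        Chromosome("w", seq), window_bp=len(seq), step_bp=max(len(seq), 1),
        k_max=k_max)
    return float(track.values[0])
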