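"""Tandem-repeat periodicity spectra, monomer consensus, telomere arrays.

The spectrum generalizes the k-mer interval-tally idea behind tandem-repeat
periodicity browsers: for every k-mer occurring at least ``min_kmer_count``
times in a region, the distances between consecutive occurrence start
positions are tallied.  In a tandem array with monomer length p every
k-mer recurs with spacing p, so the tally concentrates at lag p regardless
of k (for k up to the monomer length), and the dominant lag recovers the
monomer length directly.  We aggregate the tally over all k-mers rather
than keeping a per-k-mer matrix; the per-k-mer breakdown is available via
``per_kmer=True`` for diagnostic dumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import Chromosome, Interval, encode_seq, revcomp

DOMINANT_COUNT_FLOOR = 50


@dataclass
class PeriodSpectrum:
    """Aggregate consecutive-occurrence interval tally.

    ``counts[lag]`` is the number of consecutive same-k-mer occurrence
    pairs at that spacing, for lags 1..max_lag.
    """

    k: int
    max_lag: int
    counts: np.ndarray                      # length max_lag + 1, index = lag
    region: Interval | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def write_tsv(self, path: str | Path) -> None:
        lags = np.nonzero(self.counts)[0]
        pd.DataFrame({"lag": lags, "count": self.counts[lags]}).to_csv(
            path, sep="\t", index=False)


def _kmer_positions(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, positions) of valid (N-free) k-mers."""
    codes = encode_seq(seq).astype(np.int64)
    n = len(codes)
    m = n - k + 1
    bad = codes < 0
    km = np.zeros(m, dtype=np.int64)
    cc = np.where(bad, 0, codes)
    for j in range(k):
        km = km * 4 + cc[j:j + m]
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return km[pos], pos


def interval_spectrum(seq: str, k: int = 8, max_lag: int = 3000,
                      min_kmer_count: int = 3,
                      region: Interval | None = None) -> PeriodSpectrum:
    """Tally consecutive-occurrence spacings of all recurrent k-mers.

    k-mers containing N are skipped; spacings above ``max_lag`` are
    ignored.  Raises if the sequence is not longer than k.
    """
    if len(seq) <= k:
        raise ValueError(f"sequence length {len(seq)} <= k={k}")
    km, pos = _kmer_positions(seq, k)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    if len(km) == 0:
        return PeriodSpectrum(k, max_lag, counts, region)
    order = np.argsort(km, kind="stable")     # positions ascending per k-mer
    km_s, pos_s = km[order], pos[order]
    same = km_s[1:] == km_s[:-1]
    # per-k-mer occurrence counts, mapped to each consecutive pair
    boundaries = np.concatenate(([0], np.nonzero(~same)[0] + 1, [len(km_s)]))
    sizes = np.diff(boundaries)
    size_per_elem = np.repeat(sizes, sizes)
    gaps = pos_s[1:] - pos_s[:-1]
    keep = same & (size_per_elem[1:] >= min_kmer_count) & (gaps >= 1) & (
        gaps <= max_lag)
    np.add.at(counts, gaps[keep], 1)
    return PeriodSpectrum(k, max_lag, counts, region)


def dominant_period(spectrum: PeriodSpectrum, min_lag: int = 2,
                    count_floor: int = DOMINANT_COUNT_FLOOR,
                    min_fraction: float = 0.1) -> int | None:
    """Highest-count lag in [min_lag, max_lag]; ties break to the smallest
    lag.

    None when the tally in range is below ``count_floor`` or when the best
    lag holds less than ``min_fraction`` of it: background coincidences in
    non-repetitive sequence scatter thinly across lags (no lag collects
    even 5% of the tally), while a genuine tandem array concentrates the
    tally at its period.
    """
    c = spectrum.counts[min_lag:]
    total = c.sum()
    if total < count_floor:
        return None
    best = int(np.argmax(c))
    if c[best] < min_fraction * total:
        return None
    return best + min_lag


def top_periods(spectrum: PeriodSpectrum, n: int,
                min_lag: int = 2) -> list[tuple[int, int]]:
    """The n highest-count lags, by descending count then ascending lag."""
    lags = np.arange(min_lag, spectrum.max_lag + 1)
    c = spectrum.counts[min_lag:]
    nz = c > 0
    lags, c = lags[nz], c[nz]
    order = np.lexsort((lags, -c))
    return [(int(lags[i]), int(c[i])) for i in order[:n]]


def monomer_consensus(seq: str, period: int, k: int = 8) -> str:
    """Per-column majority consensus of a tandem array with known period.

    The most frequent k-mer whose modal consecutive spacing equals the
    period anchors the array; the sequence is cut at anchor occurrences and
    slices of exactly ``period`` bp are column-voted.  The returned
    consensus has length ``period`` and is an arbitrary rotation of the
    underlying monomer.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    km, pos = _kmer_positions(seq, k)
    order = np.argsort(km, kind="stable")
    km_s, pos_s = km[order], pos[order]
    boundaries = np.concatenate(([0], np.nonzero(km_s[1:] != km_s[:-1])[0]
                                 + 1, [len(km_s)]))
    best_code, best_count = None, 0
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        if b1 - b0 <= best_count:
            continue
        gaps = np.diff(pos_s[b0:b1])
        if len(gaps) == 0:
            continue
        vals, cnts = np.unique(gaps, return_counts=True)
        # modal spacing equal to (or an exact divisor of) the requested
        # period anchors it; the divisor case covers doubled periods
        if period % vals[np.argmax(cnts)] == 0:
            best_code, best_count = km_s[b0], b1 - b0
    if best_code is None:
        raise ValueError("no anchor k-mer with modal spacing == period")
    anchors = pos[km == best_code]
    # keep one rotation phase: anchor occurrences spaced a whole number of
    # periods from the first, with a full period of sequence after them
    starts = anchors[(anchors - anchors[0]) % period == 0]
    starts = starts[starts + period <= len(seq)]
    if len(starts) < 3:
        raise ValueError("fewer than 3 full-length monomer slices")
    codes = encode_seq(seq).astype(np.int64)
    slices = codes[starts[:, None] + np.arange(period)]
    cons = np.empty(period, dtype=np.int64)
    for col in range(period):
        cons[col] = np.bincount(slices[:, col], minlength=4).argmax()
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[cons].tobytes().decode()


# ---------------------------------------------------------------------------
# telomere arrays
# ---------------------------------------------------------------------------

@dataclass
class TelomereArray:
    interval: Interval
    copy_count: int
    strand: str
    kind: str                               # terminal | interstitial


def _motif_runs(codes: np.ndarray, motif_codes: np.ndarray,
                tolerate_variant_copy: bool) -> list[tuple[int, int]]:
    """Maximal runs of exact tandem motif copies: (start, n_copies)."""
    m = len(motif_codes)
    n = len(codes)
    if n < m:
        return []
    hit = np.ones(n - m + 1, dtype=bool)
    for j in range(m):
        hit &= codes[j:n - m + 1 + j] == motif_codes[j]
    occ = np.nonzero(hit)[0]
    if len(occ) == 0:
        return []
    # tandem chains: consecutive occurrences spaced exactly m
    step = np.diff(occ)
    breaks = np.nonzero(step != m)[0]
    runs = []
    start_idx = 0
    for b in np.concatenate((breaks, [len(occ) - 1])):
        runs.append((int(occ[start_idx]), int(b - start_idx + 1)))
        start_idx = b + 1
    if tolerate_variant_copy:
        merged = [runs[0]]
        for s, c in runs[1:]:
            ps, pc = merged[-1]
            if s - (ps + pc * m) == m:       # exactly one variant copy
                merged[-1] = (ps, pc + 1 + c)
            else:
                merged.append((s, c))
        runs = merged
    return runs


def telomere_arrays(chrom: Chromosome, motif: str = "TTAGGG",
                    min_copies: int = 70, terminal_margin: int = 10_000,
                    tolerate_variant_copy: bool = False
                    ) -> list[TelomereArray]:
    """Maximal exact tandem arrays of the telomere motif (both strands)
    with at least ``min_copies`` copies.

    Arrays starting or ending within ``terminal_margin`` of a chromosome
    end are terminal, the rest interstitial.  The optional
    mismatch-tolerant mode merges runs interrupted by a single variant
    copy.
    """
    if not motif:
        raise ValueError("empty motif")
    codes = chrom.codes()
    m = len(motif)
    out: list[TelomereArray] = []
    for strand, mot in (("+", motif), ("-", revcomp(motif))):
        for start, copies in _motif_runs(codes, encode_seq(mot),
                                         tolerate_variant_copy):
            if copies < min_copies:
                continue
            end = start + copies * m
            kind = ("terminal"
                    if start < terminal_margin
                    or chrom.length - end < terminal_margin
                    else "interstitial")
            out.append(TelomereArray(Interval(chrom.name, start, end),
                                     copies, strand, kind))
    out.sort(key=lambda t: t.interval.start)
    return out
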