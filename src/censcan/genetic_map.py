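"""Marey-map recombination-rate estimation and hotspot calling.

A Marey map plots genetic position (cM) against physical position (bp);
its local slope is the recombination rate in cM/Mb.  Rates are estimated
by ordinary least squares over a sliding window of ``w`` consecutive
markers (default 8) stepping one marker at a time.  Hotspots are merged
runs of windows whose slope reaches ``fold`` (default 5) times the pooled
genome-average rate (total map length over total marker span).
Non-recombining chromosomes (e.g. a Y) can be excluded by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneticMarker, Interval

logger = logging.getLogger("censcan")


@dataclass
class RateWindow:
    chrom: str
    first_index: int
    last_index: int
    span: Interval
    slope: float                    # cM/Mb


@dataclass
class HotspotRegion:
    interval: Interval
    peak_rate: float                # cM/Mb
    fold: float


def _by_chrom(markers: Sequence[GeneticMarker]
              ) -> dict[str, list[GeneticMarker]]:
    out: dict[str, list[GeneticMarker]] = {}
    for m in markers:
        out.setdefault(m.chrom, []).append(m)
    for chrom, ms in out.items():
        ms.sort(key=lambda m: m.bp)
        bps = [m.bp for m in ms]
        if len(set(bps)) != len(bps):
            raise ValueError(f"duplicate marker positions on {chrom}; "
                             "collapse them first (see read_markers)")
    return out


def marey_rates(markers: Sequence[GeneticMarker],
                w: int = 8) -> list[RateWindow]:
    """OLS slope of cM on Mb for every window of w consecutive markers.

    Chromosomes with fewer than w markers produce no windows (logged).
    """
    if w < 2:
        raise ValueError("window size w must be >= 2")
    windows: list[RateWindow] = []
    for chrom, ms in _by_chrom(markers).items():
        n = len(ms)
        if n < w:
            logger.warning("chromosome %s has %d < %d markers; skipped",
                           chrom, n, w)
            continue
        x = np.array([m.bp for m in ms], dtype=float) / 1e6    # Mb
        y = np.array([m.cM for m in ms], dtype=float)
        cx = np.concatenate(([0.0], np.cumsum(x)))
        cy = np.concatenate(([0.0], np.cumsum(y)))
        cxx = np.concatenate(([0.0], np.cumsum(x * x)))
        cxy = np.concatenate(([0.0], np.cumsum(x * y)))
        i = np.arange(n - w + 1)
        sx = cx[i + w] - cx[i]
        sy = cy[i + w] - cy[i]
        sxx = cxx[i + w] - cxx[i]
        sxy = cxy[i + w] - cxy[i]
        slope = (w * sxy - sx * sy) / (w * sxx - sx * sx)
        for j in range(n - w + 1):
            windows.append(RateWindow(
                chrom, j, j + w - 1,
                Interval(chrom, ms[j].bp, ms[j + w - 1].bp),
                float(slope[j])))
    return windows


def genome_average_rate(markers: Sequence[GeneticMarker],
                        exclude: Iterable[str] = ()) -> float:
    """Pooled genome rate: sum of per-chromosome map lengths (cM) over the
    sum of per-chromosome marker spans (Mb)."""
    exclude = set(exclude)
    total_cm = 0.0
    total_mb = 0.0
    n_used = 0
    for chrom, ms in _by_chrom(markers).items():
        if chrom in exclude or len(ms) < 2:
            continue
        cms = [m.cM for m in ms]
        total_cm += max(cms) - min(cms)
        total_mb += (ms[-1].bp - ms[0].bp) / 1e6
        n_used += 1
    if n_used == 0 or total_mb == 0:
        raise ValueError("no chromosome with >= 2 markers")
    return total_cm / total_mb


def call_hotspots(rate_windows: Sequence[RateWindow], avg_rate: float,
                  fold: float = 5.0) -> list[HotspotRegion]:
    """Merge qualifying windows (slope >= fold * genome average) into
    hotspot regions; region fold is the peak window slope over the
    average.  Negative-slope windows are never eligible."""
    if avg_rate <= 0:
        raise ValueError("avg_rate must be positive")
    thr = fold * avg_rate
    regions: list[HotspotRegion] = []
    for chrom in sorted({rw.chrom for rw in rate_windows}):
        qual = sorted((rw for rw in rate_windows
                       if rw.chrom == chrom and rw.slope >= thr),
                      key=lambda rw: rw.span.start)
        current: list[RateWindow] = []
        for rw in qual:
            if current and rw.span.start <= current[-1].span.end:
                current.append(rw)
            else:
                if current:
                    regions.append(_merge(current, avg_rate))
                current = [rw]
        if current:
            regions.append(_merge(current, avg_rate))
    return regions


def _merge(windows: list[RateWindow], avg_rate: float) -> HotspotRegion:
    peak = max(rw.slope for rw in windows)
    return HotspotRegion(
        Interval(windows[0].chrom, windows[0].span.start,
                 max(rw.span.end for rw in windows)),
        peak, peak / avg_rate)


def rate_windows_frame(windows: Sequence[RateWindow]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [rw.chrom for rw in windows],
        "start": [rw.span.start for rw in windows],
        "end": [rw.span.end for rw in windows],
        "slope_cM_per_Mb": [rw.slope for rw in windows],
    })
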