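"""Spatial statistics for a flagged gene subset and their permutation nulls.

Four observed statistics over a gene subset (genes located by midpoint):

* nearest-neighbor distance: mean distance from each subset gene to the
  closest other subset gene on the same chromosome;
* feature distance: mean distance from each gene midpoint to the nearest
  feature interval (0 inside a feature) — features are e.g. recombination
  hotspots or telomere-repeat arrays;
* arm position: mean position along the chromosome arm, in percent from
  the centromere edge (0) to the telomere end (100);
* the permutation engine draws equally sized random gene sets from the
  full gene universe (without replacement within a draw), recomputes the
  statistic with identical exclusion rules, and reports the one-sided
  pseudocount p-value  p = (1 + #extreme) / (n_perm + 1).

Genes that a statistic cannot score (alone on their chromosome; on a
chromosome without features; inside the centromere) are excluded from the
mean and reported via ``n_genes_used``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_core import GeneRecord, Interval

_CHROM_STRIDE = 1 << 40             # > any chromosome length, for encoding


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    direction: str                  # "less" | "greater"
    seed: int
    n_genes_used: int


# ---------------------------------------------------------------------------
# observed statistics
# ---------------------------------------------------------------------------

def _mids_and_chroms(genes: Sequence[GeneRecord]
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    chrom_names = sorted({g.interval.chrom for g in genes})
    index = {c: i for i, c in enumerate(chrom_names)}
    mids = np.array([g.interval.midpoint for g in genes], dtype=float)
    codes = np.array([index[g.interval.chrom] for g in genes],
                     dtype=np.int64)
    return mids, codes, chrom_names


def _nn_values(mids: np.ndarray, chrom_codes: np.ndarray) -> np.ndarray:
    """Per-gene distance to the nearest other gene on the same chromosome
    (NaN for genes alone on their chromosome)."""
    order = np.argsort(chrom_codes * np.float64(_CHROM_STRIDE) + mids)
    m = mids[order]
    c = chrom_codes[order]
    n = len(m)
    left = np.full(n, np.inf)
    right = np.full(n, np.inf)
    if n > 1:
        d = m[1:] - m[:-1]
        same = c[1:] == c[:-1]
        left[1:] = np.where(same, d, np.inf)
        right[:-1] = np.where(same, d, np.inf)
    nn = np.minimum(left, right)
    out = np.full(n, np.nan)
    finite = np.isfinite(nn)
    out[order[finite]] = nn[finite]
    return out


def stat_nn_distance(gene_subset: Sequence[GeneRecord]) -> float:
    """Mean nearest-neighbor distance (bp) within the subset."""
    if len(gene_subset) < 2:
        raise ValueError("need >= 2 genes")
    mids, codes, _ = _mids_and_chroms(gene_subset)
    vals = _nn_values(mids, codes)
    if np.all(np.isnan(vals)):
        raise ValueError("no gene has a same-chromosome companion")
    return float(np.nanmean(vals))


def _feature_distance_values(mids: np.ndarray, chroms: Sequence[str],
                             features: Sequence[Interval]) -> np.ndarray:
    """Per-gene distance to the nearest feature on the same chromosome
    (0 inside a feature; NaN when the chromosome has no feature)."""
    by_chrom: dict[str, list[Interval]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append(f)
    pre: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, fs in by_chrom.items():
        fs.sort(key=lambda f: f.start)
        starts = np.array([f.start for f in fs], dtype=float)
        ends = np.maximum.accumulate(np.array([f.end for f in fs],
                                              dtype=float))
        pre[chrom] = (starts, ends)
    out = np.full(len(mids), np.nan)
    for i, (mid, chrom) in enumerate(zip(mids, chroms)):
        if chrom not in pre:
            continue
        starts, ends = pre[chrom]
        idx = np.searchsorted(starts, mid, side="right")
        d = np.inf
        if idx > 0:
            d = 0.0 if ends[idx - 1] > mid else mid - ends[idx - 1]
        if idx < len(starts):
            d = min(d, starts[idx] - mid)
        out[i] = max(d, 0.0)
    return out


def stat_feature_distance(gene_subset: Sequence[GeneRecord],
                          features: Sequence[Interval],
                          same_chromosome_only: bool = True) -> float:
    """Mean distance (bp) from gene midpoints to the nearest feature."""
    if not features:
        raise ValueError("no features")
    if not same_chromosome_only:
        raise NotImplementedError(
            "distances are defined on physical coordinates only")
    mids = np.array([g.interval.midpoint for g in gene_subset])
    chroms = [g.interval.chrom for g in gene_subset]
    vals = _feature_distance_values(mids, chroms, features)
    if np.all(np.isnan(vals)):
        raise ValueError("all genes lie on feature-free chromosomes")
    return float(np.nanmean(vals))


def _arm_position_values(mids: np.ndarray, chroms: Sequence[str],
                         centromeres: Mapping[str, Interval],
                         chrom_lengths: Mapping[str, int]) -> np.ndarray:
    """Per-gene arm position in percent toward the telomere (NaN inside
    the centromere or on a zero-length arm)."""
    out = np.full(len(mids), np.nan)
    for i, (mid, chrom) in enumerate(zip(mids, chroms)):
        cen = centromeres.get(chrom)
        if cen is None:
            raise ValueError(f"no centromere call for chromosome {chrom}")
        L = chrom_lengths[chrom]
        if cen.start <= mid < cen.end:
            continue
        if mid < cen.start:
            arm = cen.start
            pos = (cen.start - mid) / arm if arm > 0 else np.nan
        else:
            arm = L - cen.end
            pos = (mid - cen.end) / arm if arm > 0 else np.nan
        out[i] = 100.0 * pos
    return out


def stat_arm_position(gene_subset: Sequence[GeneRecord],
                      centromeres: Mapping[str, Interval],
                      chrom_lengths: Mapping[str, int]) -> float:
    """Mean arm position (%); 0 at the centromere edge, 100 at the
    telomere end of the arm carrying the gene."""
    mids = np.array([g.interval.midpoint for g in gene_subset])
    chroms = [g.interval.chrom for g in gene_subset]
    vals = _arm_position_values(mids, chroms, centromeres, chrom_lengths)
    if np.all(np.isnan(vals)):
        raise ValueError("no gene outside the centromeres")
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

_DIRECTIONS = {"nn_distance": "less", "feature_distance": "less",
               "arm_position": "greater"}


def _draw_indices(rng: np.random.Generator, n_universe: int, m: int,
                  n_draws: int) -> np.ndarray:
    """(n_draws, m) indices, each row drawn without replacement."""
    u = rng.random((n_draws, n_universe))
    return np.argpartition(u, m - 1, axis=1)[:, :m]


def permutation_test(stat_name: str, outlier_subset: Sequence[GeneRecord],
                     gene_universe: Sequence[GeneRecord],
                     features_context: Mapping | None = None,
                     n_perm: int = 1_000_000, direction: str | None = None,
                     seed: int = 0, chunk: int = 20_000,
                     max_error_fraction: float = 0.01) -> PermutationResult:
    """One-sided permutation test of an observed spatial statistic.

    ``features_context`` supplies ``features`` (list of Interval) for
    ``feature_distance`` and ``centromeres`` (chrom -> Interval) plus
    ``chrom_lengths`` for ``arm_position``.  Null draws are subsets of
    ``gene_universe`` of the observed subset size, scored with the same
    exclusion rules; draws where the statistic is undefined are counted
    and abort the test above ``max_error_fraction``.
    """
    if stat_name not in _DIRECTIONS:
        raise ValueError(f"unknown statistic {stat_name}")
    if len(outlier_subset) > len(gene_universe):
        raise ValueError("subset larger than universe")
    direction = direction or _DIRECTIONS[stat_name]
    if direction not in ("less", "greater"):
        raise ValueError(f"invalid direction {direction}")
    ctx = features_context or {}
    rng = np.random.default_rng(seed)
    m = len(outlier_subset)

    uni_mids, uni_codes, chrom_names = _mids_and_chroms(gene_universe)
    uni_chroms = [g.interval.chrom for g in gene_universe]

    if stat_name == "nn_distance":
        observed = stat_nn_distance(outlier_subset)
        sub_mids, sub_codes, _ = _mids_and_chroms(outlier_subset)
        n_used = int(np.isfinite(_nn_values(sub_mids, sub_codes)).sum())
        per_gene = None
    elif stat_name == "feature_distance":
        features = ctx["features"]
        observed = stat_feature_distance(outlier_subset, features)
        sub_vals = _feature_distance_values(
            np.array([g.interval.midpoint for g in outlier_subset]),
            [g.interval.chrom for g in outlier_subset], features)
        n_used = int(np.isfinite(sub_vals).sum())
        per_gene = _feature_distance_values(uni_mids, uni_chroms, features)
    else:
        cens, lens = ctx["centromeres"], ctx["chrom_lengths"]
        observed = stat_arm_position(outlier_subset, cens, lens)
        sub_vals = _arm_position_values(
            np.array([g.interval.midpoint for g in outlier_subset]),
            [g.interval.chrom for g in outlier_subset], cens, lens)
        n_used = int(np.isfinite(sub_vals).sum())
        per_gene = _arm_position_values(uni_mids, uni_chroms, cens, lens)

    null = np.empty(n_perm)
    n_universe = len(gene_universe)
    enc = uni_codes * np.float64(_CHROM_STRIDE) + uni_mids
    done = 0
    while done < n_perm:
        nd = min(chunk, n_perm - done)
        idx = _draw_indices(rng, n_universe, m, nd)
        if per_gene is not None:
            vals = per_gene[idx]
            with np.errstate(invalid="ignore"):
                null[done:done + nd] = np.nanmean(vals, axis=1)
        else:
            e = np.sort(enc[idx], axis=1)
            mm = e % np.float64(_CHROM_STRIDE)
            cc = np.floor(e / np.float64(_CHROM_STRIDE))
            d = mm[:, 1:] - mm[:, :-1]
            same = cc[:, 1:] == cc[:, :-1]
            d = np.where(same, d, np.inf)
            left = np.concatenate(
                [np.full((nd, 1), np.inf), d], axis=1)
            right = np.concatenate(
                [d, np.full((nd, 1), np.inf)], axis=1)
            nn = np.minimum(left, right)
            nn[~np.isfinite(nn)] = np.nan
            with np.errstate(invalid="ignore"):
                null[done:done + nd] = np.nanmean(nn, axis=1)
        done += nd

    bad = ~np.isfinite(null)
    n_bad = int(bad.sum())
    if n_bad > max_error_fraction * n_perm:
        raise RuntimeError(
            f"statistic undefined on {n_bad}/{n_perm} null draws")
    ok = null[~bad]
    if direction == "less":
        extreme = int((ok <= observed).sum())
    else:
        extreme = int((ok >= observed).sum())
    p = (1 + extreme) / (n_perm + 1)
    return PermutationResult(
        statistic_name=stat_name, observed=observed,
        null_mean=float(ok.mean()), null_sd=float(ok.std(ddof=1)),
        p_value=p, n_perm=n_perm, direction=direction, seed=seed,
        n_genes_used=n_used)
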