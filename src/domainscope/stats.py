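"""Interaction statistics on binned contact maps.

Covers the comparisons a conformation-capture study runs once matrices are
normalized: virtual-anchor (4C-style) interaction profiles, paired one-tailed
Wilcoxon signed-rank comparisons between region pairs of two maps,
contact-probability scaling with genomic distance, contacts stratified by a
per-bin activity track, and percentile ranking of intergenic fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import BinTrack, ContactMap, GenomicRegion

__all__ = [
    "RegionPairSample",
    "FoldChangeTable",
    "WilcoxonResult",
    "virtual_anchor_profile",
    "region_pair_counts",
    "paired_wilcoxon",
    "contact_scaling",
    "fit_scaling_exponent",
    "stratified_contacts",
    "intergenic_percentiles",
]


@dataclass
class RegionPairSample:
    """Counts over unmasked bin pairs, keyed by (bin_i, bin_j)."""

    keys: list[tuple[int, int]]
    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.keys) != self.values.size:
            raise ValueError("keys and values differ in length")


@dataclass
class FoldChangeTable:
    regions: list[GenomicRegion]
    log2fc: np.ndarray
    percentile: np.ndarray  # mid-rank percentile within the full table


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive (sample1 - sample2) diffs
    p_value: float    # NaN when no nonzero differences exist
    n_effective: int
    method: str       # "exact", "normal", or "none"


def virtual_anchor_profile(
    cmap: ContactMap, anchor: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of contacts between an anchor bin interval and each bin.

    The anchor is a half-open bin interval [lo, hi). For every non-anchor bin
    j the mean and standard deviation of counts[a, j] over unmasked anchor
    bins a are returned; anchor-internal pairs and masked bins are NaN.
    """
    lo, hi = anchor
    n = cmap.n_bins
    if not (0 <= lo < hi <= n):
        raise ValueError(f"anchor [{lo},{hi}) outside grid of {n} bins")
    abins = np.array([a for a in range(lo, hi) if cmap.mask[a]])
    if abins.size == 0:
        raise ValueError("anchor contains no unmasked bins")
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    for j in range(n):
        if lo <= j < hi or not cmap.mask[j]:
            continue
        vals = cmap.counts[abins, j]
        mean[j] = vals.mean()
        sd[j] = vals.std()
    return mean, sd


def region_pair_counts(
    cmap: ContactMap,
    a: tuple[int, int],
    b: tuple[int, int],
    d_min_bp: int = 0,
) -> RegionPairSample:
    """Counts for all unmasked bin pairs (i in a, j in b), i != j.

    Overlapping intervals count each unordered pair once. With ``a == b``
    the upper-triangle pairs of the interval are returned, optionally
    restricted to genomic separations strictly greater than ``d_min_bp``.
    """
    n = cmap.n_bins
    for lo, hi in (a, b):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"interval [{lo},{hi}) outside grid of {n} bins")
    d_min_bins = d_min_bp // cmap.grid.resolution
    pair_set: set[tuple[int, int]] = set()
    for i in range(a[0], a[1]):
        for j in range(b[0], b[1]):
            if i == j or not (cmap.mask[i] and cmap.mask[j]):
                continue
            if d_min_bp > 0 and abs(j - i) <= d_min_bins:
                continue
            pair_set.add((min(i, j), max(i, j)))
    keys = sorted(pair_set)
    if not keys:
        raise ValueError(
            "no unmasked bin pairs between the intervals; inspect the mask"
        )
    values = np.array([cmap.counts[i, j] for i, j in keys])
    return RegionPairSample(keys, values, source=str(cmap.metadata.get("label", "")))


def _signed_rank_exact_sf(w: float, ranks: np.ndarray) -> float:
    """P(W+ >= w) under the exact signed-rank null, tie-aware.

    Convolution over doubled mid-ranks (integers even with .5 ties): the null
    assigns each rank to the positive set independently with probability 1/2.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.ceil(2 * w - 1e-9))
    return float(dist[w2:].sum())


def paired_wilcoxon(
    sample1: RegionPairSample,
    sample2: RegionPairSample,
    alternative: str = "greater",
) -> WilcoxonResult:
    """One-tailed Wilcoxon signed-rank test on paired bin-pair counts.

    Differences are ``sample1 - sample2``; ``alternative='greater'`` tests
    whether sample1 counts exceed sample2 (and ``'less'`` the reverse). Zero
    differences are dropped (Wilcoxon's treatment), ties get mid-ranks. The
    exact tie-aware null distribution is used for n_effective <= 25, the
    tie-corrected normal approximation above. The statistic reported is W+,
    the rank sum of positive differences.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if sample1.keys != sample2.keys:
        raise ValueError("samples are not paired over identical bin-pair keys")
    d = sample1.values - sample2.values
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(float("nan"), float("nan"), 0, "none")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= 25:
        if alternative == "greater":
            p = _signed_rank_exact_sf(w_plus, ranks)
        else:
            w_minus = float(ranks[d < 0].sum())
            p = _signed_rank_exact_sf(w_minus, ranks)
        return WilcoxonResult(w_plus, p, n, "exact")

    # normal approximation with tie correction
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    w = w_plus if alternative == "greater" else float(ranks[d < 0].sum())
    z = (w - mean) / np.sqrt(var)
    p = float(sps.norm.sf(z))
    return WilcoxonResult(w_plus, p, n, "normal")


def contact_scaling(
    cmap: ContactMap,
    region: tuple[int, int] | None = None,
    exclude: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact per genomic separation inside a bin interval.

    Pairs with *both* ends inside ``exclude`` are omitted (e.g. to drop a
    sub-TAD from the curve). Returns (normalized, raw): the raw per-distance
    means and the same curve normalized to sum 1 (a contact probability per
    distance); distances with no eligible pair are NaN.
    """
    n = cmap.n_bins
    lo, hi = region if region is not None else (0, n)
    if not (0 <= lo < hi <= n):
        raise ValueError(f"region [{lo},{hi}) outside grid")
    span = hi - lo
    raw = np.full(span, np.nan)
    for d in range(span):
        vals = []
        for i in range(lo, hi - d):
            j = i + d
            if not (cmap.mask[i] and cmap.mask[j]):
                continue
            if exclude is not None and (
                exclude[0] <= i < exclude[1] and exclude[0] <= j < exclude[1]
            ):
                continue
            vals.append(cmap.counts[i, j])
        if vals:
            raw[d] = np.mean(vals)
    if np.all(np.isnan(raw)):
        raise ValueError("no eligible pairs; exclusion covers the whole region")
    total = np.nansum(raw)
    norm = raw / total if total > 0 else raw.copy()
    return norm, raw


def fit_scaling_exponent(raw: np.ndarray, d_min: int = 1) -> float:
    """Log-log slope of mean contact vs (distance + 1), distances >= d_min."""
    d = np.arange(raw.size)
    ok = (d >= d_min) & np.isfinite(raw) & (raw > 0)
    slope, _ = np.polyfit(np.log(d[ok] + 1.0), np.log(raw[ok]), 1)
    return float(slope)


def stratified_contacts(
    cmap: ContactMap,
    track: BinTrack,
    n_groups: int = 4,
    mode: str = "level",
) -> tuple[dict[tuple[int, int], np.ndarray], np.ndarray]:
    """Distributions of contacts between quantile groups of a per-bin track.

    Unmasked bins are split into ``n_groups`` by track quantile ("level" mode
    takes the track as-is; "change" expects a difference/log-ratio track and
    is handled identically — the distinction is documentation of intent).
    Returns ({(g1, g2): counts}, group_boundaries); within-group entries use
    the upper triangle.
    """
    if mode not in ("level", "change"):
        raise ValueError("mode must be 'level' or 'change'")
    if track.grid != cmap.grid:
        raise ValueError("track is on a different grid")
    idx = np.flatnonzero(cmap.mask & ~track.missing)
    vals = track.values[idx]
    if np.unique(vals).size < n_groups:
        raise ValueError("fewer distinct track values than groups")
    edges = np.quantile(vals, np.linspace(0, 1, n_groups + 1))
    group = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, n_groups - 1)
    out: dict[tuple[int, int], list[float]] = {
        (g1, g2): [] for g1 in range(n_groups) for g2 in range(g1, n_groups)
    }
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            i, j = idx[a], idx[b]
            g = (min(group[a], group[b]), max(group[a], group[b]))
            out[g].append(cmap.counts[i, j])
    return {k: np.asarray(v) for k, v in out.items()}, edges


def _merge_regions(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    merged: list[GenomicRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicRegion(r.chrom, last.start, max(last.end, r.end)))
        else:
            merged.append(r)
    return merged


def intergenic_percentiles(
    genes: list[GenomicRegion],
    coverage_a: BinTrack,
    coverage_b: BinTrack,
    epsilon: float = 1.0,
) -> FoldChangeTable:
    """Percentile-rank intergenic regions by coverage log2 fold change.

    Intergenic regions are the complement of merged gene spans within the
    coverage grid's region. Per-region coverage is the overlap-weighted sum of
    track values; the fold change is ``log2((cov_b + eps) / (cov_a + eps))``
    and percentiles are mid-rank percentiles (100 * rank / N) within the full
    table, so a query subset's percentiles are read off the same distribution.
    """
    if coverage_a.grid != coverage_b.grid:
        raise ValueError("coverage tracks are on different grids")
    span = coverage_a.grid.region
    merged = [g for g in _merge_regions(genes) if g.chrom == span.chrom]
    inter: list[GenomicRegion] = []
    cursor = span.start
    for g in merged:
        lo, hi = max(g.start, span.start), min(g.end, span.end)
        if lo > cursor:
            inter.append(GenomicRegion(span.chrom, cursor, lo))
        cursor = max(cursor, hi)
    if cursor < span.end:
        inter.append(GenomicRegion(span.chrom, cursor, span.end))
    if not inter:
        import warnings

        warnings.warn("gene spans cover the whole region; no intergenic loci")
        return FoldChangeTable([], np.array([]), np.array([]))

    def region_cov(track: BinTrack, r: GenomicRegion) -> float:
        grid = track.grid
        total = 0.0
        for i in range(grid.bin_of(r.start), grid.n_bins):
            blo, bhi = grid.bin_interval(i)
            if blo >= r.end:
                break
            ov = min(r.end, bhi) - max(r.start, blo)
            v = track.values[i]
            if ov > 0 and not np.isnan(v):
                total += v * ov / (bhi - blo)
        return total

    cov_a = np.array([region_cov(coverage_a, r) for r in inter])
    cov_b = np.array([region_cov(coverage_b, r) for r in inter])
    log2fc = np.log2((cov_b + epsilon) / (cov_a + epsilon))
    pct = 100.0 * sps.rankdata(log2fc, method="average") / log2fc.size
    return FoldChangeTable(inter, log2fc, pct)
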