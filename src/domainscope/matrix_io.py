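"""Readers and writers for the text formats the pipeline touches.

Dense whitespace-separated matrices, upper-triangle triplet files
(``i<TAB>j<TAB>value``), BED3/BED6, bedGraph tracks, and a BED sidecar for
bin masks. All genomic output is 0-based half-open (BED-native).
"""

from __future__ import annotations

import os

import numpy as np

from .core import BinGrid, BinTrack, ContactMap, DomainSet

__all__ = [
    "read_contact_map",
    "write_contact_map",
    "read_mask_bed",
    "write_mask_bed",
    "write_domains_bed",
    "read_domains_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed_regions",
]


class ParseError(ValueError):
    """Malformed line in a text input; carries path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")


def read_contact_map(path, format: str, grid: BinGrid) -> ContactMap:
    """Read a contact matrix in ``dense`` or ``triplet`` format.

    Triplet files carry the upper triangle once per entry as 0-based
    ``i j value``; entries are mirrored onto the lower triangle. Duplicate
    (i, j) keys are an error, as are indices outside the grid.
    """
    n = grid.n_bins
    if format == "dense":
        counts = np.loadtxt(path, dtype=float, ndmin=2)
        return ContactMap(grid, counts)
    if format != "triplet":
        raise ValueError(f"unknown contact-map format: {format!r}")

    counts = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 fields, got {len(parts)}")
            try:
                i, j, value = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(
                    f"{path}:{lineno}: bin index ({i},{j}) outside grid of {n} bins"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParseError(path, lineno, f"duplicate entry for bin pair {key}")
            seen.add(key)
            counts[i, j] = value
            counts[j, i] = value
    return ContactMap(grid, counts)


def write_contact_map(cmap: ContactMap, path, format: str = "triplet") -> None:
    """Write a contact map; triplet output stores the upper triangle only."""
    if format == "dense":
        np.savetxt(path, cmap.counts, fmt="%.10g")
        return
    if format != "triplet":
        raise ValueError(f"unknown contact-map format: {format!r}")
    with open(path, "w") as fh:
        iu, ju = np.triu_indices(cmap.n_bins)
        for i, j in zip(iu, ju):
            v = cmap.counts[i, j]
            if v != 0.0:
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


def write_mask_bed(cmap: ContactMap, path) -> None:
    """Sidecar BED of *excluded* (masked-out) bin intervals."""
    grid = cmap.grid
    with open(path, "w") as fh:
        for i in np.flatnonzero(~cmap.mask):
            lo, hi = grid.bin_interval(int(i))
            fh.write(f"{grid.region.chrom}\t{lo}\t{hi}\n")


def read_mask_bed(path, grid: BinGrid) -> np.ndarray:
    """Read an excluded-interval BED back into a per-bin validity mask."""
    mask = np.ones(grid.n_bins, dtype=bool)
    for chrom, lo, hi in read_bed_regions(path):
        if chrom != grid.region.chrom:
            continue
        for i in range(grid.n_bins):
            blo, bhi = grid.bin_interval(i)
            if lo < bhi and blo < hi:
                mask[i] = False
    return mask


def write_domains_bed(domains: DomainSet, grid: BinGrid, path) -> None:
    """Write domains as BED3 genomic intervals; overlap is a validation error.

    Round-trip through :func:`read_domains_bed` recovers identical bin
    intervals.
    """
    n = grid.n_bins
    for lo, hi in domains:
        if not (0 <= lo < hi <= n):
            raise ValueError(f"domain [{lo},{hi}) outside grid of {n} bins")
    with open(path, "w") as fh:
        for lo, hi in domains:
            g_lo = grid.bin_interval(lo)[0]
            g_hi = grid.bin_interval(hi - 1)[1]
            fh.write(f"{grid.region.chrom}\t{g_lo}\t{g_hi}\n")


def read_domains_bed(path, grid: BinGrid) -> DomainSet:
    intervals = []
    res = grid.resolution
    start = grid.region.start
    for chrom, lo, hi in read_bed_regions(path):
        if chrom != grid.region.chrom:
            raise ValueError(f"domain on {chrom} does not match grid chromosome")
        intervals.append(((lo - start) // res, -(-(hi - start) // res)))
    return DomainSet(sorted(intervals))


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Read BED3+ intervals as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(path, lineno, "BED line needs >= 3 fields")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bedgraph(track: BinTrack, path) -> None:
    """Write a per-bin track as bedGraph; missing (NaN) bins are omitted."""
    grid = track.grid
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isnan(v):
                continue
            lo, hi = grid.bin_interval(i)
            fh.write(f"{grid.region.chrom}\t{lo}\t{hi}\t{v:.10g}\n")


def read_bedgraph(path, grid: BinGrid, name: str = "") -> BinTrack:
    """Read a bedGraph onto a grid; uncovered bins are NaN (missing).

    Intervals must align with bin edges or cover bins exactly once; partial
    coverage takes the overlap-weighted mean.
    """
    values = np.full(grid.n_bins, np.nan)
    weight = np.zeros(grid.n_bins)
    acc = np.zeros(grid.n_bins)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ParseError(path, lineno, "bedGraph line needs 4 fields")
            chrom, lo, hi, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom != grid.region.chrom:
                continue
            lo = max(lo, grid.region.start)
            hi = min(hi, grid.region.end)
            for i in range(grid.bin_of(lo) if lo < hi else 0, grid.n_bins):
                blo, bhi = grid.bin_interval(i)
                if blo >= hi:
                    break
                ov = min(hi, bhi) - max(lo, blo)
                if ov > 0:
                    acc[i] += v * ov
                    weight[i] += ov
    covered = weight > 0
    values[covered] = acc[covered] / weight[covered]
    return BinTrack(grid, values, name=name or os.path.basename(str(path)))
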