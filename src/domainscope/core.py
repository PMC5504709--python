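"""Core genomic data model: regions, bin grids, contact maps, tracks.

All coordinates are 0-based, half-open. Bin grids partition a region into
fixed-width windows; contact maps are dense symmetric matrices over a grid
with a per-bin validity mask (True = bin usable). Masked bins always carry
all-zero rows and columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicRegion",
    "BinGrid",
    "ContactMap",
    "BinTrack",
    "FragmentMap",
    "DomainSet",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo.replace(",", "")), int(hi.replace(",", "")))


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of a region.

    Bin ``i`` covers ``[start + i*resolution, min(start + (i+1)*resolution, end))``.
    """

    region: GenomicRegion
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return math.ceil(len(self.region) / self.resolution)

    def bin_of(self, pos: int) -> int:
        """Bin index of a genomic position (must lie inside the region)."""
        if not (self.region.start <= pos < self.region.end):
            raise IndexError(
                f"position {pos} outside {self.region.chrom}:"
                f"{self.region.start}-{self.region.end}"
            )
        return (pos - self.region.start) // self.resolution

    def bin_interval(self, i: int) -> tuple[int, int]:
        """Genomic (start, end) of bin ``i``."""
        if not (0 <= i < self.n_bins):
            raise IndexError(f"bin {i} out of range [0, {self.n_bins})")
        lo = self.region.start + i * self.resolution
        hi = min(lo + self.resolution, self.region.end)
        return lo, hi


def _check_square_symmetric(counts: np.ndarray) -> None:
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"counts must be square, got shape {counts.shape}")
    if not np.allclose(counts, counts.T, rtol=0, atol=1e-8):
        raise ValueError("counts matrix is not symmetric")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")


@dataclass
class ContactMap:
    """Symmetric contact-count matrix over a bin grid.

    ``mask`` holds per-bin validity flags (True = valid). Rows/columns of
    invalid bins are forced to zero on construction.
    """

    grid: BinGrid
    counts: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        _check_square_symmetric(self.counts)
        if self.counts.shape[0] != self.grid.n_bins:
            raise ValueError(
                f"matrix size {self.counts.shape[0]} != grid n_bins {self.grid.n_bins}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.grid.n_bins,):
                raise ValueError("mask length must equal n_bins")
        self.counts[~self.mask, :] = 0.0
        self.counts[:, ~self.mask] = 0.0

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.grid, self.counts.copy(), self.mask.copy(), dict(self.metadata)
        )

    def total(self) -> float:
        """Total count over the upper triangle including the diagonal."""
        return float(np.triu(self.counts).sum())


@dataclass
class BinTrack:
    """Per-bin scalar values (e.g. transcription, CpG density); NaN = missing."""

    grid: BinGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != n_bins {self.grid.n_bins}"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling a region, gap- and overlap-free."""

    region: GenomicRegion
    fragments: list[tuple[int, int]]
    enzyme_site_length: int = 6

    def __post_init__(self):
        if not self.fragments:
            raise ValueError("fragment map is empty")
        prev = self.region.start
        for k, (lo, hi) in enumerate(self.fragments):
            if lo != prev or hi <= lo:
                raise ValueError(
                    f"fragment {k} ({lo}-{hi}) does not tile the region "
                    f"contiguously from {prev}"
                )
            prev = hi
        if prev != self.region.end:
            raise ValueError("fragments do not reach the region end")
        self._starts = np.array([lo for lo, _ in self.fragments])

    def __len__(self) -> int:
        return len(self.fragments)

    def fragment_of(self, pos: int) -> int:
        """Index of the fragment containing ``pos``."""
        if not (self.region.start <= pos < self.region.end):
            raise IndexError(f"position {pos} outside fragment map region")
        return int(np.searchsorted(self._starts, pos, side="right") - 1)

    def midpoint(self, i: int) -> int:
        lo, hi = self.fragments[i]
        return (lo + hi) // 2

    def length(self, i: int) -> int:
        lo, hi = self.fragments[i]
        return hi - lo

    @property
    def sites(self) -> np.ndarray:
        """Restriction-site boundary coordinates (fragment edges)."""
        return np.array([lo for lo, _ in self.fragments] + [self.region.end])

    def distance_to_site(self, pos: int) -> int:
        return int(np.min(np.abs(self.sites - pos)))


@dataclass
class DomainSet:
    """Non-overlapping, sorted half-open bin intervals with scores."""

    domains: list[tuple[int, int]]
    scores: list[float] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.scores is None:
            self.scores = [float("nan")] * len(self.domains)
        if len(self.scores) != len(self.domains):
            raise ValueError("scores length must match domains")
        prev_end = -1
        for lo, hi in self.domains:
            if hi <= lo:
                raise ValueError(f"empty domain [{lo}, {hi})")
            if lo < prev_end:
                raise ValueError("domains overlap or are unsorted")
            prev_end = hi

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def boundaries(self) -> list[int]:
        """Interior domain edges: every start/end that is not the outermost."""
        edges: list[int] = []
        for lo, hi in self.domains:
            edges.extend((lo, hi))
        return sorted(set(edges))
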