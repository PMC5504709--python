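"""Capture Hi-C (C-TALE) read-pair classification and 5-Kb binning.

Read pairs are screened through the standard proximity-ligation filter
cascade before binning: PCR duplicates, ends within 5 bp of a restriction
site, ends on out-of-range fragments (<100 bp or >100 Kb), self-ligations
(both ends on one fragment) and dangling ends (ends closer than 500 bp) are
all removed; only the surviving pairs enter the contact matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BinGrid, ContactMap, FragmentMap, GenomicRegion

__all__ = [
    "ReadEnd",
    "ReadPair",
    "FilterParams",
    "CLASSES",
    "classify_read_pair",
    "filter_and_bin",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

#: classification outcomes, in rule-precedence order (first match wins; the
#: off_target check precedes all of them)
CLASSES = (
    "off_target",
    "duplicate",
    "near_site",
    "fragment_length",
    "same_fragment",
    "proximity",
    "valid",
)


@dataclass(frozen=True)
class ReadEnd:
    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ReadPair:
    end1: ReadEnd
    end2: ReadEnd
    true_class: str | None = None  # simulation ground truth, if any

    def canonical_key(self) -> tuple:
        """Duplicate identity: exact (pos, strand) of both ends, end-order free."""
        a = (self.end1.chrom, self.end1.pos, self.end1.strand)
        b = (self.end2.chrom, self.end2.pos, self.end2.strand)
        return tuple(sorted([a, b]))


@dataclass
class FilterParams:
    """Thresholds of the filter cascade (defaults are the standard values)."""

    site_margin: int = 5          # bp; inclusive ("within 5 bp of a site")
    min_separation: int = 500     # bp; pairs closer than this are dangling ends
    min_fragment: int = 100       # bp; fragments shorter than this are dropped
    max_fragment: int = 100_000   # bp; fragments longer than this are dropped
    target: GenomicRegion | None = None

    def __post_init__(self):
        if min(self.site_margin, self.min_separation, self.min_fragment) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_fragment >= self.max_fragment:
            raise ValueError("min_fragment must be < max_fragment")


def classify_read_pair(
    pair: ReadPair,
    fragmap: FragmentMap,
    params: FilterParams,
    seen: set | None = None,
) -> str:
    """Classify one read pair; first matching rule in fixed order wins.

    Order: off_target, duplicate, near_site, fragment_length, same_fragment,
    proximity, valid. ``seen`` is the duplicate registry (a set of canonical
    coordinate keys); the first occurrence of a coordinate pair is kept and
    registered, repeats are duplicates.
    """
    target = params.target or fragmap.region
    for end in (pair.end1, pair.end2):
        if not target.contains(end.chrom, end.pos) or not fragmap.region.contains(
            end.chrom, end.pos
        ):
            return "off_target"

    if seen is not None:
        key = pair.canonical_key()
        if key in seen:
            return "duplicate"
        seen.add(key)

    if (
        fragmap.distance_to_site(pair.end1.pos) <= params.site_margin
        or fragmap.distance_to_site(pair.end2.pos) <= params.site_margin
    ):
        return "near_site"

    f1 = fragmap.fragment_of(pair.end1.pos)
    f2 = fragmap.fragment_of(pair.end2.pos)
    for f in (f1, f2):
        if not (params.min_fragment <= fragmap.length(f) <= params.max_fragment):
            return "fragment_length"

    if f1 == f2:
        return "same_fragment"

    if (
        pair.end1.chrom == pair.end2.chrom
        and abs(pair.end1.pos - pair.end2.pos) < params.min_separation
    ):
        return "proximity"

    return "valid"


def filter_and_bin(
    pairs: list[ReadPair],
    fragmap: FragmentMap,
    params: FilterParams,
    grid: BinGrid,
) -> tuple[ContactMap, dict[str, int]]:
    """Run the filter cascade and bin surviving pairs onto a grid.

    Only ``valid`` pairs contribute. Reads are grouped by (fragment, fragment)
    pair; each bin-pair value is the mean read count over the fragment pairs
    mapping into it (fragment midpoints decide bin membership). The tally
    reports every class count and sums to ``len(pairs)``. Bins untouched by
    any valid pair are masked.
    """
    tally = {c: 0 for c in CLASSES}
    seen: set = set()
    frag_pair_reads: dict[tuple[int, int], int] = {}
    for pair in pairs:
        cls = classify_read_pair(pair, fragmap, params, seen)
        tally[cls] += 1
        if cls != "valid":
            continue
        f1 = fragmap.fragment_of(pair.end1.pos)
        f2 = fragmap.fragment_of(pair.end2.pos)
        key = (min(f1, f2), max(f1, f2))
        frag_pair_reads[key] = frag_pair_reads.get(key, 0) + 1

    n = grid.n_bins
    acc = np.zeros((n, n))
    npairs = np.zeros((n, n), dtype=int)
    for (f1, f2), reads in frag_pair_reads.items():
        m1, m2 = fragmap.midpoint(f1), fragmap.midpoint(f2)
        if not (
            grid.region.contains(grid.region.chrom, m1)
            and grid.region.contains(grid.region.chrom, m2)
        ):
            continue
        b1, b2 = sorted((grid.bin_of(m1), grid.bin_of(m2)))
        acc[b1, b2] += reads
        npairs[b1, b2] += 1

    with np.errstate(invalid="ignore"):
        counts = np.where(npairs > 0, acc / np.maximum(npairs, 1), 0.0)
    counts = np.triu(counts)
    counts = counts + counts.T - np.diag(np.diag(counts))

    touched = (npairs + npairs.T).sum(axis=0) > 0
    if tally["valid"] == 0:
        warnings.warn("no valid read pairs; returning an all-masked empty map")
    cmap = ContactMap(grid, counts, mask=touched)
    return cmap, tally


def read_pairs_tsv(path) -> list[ReadPair]:
    """Read pairs from ``chrom1 pos1 strand1 chrom2 pos2 strand2`` TSV."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields")
            out.append(
                ReadPair(
                    ReadEnd(parts[0], int(parts[1]), parts[2]),
                    ReadEnd(parts[3], int(parts[4]), parts[5]),
                )
            )
    return out


def write_pairs_tsv(pairs: list[ReadPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.end1.chrom}\t{p.end1.pos}\t{p.end1.strand}\t"
                f"{p.end2.chrom}\t{p.end2.pos}\t{p.end2.strand}\n"
            )
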