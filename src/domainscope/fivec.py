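"""5C design representation and primer-level processing.

5C interrogates a region through forward/reverse primers placed on
alternating restriction fragments; ligation products are only detected
between a forward and a reverse primer, so an alternating design over m
eligible fragments yields ceil(m/2) x floor(m/2) observable pairs
(93 x 92 = 8556 for a 185-fragment design). Counts arrive as a
forward x reverse primer-pair table which is filtered for dead primers and
binned to a fixed-resolution contact map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BinGrid, ContactMap, FragmentMap

__all__ = [
    "Primer",
    "PrimerSet",
    "PrimerPairCounts",
    "design_alternating_primers",
    "filter_primers",
    "bin_primer_matrix",
]


@dataclass(frozen=True)
class Primer:
    fragment_index: int
    orientation: str  # "forward" | "reverse"

    def __post_init__(self):
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class PrimerSet:
    """Primers of an alternating 5C design, at most one per fragment."""

    primers: list[Primer]
    scheme: str = "alternating"

    def __post_init__(self):
        frags = [p.fragment_index for p in self.primers]
        if len(set(frags)) != len(frags):
            raise ValueError("at most one primer per fragment")

    def __len__(self) -> int:
        return len(self.primers)

    @property
    def forward(self) -> list[Primer]:
        return [p for p in self.primers if p.orientation == "forward"]

    @property
    def reverse(self) -> list[Primer]:
        return [p for p in self.primers if p.orientation == "reverse"]

    def n_pairs(self) -> int:
        """Number of interrogatable forward x reverse primer pairs."""
        return len(self.forward) * len(self.reverse)

    def by_fragment(self) -> dict[int, Primer]:
        return {p.fragment_index: p for p in self.primers}


@dataclass
class PrimerPairCounts:
    """Counts keyed by (forward fragment index, reverse fragment index)."""

    counts: dict[tuple[int, int], float]
    label: str = ""

    def validate(self, primers: PrimerSet) -> None:
        byfrag = primers.by_fragment()
        for f, r in self.counts:
            if f == r:
                # same-fragment interaction: cannot pair F with R, but such
                # keys are tolerated here and excluded during binning
                continue
            if (
                f not in byfrag
                or r not in byfrag
                or byfrag[f].orientation != "forward"
                or byfrag[r].orientation != "reverse"
            ):
                raise ValueError(
                    f"count key ({f},{r}) does not pair a forward with a reverse primer"
                )


def design_alternating_primers(
    fragmap: FragmentMap, min_len: int = 100, max_len: int = 50_000
) -> PrimerSet:
    """Place primers on eligible fragments in strictly alternating orientation.

    Fragments shorter than ``min_len`` or longer than ``max_len`` are skipped
    without resetting the alternation phase; the first eligible fragment gets
    a forward primer.
    """
    primers: list[Primer] = []
    k = 0
    for i in range(len(fragmap)):
        if not (min_len <= fragmap.length(i) <= max_len):
            continue
        primers.append(Primer(i, "forward" if k % 2 == 0 else "reverse"))
        k += 1
    if not primers:
        warnings.warn("no eligible fragments; returning an empty primer set")
    return PrimerSet(primers)


def filter_primers(
    counts_by_celltype: list[PrimerPairCounts], primers: PrimerSet
) -> PrimerSet:
    """Drop primers with zero total interactions in at least one cell type.

    The marginal (row/column total of the forward x reverse table) is computed
    per cell type; a primer survives only if its marginal is positive in every
    cell type, and the filter is applied jointly to all cell types.
    """
    if not counts_by_celltype:
        return PrimerSet([])
    keep = {p.fragment_index for p in primers.primers}
    for table in counts_by_celltype:
        table.validate(primers)
        marginal: dict[int, float] = {p.fragment_index: 0.0 for p in primers.primers}
        for (f, r), v in table.counts.items():
            marginal[f] += v
            marginal[r] += v
        keep &= {frag for frag, total in marginal.items() if total > 0}
    return PrimerSet([p for p in primers.primers if p.fragment_index in keep])


def restrict_counts(table: PrimerPairCounts, primers: PrimerSet) -> PrimerPairCounts:
    """Project a count table onto a (filtered) primer set."""
    frags = {p.fragment_index for p in primers.primers}
    return PrimerPairCounts(
        {k: v for k, v in table.counts.items() if k[0] in frags and k[1] in frags},
        label=table.label,
    )


def bin_primer_matrix(
    counts: PrimerPairCounts,
    primers: PrimerSet,
    fragmap: FragmentMap,
    grid: BinGrid,
) -> ContactMap:
    """Bin a primer-pair count table to a contact map.

    Each pair is assigned to the bins of its two fragments' midpoints; the
    bin-pair value is the arithmetic mean (not the sum) of contributing pair
    counts. Pairs whose two primers lie on the same fragment are excluded.
    The result is symmetric; bins receiving no pairs are masked, and the
    per-bin-pair contribution count is stored as ``metadata['coverage']`` so
    empty bin pairs remain distinguishable from measured zeros.
    """
    counts.validate(primers)
    n = grid.n_bins
    acc = np.zeros((n, n))
    npairs = np.zeros((n, n), dtype=int)
    for (f, r), v in counts.counts.items():
        if f == r:  # same-fragment interaction: removed
            continue
        mf, mr = fragmap.midpoint(f), fragmap.midpoint(r)
        for m in (mf, mr):
            if not grid.region.contains(grid.region.chrom, m):
                raise IndexError(f"fragment midpoint {m} outside the bin grid")
        b1, b2 = sorted((grid.bin_of(mf), grid.bin_of(mr)))
        acc[b1, b2] += v
        npairs[b1, b2] += 1

    mat = np.where(npairs > 0, acc / np.maximum(npairs, 1), 0.0)
    mat = np.triu(mat)
    mat = mat + mat.T - np.diag(np.diag(mat))
    coverage = npairs + npairs.T - np.diag(np.diag(npairs))
    touched = coverage.sum(axis=0) > 0
    return ContactMap(
        grid, mat, mask=touched, metadata={"coverage": coverage, "label": counts.label}
    )
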