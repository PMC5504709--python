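"""5C primer design combinatorics and primer-pair binning.

An alternating design over 185 eligible restriction fragments yields 93
forward and 92 reverse primers, i.e. 8,556 interrogatable primer pairs —
the size of the published design. A small count table is then binned to a
contact map with the mean-per-bin rule.
"""

from domainscope.core import BinGrid, FragmentMap, GenomicRegion
from domainscope.fivec import (
    PrimerPairCounts,
    bin_primer_matrix,
    design_alternating_primers,
)

region = GenomicRegion("chr14", 9_800_000, 9_800_000 + 185_000)
frags = [(region.start + i * 1000, region.start + (i + 1) * 1000) for i in range(185)]
fragmap = FragmentMap(region, frags)

primers = design_alternating_primers(fragmap)
print(f"{len(primers.forward)} forward + {len(primers.reverse)} reverse primers")
print(f"interrogatable forward x reverse pairs: {primers.n_pairs()}")

# two pairs landing in the same bin pair are averaged, not summed
grid = BinGrid(region, 30_000)
counts = PrimerPairCounts({(0, 1): 4.0, (2, 3): 6.0})
cmap = bin_primer_matrix(counts, primers, fragmap, grid)
print(f"bin (0,0) value (mean of 4.0 and 6.0): {cmap.counts[0, 0]}")
print(f"contributing pairs at (0,0): {cmap.metadata['coverage'][0, 0]}")
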