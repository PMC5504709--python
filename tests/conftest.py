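import numpy as np
import pytest

from domainscope.core import BinGrid, ContactMap, FragmentMap, GenomicRegion


@pytest.fixture
def grid3():
    return BinGrid(GenomicRegion("chr14", 0, 90_000), 30_000)


@pytest.fixture
def grid10():
    return BinGrid(GenomicRegion("chr14", 9_800_000, 10_100_000), 30_000)


def make_map(counts, grid=None, mask=None, start=0, resolution=30_000):
    counts = np.asarray(counts, dtype=float)
    if grid is None:
        grid = BinGrid(
            GenomicRegion("chr14", start, start + counts.shape[0] * resolution),
            resolution,
        )
    return ContactMap(grid, counts, mask=mask)


def random_symmetric_map(n, rng, scale=10.0, start=0, resolution=30_000):
    upper = rng.uniform(0, scale, size=(n, n))
    counts = np.triu(upper)
    counts = counts + counts.T - np.diag(np.diag(counts))
    return make_map(counts, start=start, resolution=resolution)


@pytest.fixture
def uniform_fragmap():
    """185 fragments of 1 kb each (all eligible for 5C primer design)."""
    region = GenomicRegion("chr14", 9_800_000, 9_800_000 + 185_000)
    frags = [
        (region.start + i * 1000, region.start + (i + 1) * 1000) for i in range(185)
    ]
    return FragmentMap(region, frags)
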