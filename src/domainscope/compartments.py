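"""A/B-like compartment annotation from a corrected contact map.

The classic eigenvector procedure: divide the map by the mean contact at
each genomic separation (observed/expected), take the Pearson correlation
matrix of the result, and extract the first principal component. The sign of
PC1 is arbitrary and is oriented against an activity reference track (gene
density, transcription or CpG density); under the ``A_negative`` convention
the A-like (active) compartment carries negative PC1 values, matching how
the source data are usually displayed. Compartment borders are the sign
transitions that survive a minimum-run-length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinGrid, BinTrack, ContactMap

__all__ = [
    "CompartmentTrack",
    "expected_by_distance",
    "observed_over_expected",
    "compartment_pca",
    "orient_and_call",
]


@dataclass
class CompartmentTrack:
    grid: BinGrid
    pc1: np.ndarray  # NaN on masked bins
    orientation_reference: str = ""
    labels: np.ndarray | None = None  # "A" / "B" / "masked"
    borders: list[int] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.pc1)


def expected_by_distance(cmap: ContactMap) -> np.ndarray:
    """Mean contact at each genomic separation d over unmasked bin pairs.

    Distances with no unmasked pair are NaN.
    """
    n = cmap.n_bins
    out = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(cmap.counts, d)
        ok = cmap.mask[: n - d] & cmap.mask[d:]
        if ok.any():
            out[d] = diag[ok].mean()
    return out


def observed_over_expected(cmap: ContactMap) -> np.ndarray:
    """O/E matrix on unmasked pairs; masked or zero-expected entries are NaN."""
    n = cmap.n_bins
    exp = expected_by_distance(cmap)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = cmap.counts / exp[d]
    oe[~cmap.mask, :] = np.nan
    oe[:, ~cmap.mask] = np.nan
    return oe


def compartment_pca(cmap: ContactMap) -> CompartmentTrack:
    """First principal component of the O/E Pearson correlation matrix.

    Deterministic up to sign (the returned sign is fixed so that the
    component sums non-negatively; orientation against a reference happens in
    :func:`orient_and_call`). Requires >= 3 unmasked bins; constant O/E
    columns make the correlation undefined and are reported as an error.
    """
    idx = np.flatnonzero(cmap.mask)
    if idx.size < 3:
        raise ValueError("need at least 3 unmasked bins for compartment PCA")
    oe = observed_over_expected(cmap)[np.ix_(idx, idx)]
    sd = oe.std(axis=0)
    degenerate = idx[sd == 0]
    if degenerate.size:
        raise ValueError(
            f"constant O/E columns for bins {degenerate.tolist()}; "
            "mask them before PCA"
        )
    corr = np.corrcoef(oe, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    pc1 = np.full(cmap.n_bins, np.nan)
    pc1[idx] = v
    return CompartmentTrack(cmap.grid, pc1)


def _absorb_short_runs(signs: np.ndarray, min_run: int) -> np.ndarray:
    """Flip sign runs shorter than min_run into the flanking label."""
    s = signs.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(s) + 1):
            if i == len(s) or s[i] != s[start]:
                runs.append((start, i))
                start = i
        if len(runs) <= 1:
            break
        lengths = [b - a for a, b in runs]
        for r, (a, b) in enumerate(runs):
            if lengths[r] >= min_run:
                continue
            left_len = lengths[r - 1] if r > 0 else -1
            right_len = lengths[r + 1] if r + 1 < len(runs) else -1
            donor = r - 1 if left_len >= right_len else r + 1
            s[a:b] = s[runs[donor][0]]
            changed = True
            break
    return s


def orient_and_call(
    track: CompartmentTrack,
    reference: BinTrack,
    convention: str = "A_negative",
    min_run: int = 2,
) -> CompartmentTrack:
    """Orient PC1 against an activity reference and call labels and borders.

    A-like bins are those whose PC1 correlates positively with the reference
    (the reference must increase with activity: gene density, transcription,
    CpG density). Under ``A_negative`` the component is flipped so A-like
    bins are negative. Sign runs shorter than ``min_run`` bins are absorbed
    into their flank before borders are emitted at the remaining transitions.
    """
    if convention not in ("A_negative", "A_positive"):
        raise ValueError(f"unknown convention {convention!r}")
    if reference.grid != track.grid:
        raise ValueError("reference track is on a different grid")
    ok = track.mask & ~reference.missing
    ref = reference.values[ok]
    if np.std(ref) == 0:
        raise ValueError("reference track has zero variance")
    r = float(np.corrcoef(track.pc1[ok], ref)[0, 1])

    pc1 = track.pc1.copy()
    # positively-correlated bins are A-like; flip to satisfy the convention
    if (convention == "A_negative") == (r > 0):
        pc1 = -pc1

    idx = np.flatnonzero(track.mask)
    signs = np.where(pc1[idx] < 0, -1, 1)
    signs = _absorb_short_runs(signs, min_run)

    a_sign = -1 if convention == "A_negative" else 1
    labels = np.full(track.grid.n_bins, "masked", dtype=object)
    labels[idx] = np.where(signs == a_sign, "A", "B")
    borders = [
        int(idx[t]) for t in range(1, len(idx)) if signs[t] != signs[t - 1]
    ]
    return CompartmentTrack(
        track.grid,
        np.where(track.mask, pc1, np.nan),
        orientation_reference=reference.name,
        labels=labels,
        borders=borders,
    )
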