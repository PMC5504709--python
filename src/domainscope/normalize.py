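"""Matrix normalization: iterative correction, replicate merging, smoothing.

Iterative correction (ICE) removes multiplicative per-bin biases by
repeatedly dividing rows and columns by their coverage until all unmasked
row sums are equal; replicates passing a Pearson-correlation gate are merged
by element-wise summation; 5C maps are denoised with a zero-preserving 3x3
median filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ContactMap

__all__ = [
    "BalanceResult",
    "iterative_correction",
    "replicate_correlation",
    "merge_replicates",
    "median_smooth",
]


@dataclass
class BalanceResult:
    corrected: ContactMap
    biases: np.ndarray  # per-bin; NaN on masked bins
    n_iterations: int
    converged: bool


def iterative_correction(
    cmap: ContactMap, tol: float = 1e-5, max_iter: int = 200
) -> BalanceResult:
    """Balance a contact map so unmasked row sums are uniform.

    Bins with zero marginal are auto-masked before balancing. Each round
    divides rows and columns by their sums normalized to the mean unmasked
    row sum, so the total count is preserved up to a global rescaling;
    convergence is declared when the coefficient of variation of the unmasked
    row sums drops below ``tol``. The accumulated per-bin biases satisfy
    ``corrected[i, j] = raw[i, j] / (biases[i] * biases[j])``.
    """
    W = cmap.counts.copy()
    mask = cmap.mask.copy()
    mask &= W.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("all bins are masked or empty; nothing to balance")
    W[~mask, :] = 0.0
    W[:, ~mask] = 0.0

    biases = np.ones(cmap.n_bins)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = W.sum(axis=1)
        sub = s[mask]
        cv = sub.std() / sub.mean()
        if cv < tol:
            converged = True
            break
        norm = np.ones_like(s)
        norm[mask] = sub / sub.mean()
        W /= np.outer(norm, norm)
        biases *= norm
    else:
        sub = W.sum(axis=1)[mask]
        converged = sub.std() / sub.mean() < tol

    biases_out = np.where(mask, biases, np.nan)
    corrected = ContactMap(cmap.grid, W, mask=mask, metadata=dict(cmap.metadata))
    return BalanceResult(corrected, biases_out, it, converged)


def _upper_offdiag(cmap: ContactMap) -> np.ndarray:
    """Unmasked, off-diagonal upper-triangle values as a flat vector."""
    n = cmap.n_bins
    iu, ju = np.triu_indices(n, k=1)
    ok = cmap.mask[iu] & cmap.mask[ju]
    return cmap.counts[iu[ok], ju[ok]]


def replicate_correlation(a: ContactMap, b: ContactMap) -> float:
    """Pearson correlation over unmasked off-diagonal upper-triangle entries."""
    if a.grid != b.grid:
        raise ValueError("replicates are on different grids")
    if not np.array_equal(a.mask, b.mask):
        raise ValueError("replicates carry different masks")
    x, y = _upper_offdiag(a), _upper_offdiag(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(np.corrcoef(x, y)[0, 1])


def merge_replicates(a: ContactMap, b: ContactMap, min_r: float = 0.9) -> ContactMap:
    """Element-wise sum of two replicates; masks are unioned (either-masked).

    Replicates below the correlation gate ``min_r`` are still merged, with a
    warning and a ``low_replicate_correlation`` metadata flag.
    """
    if a.grid != b.grid:
        raise ValueError("replicates are on different grids")
    meta = {**a.metadata, **b.metadata}
    r = replicate_correlation(a, b)
    meta["replicate_pearson_r"] = r
    if not r >= min_r:  # also catches NaN (e.g. a constant replicate)
        warnings.warn(
            f"replicate correlation {r:.3f} below gate {min_r}; merging anyway"
        )
        meta["low_replicate_correlation"] = True
    mask = a.mask & b.mask
    return ContactMap(a.grid, a.counts + b.counts, mask=mask, metadata=meta)


def median_smooth(cmap: ContactMap) -> ContactMap:
    """Zero-preserving 3x3 median filter.

    Every nonzero unmasked element is replaced by the median of the existing
    (nonzero, in-bounds) values of its Moore 3x3 neighborhood including
    itself; all medians are computed from the input matrix. Zero elements
    represent absent data: they are neither smoothed nor allowed to pull a
    measured value to zero, so the zero set of the matrix is exactly
    invariant. Symmetry is restored by smoothing the upper triangle and
    mirroring.
    """
    X = cmap.counts
    n = cmap.n_bins
    out = X.copy()
    for i in range(n):
        if not cmap.mask[i]:
            continue
        for j in range(i, n):
            if not cmap.mask[j] or X[i, j] == 0.0:
                continue
            window = X[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
            vals = window[window != 0.0]
            out[i, j] = np.median(vals)
            out[j, i] = out[i, j]
    return ContactMap(cmap.grid, out, mask=cmap.mask.copy(), metadata=dict(cmap.metadata))
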