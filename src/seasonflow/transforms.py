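"""Compositional and diversity transforms.

Read counts from amplicon surveys are compositional: only relative
information is meaningful.  The robust centred log-ratio (rclr) divides
each taxon's reads by the geometric mean over the *observed* (non-zero)
taxa of the sample before taking logs, leaving zeros as missing rather
than imputing pseudocounts.  The Hellinger transform (square root of
proportions) prepares counts for Euclidean ordination.  Alpha diversity
(richness and Simpson's 1-D) is computed on reads rarefied to a common
depth by subsampling without replacement.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relative_abundance",
    "rclr",
    "hellinger",
    "rarefy",
    "richness",
    "simpson_1_minus_d",
]


def _as_2d(counts: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError("counts must be 1- or 2-dimensional")


def relative_abundance(counts: np.ndarray) -> np.ndarray:
    """Row-normalise counts to proportions (each row sums to 1)."""
    arr, squeeze = _as_2d(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    sums = arr.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("cannot normalise a sample with zero total reads")
    out = arr / sums
    return out[0] if squeeze else out


def rclr(counts: np.ndarray) -> np.ndarray:
    """Robust centred log-ratio transform.

    For each sample, positive counts x_i map to
    ``ln(x_i) - mean(ln x_j over positive j)`` — the log of the count
    divided by the geometric mean over the taxa observed in that sample.
    Zero counts are returned as NaN (missing), and the non-missing
    values of each sample sum to zero.
    """
    arr, squeeze = _as_2d(counts)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=1) <= 0):
        raise ValueError("rclr undefined for an all-zero sample")
    pos = arr > 0
    logs = np.zeros_like(arr)
    np.log(arr, where=pos, out=logs)
    gmean_log = logs.sum(axis=1, keepdims=True) / pos.sum(axis=1, keepdims=True)
    out = np.where(pos, logs - gmean_log, np.nan)
    return out[0] if squeeze else out


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: square roots of relative abundances."""
    return np.sqrt(relative_abundance(counts))


def rarefy(
    counts: np.ndarray,
    depth: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Subsample each sample to ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample, so the output
    row sums are exactly ``depth`` and zero taxa stay zero.  Raises if a
    sample has fewer than ``depth`` reads (callers filter those first).
    Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.asarray(counts)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("rarefaction requires integer counts")
        arr = np.round(arr).astype(np.int64)
    sums = arr.sum(axis=1)
    if np.any(sums < depth):
        bad = np.where(sums < depth)[0]
        raise ValueError(
            f"{bad.size} sample(s) have fewer than {depth} reads; filter first"
        )
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        if sums[i] == depth:
            out[i] = arr[i]
        else:
            out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    return out[0] if squeeze else out


def richness(counts: np.ndarray) -> np.ndarray | int:
    """Number of taxa with at least one read per sample."""
    arr, squeeze = _as_2d(counts)
    r = (arr > 0).sum(axis=1)
    return int(r[0]) if squeeze else r


def simpson_1_minus_d(counts: np.ndarray) -> np.ndarray | float:
    """Simpson diversity reported as 1 - D = 1 - sum(p_i^2)."""
    p = np.atleast_2d(relative_abundance(counts))
    val = 1.0 - (p**2).sum(axis=1)
    return float(val[0]) if np.asarray(counts).ndim == 1 else val
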