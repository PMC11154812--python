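"""Correlation kernels shared by the autonomy-index, CFH and seed-FC stages.

All correlations are plain Pearson product-moment coefficients on the
retained frames of a subject.  Fisher's z (atanh) is used whenever
correlations are averaged or entered into group statistics; raw r is used
inside the autonomy-index threshold counting, which thresholds on r itself.

Zero-variance voxels (possible after masking synthetic data) yield NaN and
are excluded from counts, seeds and group statistics downstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import BoldSeries

__all__ = [
    "pearson_r",
    "fisher_z",
    "clip_r",
    "standardize_columns",
    "correlation_matrix",
    "seed_fc_map",
    "full_fc_row",
    "SeedFCMap",
]

#: correlations are clipped to +/- (1 - R_CLIP_EPS) before atanh
R_CLIP_EPS = 1e-7


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two series; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return float("nan")  # zero-variance flag
    r = float((xd @ yd) / (sx * sy))
    return min(1.0, max(-1.0, r))


def fisher_z(r):
    """Fisher's variance-stabilizing transform, z = atanh(r).

    Raises for |r| >= 1; callers that may produce exact +/-1 clip first via
    :func:`clip_r`.
    """
    arr = np.asarray(r, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and np.any(np.abs(finite) >= 1.0):
        raise ValueError("|r| >= 1 is outside the domain of atanh; clip first")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def clip_r(r, eps: float = R_CLIP_EPS):
    """Clip correlations into (-1, 1) so atanh stays finite."""
    return np.clip(r, -1.0 + eps, 1.0 - eps)


def standardize_columns(data: np.ndarray) -> np.ndarray:
    """Demean columns and scale to unit norm; constant columns become 0.

    With this scaling ``S.T @ S`` is exactly the correlation matrix, and a
    zero column makes every correlation involving it 0 (flagged separately
    by callers via the variance mask).
    """
    data = np.asarray(data, dtype=float)
    centered = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe


def correlation_matrix(series: BoldSeries, block: int = 512) -> np.ndarray:
    """Full V x V correlation matrix, computed in column blocks.

    Entries involving zero-variance voxels are NaN.  Results are independent
    of ``block``.
    """
    s = standardize_columns(series.data)
    v = s.shape[1]
    out = np.empty((v, v), dtype=float)
    for start in range(0, v, block):
        stop = min(start + block, v)
        out[start:stop] = np.clip(s[:, start:stop].T @ s, -1.0, 1.0)
    bad = ~series.finite_variance
    if bad.any():
        out[bad, :] = np.nan
        out[:, bad] = np.nan
    return out


@dataclasses.dataclass
class SeedFCMap:
    """Whole-brain FC of a (possibly multi-voxel) seed time course."""

    seed_voxels: np.ndarray
    r: np.ndarray
    z: np.ndarray
    n_frames: int


def seed_fc_map(series: BoldSeries, seed_voxels: np.ndarray) -> SeedFCMap:
    """Correlate the mean seed time course against every in-mask voxel.

    The seed course is the plain average of the member voxels' series; r is
    Fisher-transformed (clipped) into the attached z map.
    """
    seed_voxels = np.atleast_1d(np.asarray(seed_voxels, dtype=int))
    if seed_voxels.size == 0:
        raise ValueError("empty seed")
    if seed_voxels.min() < 0 or seed_voxels.max() >= series.geometry.n_voxels:
        raise IndexError("seed voxel index outside mask")
    course = series.data[:, seed_voxels].mean(axis=1)
    if course.std() == 0:
        raise ValueError("seed time course has zero variance")
    cd = course - course.mean()
    cd /= np.linalg.norm(cd)
    s = standardize_columns(series.data)
    r = np.clip(cd @ s, -1.0, 1.0)
    r[~series.finite_variance] = np.nan
    z = np.arctanh(clip_r(r))
    return SeedFCMap(seed_voxels=seed_voxels, r=r, z=z, n_frames=series.n_frames)


def full_fc_row(series: BoldSeries, v: int, block: int = 2048) -> np.ndarray:
    """Correlation of voxel ``v`` with every in-mask voxel (self = 1).

    Computed in blocks so peak memory is O(block * T); the result does not
    depend on the block size.  A zero-variance voxel ``v`` yields an
    all-NaN row.
    """
    v = int(v)
    if not 0 <= v < series.geometry.n_voxels:
        raise IndexError("voxel index outside mask")
    if not series.finite_variance[v]:
        return np.full(series.geometry.n_voxels, np.nan)
    x = series.data[:, v]
    xd = x - x.mean()
    xd /= np.linalg.norm(xd)
    n = series.geometry.n_voxels
    out = np.empty(n, dtype=float)
    for start in range(0, n, block):
        stop = min(start + block, n)
        s = standardize_columns(series.data[:, start:stop])
        out[start:stop] = np.clip(xd @ s, -1.0, 1.0)
    out[~series.finite_variance] = np.nan
    return out
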