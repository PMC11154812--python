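"""Voxelwise autonomy-index (AI) maps.

The autonomy index quantifies within- versus cross-hemisphere connectivity
preponderance at each voxel v:

    AI(v) = Ni / Hi  -  Nc / Hc

where Ni (Nc) counts ipsilateral (contralateral) in-mask voxels whose time
series correlate with v above threshold — r > r_threshold AND two-sided
correlation-test p < p_threshold — and Hi, Hc are the total in-mask voxel
counts of the two hemispheres.  Positive AI marks within-hemisphere
specialization.

Conventions (documented choices where the method leaves room):

* the r threshold is one-sided positive: strong negative correlations never
  count;
* the self-correlation r(v, v) = 1 is counted in Ni and Hi/Hc are the full
  hemisphere totals, so counting runs uniformly over every hemisphere voxel
  (this preserves the exact null AI = 0 on mirror-symmetric data: the voxel
  in Ni is matched by its mirror, at correlation 1, in Nc; excluding the
  self would leave Nc = Ni + 1 there).  The self contributes a constant
  1/Hi shared by every voxel of a hemisphere, which cancels in group
  contrasts;
* midline voxels (|x| under half a voxel) belong to neither hemisphere and
  receive no AI value (NaN);
* the effective frame count for the p-test is the subject's post-scrubbing
  frame count.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .core_io import LEFT, MIDLINE, RIGHT, BoldSeries, HemisphereGeometry, MetricMap
from .connectivity import standardize_columns

logger = logging.getLogger(__name__)

__all__ = ["correlation_r_critical", "compute_ai_map"]


def correlation_r_critical(n_frames: int, p_threshold: float) -> float:
    """Smallest r whose two-sided correlation-test p falls below threshold.

    Based on t = r * sqrt((T-2) / (1-r^2)) with T-2 degrees of freedom;
    ``r > r_crit``  iff  ``p < p_threshold`` for positive r.
    """
    df = n_frames - 2
    if df < 1:
        raise ValueError("need at least 3 frames")
    t_crit = stats.t.ppf(1.0 - p_threshold / 2.0, df)
    return float(t_crit / np.sqrt(df + t_crit**2))


def compute_ai_map(
    series: BoldSeries,
    geometry: HemisphereGeometry | None = None,
    r_threshold: float = 0.25,
    p_threshold: float = 0.001,
    block: int = 256,
    return_counts: bool = False,
    swap_hemisphere_roles: bool = False,
) -> MetricMap:
    """Compute a subject's AI map by thresholded connection counting.

    The two conditions combine into a single effective r cutoff
    ``max(r_threshold, r_crit(p_threshold, T))`` because the correlation
    t-test is monotone in r.  When the p condition is the binding one (small
    T) this is logged.  Counting runs over the exact upper bound, strict
    inequalities on both conditions.

    ``swap_hemisphere_roles`` exchanges which hemisphere counts as
    ipsilateral versus contralateral for every voxel; by the definition of
    AI this negates the map exactly (relabeling the hemispheres *and* their
    totals together is instead a no-op, since each voxel keeps the same
    companions).
    """
    geometry = geometry if geometry is not None else series.geometry
    if geometry.n_voxels != series.data.shape[1]:
        raise ValueError("geometry does not match series")
    t = series.n_frames
    r_crit = correlation_r_critical(t, p_threshold)
    if r_crit > r_threshold:
        logger.info(
            "p<%g at T=%d requires r>%.4f > r_threshold=%.3f; the p-based "
            "cutoff is binding",
            p_threshold,
            t,
            r_crit,
            r_threshold,
        )
    thr = max(r_threshold, r_crit)

    s = standardize_columns(series.data)
    side = geometry.side
    left_cols = side == LEFT
    right_cols = side == RIGHT
    hi = {int(LEFT): geometry.hi_left, int(RIGHT): geometry.hi_right}

    v = geometry.n_voxels
    ni = np.zeros(v, dtype=np.int64)
    nc = np.zeros(v, dtype=np.int64)
    for start in range(0, v, block):
        stop = min(start + block, v)
        r_block = s[:, start:stop].T @ s  # rows: voxels in block
        above = r_block > thr
        n_left = above[:, left_cols].sum(axis=1)
        n_right = above[:, right_cols].sum(axis=1)
        blk_side = side[start:stop]
        is_left = blk_side == LEFT
        # self-correlation r(v,v)=1 exceeds thr and is counted in Ni
        ni[start:stop] = np.where(is_left, n_left, n_right)
        nc[start:stop] = np.where(is_left, n_right, n_left)
        mid = blk_side == MIDLINE
        ni[start:stop][mid] = 0
        nc[start:stop][mid] = 0
    if swap_hemisphere_roles:
        ni, nc = nc, ni

    values = np.full(v, np.nan)
    for code in (int(LEFT), int(RIGHT)):
        sel = side == code
        h_ipsi = hi[code]
        h_contra = hi[int(RIGHT) if code == int(LEFT) else int(LEFT)]
        if swap_hemisphere_roles:
            h_ipsi, h_contra = h_contra, h_ipsi
        if h_ipsi == 0 or h_contra == 0:
            continue
        values[sel] = ni[sel] / h_ipsi - nc[sel] / h_contra
    values[~series.finite_variance] = np.nan

    result = MetricMap(geometry=geometry, values=values, kind="AI")
    if return_counts:
        return result, ni, nc
    return result
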