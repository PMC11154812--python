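"""Connectivity between functionally homotopic voxels (CFH).

Homotopy is defined *functionally*, not by structural mirroring: for each
voxel v, seed-based whole-brain FC maps are averaged across all
participants (both groups pooled, Fisher-z averaged by default) and the
contralateral voxel with the highest group-mean connectivity becomes v's
homotopic seed.  A subject's CFH(v) is then the Pearson correlation between
v's time series and its seed's.

The argmax selection inflates CFH upward under the null, but the bias is
identical in both groups when seeds are defined on the pooled cohort, so
group contrasts remain centered (a property the tests check).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .core_io import LEFT, RIGHT, BoldSeries, HemisphereGeometry, MetricMap
from .connectivity import clip_r, standardize_columns

logger = logging.getLogger(__name__)

__all__ = [
    "SeedMap",
    "CFHMap",
    "group_mean_fc_row",
    "group_mean_fc_matrix",
    "define_homotopic_seeds",
    "compute_cfh_map",
]


@dataclasses.dataclass
class SeedMap:
    """Per-voxel index of the functionally homotopic contralateral seed.

    ``seed_index`` is -1 where no seed is defined (midline, zero-variance,
    or all-undefined contralateral row); ``tie_count`` records how many
    contralateral voxels attained the maximum (ties broken by smallest
    storage index).
    """

    geometry: HemisphereGeometry
    seed_index: np.ndarray
    tie_count: np.ndarray
    source: dict

    def __post_init__(self) -> None:
        self.seed_index = np.asarray(self.seed_index, dtype=np.int64)
        self.tie_count = np.asarray(self.tie_count, dtype=np.int64)


@dataclasses.dataclass
class CFHMap:
    """A subject's CFH values together with the seed map that produced them."""

    metric: MetricMap
    seed_map: SeedMap


def _accumulate_mean_fc(
    cohort: list[BoldSeries], use_fisher: bool, block: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of (optionally atanh-transformed) correlation matrices + counts."""
    geometry = cohort[0].geometry
    v = geometry.n_voxels
    acc = np.zeros((v, v), dtype=np.float64)
    counts = np.zeros((v, v), dtype=np.int32)
    for series in cohort:
        if series.geometry.n_voxels != v:
            raise ValueError("all subjects must share one geometry")
        s = standardize_columns(series.data)
        valid = series.finite_variance
        vv = np.outer(valid, valid)
        for start in range(0, v, block):
            stop = min(start + block, v)
            r = np.clip(s[:, start:stop].T @ s, -1.0, 1.0)
            if use_fisher:
                r = np.arctanh(clip_r(r))
            r[~vv[start:stop]] = 0.0
            acc[start:stop] += r
        counts += vv
    return acc, counts


def group_mean_fc_matrix(
    cohort: list[BoldSeries], use_fisher: bool = True, block: int = 512
) -> np.ndarray:
    """Group-mean V x V FC, averaged across ALL subjects pooled.

    Per-subject correlations are Fisher-transformed (default), averaged
    over the subjects where both voxels have variance, then inverse
    transformed.  Entries with no valid subject are NaN.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects to average FC")
    acc, counts = _accumulate_mean_fc(cohort, use_fisher, block)
    with np.errstate(invalid="ignore"):
        mean = acc / counts
    mean[counts == 0] = np.nan
    n_excluded = int((counts < len(cohort)).sum())
    if n_excluded:
        logger.info("%d FC entries averaged over fewer subjects", n_excluded)
    return np.tanh(mean) if use_fisher else mean


def group_mean_fc_row(
    cohort: list[BoldSeries], v: int, use_fisher: bool = True
) -> np.ndarray:
    """One row of the pooled group-mean FC (cheap single-voxel variant)."""
    if len(cohort) < 1:
        raise ValueError("empty cohort")
    n_vox = cohort[0].geometry.n_voxels
    acc = np.zeros(n_vox)
    counts = np.zeros(n_vox, dtype=int)
    for series in cohort:
        from .connectivity import full_fc_row

        row = full_fc_row(series, v)
        ok = np.isfinite(row)
        vals = np.arctanh(clip_r(row[ok])) if use_fisher else row[ok]
        acc[ok] += vals
        counts[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = acc / counts
    mean[counts == 0] = np.nan
    return np.tanh(mean) if use_fisher else mean


def define_homotopic_seeds(
    cohort: list[BoldSeries],
    use_fisher: bool = True,
    subjects: list[str] | None = None,
    block: int = 512,
) -> SeedMap:
    """Assign each hemispheric voxel its contralateral group-FC argmax.

    ``subjects`` optionally restricts the averaging set (per-group or
    leave-one-out sensitivity analyses); the default pools everyone.  The
    seed relation is not required to be symmetric.
    """
    if subjects is not None:
        cohort = [s for s in cohort if s.subject_id in set(subjects)]
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects to define seeds")
    geometry = cohort[0].geometry
    mean_fc = group_mean_fc_matrix(cohort, use_fisher=use_fisher, block=block)
    side = geometry.side
    n = geometry.n_voxels
    seed = np.full(n, -1, dtype=np.int64)
    ties = np.zeros(n, dtype=np.int64)
    contra_of = {int(LEFT): side == RIGHT, int(RIGHT): side == LEFT}
    for code, contra_mask in contra_of.items():
        rows = np.flatnonzero(side == code)
        contra_idx = np.flatnonzero(contra_mask)
        if contra_idx.size == 0 or rows.size == 0:
            continue
        sub = mean_fc[np.ix_(rows, contra_idx)]
        all_nan = np.all(~np.isfinite(sub), axis=1)
        filled = np.where(np.isfinite(sub), sub, -np.inf)
        arg = np.argmax(filled, axis=1)  # first max -> smallest storage index
        best = filled[np.arange(rows.size), arg]
        ties_here = (filled == best[:, None]).sum(axis=1)
        seed[rows] = contra_idx[arg]
        ties[rows] = ties_here
        seed[rows[all_nan]] = -1
        ties[rows[all_nan]] = 0
    n_seedless = int(((side == LEFT) | (side == RIGHT)).sum() - (seed >= 0).sum())
    if n_seedless:
        logger.info("%d hemispheric voxels are seedless", n_seedless)
    return SeedMap(
        geometry=geometry,
        seed_index=seed,
        tie_count=ties,
        source={
            "n_subjects": len(cohort),
            "subjects": [s.subject_id for s in cohort],
            "transform": "fisher_z" if use_fisher else "raw_r",
        },
    )


def compute_cfh_map(series: BoldSeries, seeds: SeedMap) -> CFHMap:
    """CFH(v) = Pearson r between voxel v and its contralateral seed voxel.

    Seedless voxels and zero-variance voxels get NaN and are excluded from
    downstream statistics.
    """
    if seeds.geometry.n_voxels != series.geometry.n_voxels or not seeds.geometry.grid.matches(series.geometry.grid):
        raise ValueError("seed map geometry does not match series")
    s = standardize_columns(series.data)
    n = series.geometry.n_voxels
    values = np.full(n, np.nan)
    defined = seeds.seed_index >= 0
    idx = np.flatnonzero(defined)
    if idx.size:
        prod = np.einsum("ij,ij->j", s[:, idx], s[:, seeds.seed_index[idx]])
        values[idx] = np.clip(prod, -1.0, 1.0)
    valid = series.finite_variance
    values[~valid] = np.nan
    # seed voxel itself zero-variance -> correlation undefined
    bad_seed = defined & ~valid[np.maximum(seeds.seed_index, 0)]
    values[bad_seed] = np.nan
    metric = MetricMap(geometry=series.geometry, values=values, kind="CFH")
    return CFHMap(metric=metric, seed_map=seeds)
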