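"""Group-level inference on metric maps.

Covers map smoothing, voxelwise two-sample t contrasts (AD - HC), cluster
extent family-wise-error control by label permutation, sphere-ROI
extraction around cluster peaks, and covariate-adjusted (partial)
correlation between regional imaging values and cognition.

Cluster correction: the observed t map is thresholded two-sidedly at the
t value matching the cluster-forming voxel p; suprathreshold voxels are
grouped into connected components (26-connectivity by default), separately
for positive and negative excursions.  The null distribution of the
maximum cluster extent (over both signs) is built by rerunning the
thresholding under random relabelings of the group assignment, and each
observed cluster receives

    p_corrected = (1 + #{null max extent >= observed extent}) / (n_perm + 1).

This targets the same family-wise error rate as parametric random-field
cluster correction while making no smoothness assumptions.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_io import HemisphereGeometry, MetricMap

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDesign",
    "ClusterInferenceResult",
    "smooth_map",
    "voxelwise_two_sample_t",
    "cluster_fwe_permutation",
    "extract_sphere_mean",
    "extract_cluster_mean",
    "partial_correlation",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # = 2.3548...

CLUSTER_TABLE_COLUMNS = [
    "label",
    "sign",
    "peak_x_mm",
    "peak_y_mm",
    "peak_z_mm",
    "peak_t",
    "extent_voxels",
    "p_corrected",
    "significant",
]


@dataclasses.dataclass
class GroupDesign:
    """Subject ids, AD/HC group labels and optional covariate columns."""

    subject_ids: list[str]
    labels: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.subject_ids) != self.labels.shape[0]:
            raise ValueError("subject_ids and labels must align")
        groups, counts = np.unique(self.labels.astype(str), return_counts=True)
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {list(groups)}")
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 subjects")

    @property
    def group_names(self) -> tuple[str, str]:
        """(positive, reference) groups; AD - HC sign convention."""
        groups = sorted(set(self.labels.astype(str)))
        if set(groups) == {"AD", "HC"}:
            return ("AD", "HC")
        return (groups[0], groups[1])


def smooth_map(metric_map: MetricMap, fwhm_mm: float) -> MetricMap:
    """Masked Gaussian smoothing with kernel renormalization at edges.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, in mm, converted to voxels by
    the grid spacing.  Out-of-mask (and NaN) voxels carry zero weight, so a
    constant map stays constant and values never bleed across the mask
    boundary.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return MetricMap(
            geometry=metric_map.geometry,
            values=metric_map.values.copy(),
            kind=metric_map.kind,
        )
    geom = metric_map.geometry
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / geom.grid.voxel_size_mm
    finite = np.isfinite(metric_map.values)
    vals = np.where(finite, metric_map.values, 0.0)
    vol = geom.scatter(vals, fill=0.0)
    weight = geom.scatter(finite.astype(float), fill=0.0)
    num = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(weight, sigma=sigma_vox, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    out = geom.gather(sm)
    out[~finite] = np.nan
    return MetricMap(geometry=geom, values=out, kind=metric_map.kind)


def _stack_maps(maps: list[MetricMap]) -> tuple[np.ndarray, HemisphereGeometry]:
    geom = maps[0].geometry
    for m in maps:
        if m.geometry.n_voxels != geom.n_voxels:
            raise ValueError("all maps must share one geometry")
    return np.vstack([m.values for m in maps]), geom


def _two_sample_t(y: np.ndarray, in_pos: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; positive group minus rest."""
    n1 = int(in_pos.sum())
    n2 = y.shape[0] - n1
    y1 = y[in_pos]
    y2 = y[~in_pos]
    m1 = y1.mean(axis=0)
    m2 = y2.mean(axis=0)
    ss1 = ((y1 - m1) ** 2).sum(axis=0)
    ss2 = ((y2 - m2) ** 2).sum(axis=0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t[sp2 == 0] = np.nan
    return t


def voxelwise_two_sample_t(
    maps: list[MetricMap], design: GroupDesign
) -> MetricMap:
    """Pooled-variance two-sample t map (AD - HC), df = n1 + n2 - 2.

    Voxels that are NaN in any subject, or with zero pooled variance, are
    flagged NaN.
    """
    y, geom = _stack_maps(maps)
    if y.shape[0] != len(design.subject_ids):
        raise ValueError("number of maps must match design rows")
    pos, _ = design.group_names
    in_pos = design.labels.astype(str) == pos
    valid = np.all(np.isfinite(y), axis=0)
    t = np.full(y.shape[1], np.nan)
    t[valid] = _two_sample_t(y[:, valid], in_pos)
    return MetricMap(geometry=geom, values=t, kind="TSTAT")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


def _clusters_from_t(
    t_in_mask: np.ndarray,
    geom: HemisphereGeometry,
    t_crit: float,
    structure: np.ndarray,
    scratch: np.ndarray,
) -> list[dict]:
    """Connected suprathreshold components, both signs; peak = max |t|."""
    out = []
    for sign in (1, -1):
        supra = (t_in_mask > t_crit) if sign == 1 else (t_in_mask < -t_crit)
        if not supra.any():
            continue
        scratch[:] = False
        scratch[tuple(geom.voxel_ijk[supra].T)] = True
        labeled, n_lab = ndimage.label(scratch, structure=structure)
        lab_in_mask = labeled[tuple(geom.voxel_ijk.T)]
        for lab in range(1, n_lab + 1):
            members = np.flatnonzero(lab_in_mask == lab)
            tvals = t_in_mask[members]
            peak_local = int(np.argmax(np.abs(tvals)))  # first-max tie-break
            out.append(
                {
                    "sign": sign,
                    "members": members,
                    "extent": int(members.size),
                    "peak_index": int(members[peak_local]),
                    "peak_t": float(tvals[peak_local]),
                }
            )
    return out


def _max_extent(
    t_in_mask: np.ndarray,
    geom: HemisphereGeometry,
    t_crit: float,
    structure: np.ndarray,
    scratch: np.ndarray,
) -> int:
    best = 0
    for sign in (1, -1):
        supra = (t_in_mask > t_crit) if sign == 1 else (t_in_mask < -t_crit)
        n_supra = int(supra.sum())
        if n_supra <= best:
            continue
        scratch[:] = False
        scratch[tuple(geom.voxel_ijk[supra].T)] = True
        labeled, n_lab = ndimage.label(scratch, structure=structure)
        if n_lab:
            sizes = np.bincount(labeled.ravel())[1:]
            best = max(best, int(sizes.max()))
    return best


@dataclasses.dataclass
class ClusterInferenceResult:
    """Observed t map, all suprathreshold clusters, and the permutation null."""

    t_map: MetricMap
    clusters: pd.DataFrame
    cluster_members: list[np.ndarray]
    null_max_extent: np.ndarray
    n_perm_used: int
    t_critical: float

    @property
    def table(self) -> pd.DataFrame:
        """Significant clusters only — the published-table schema."""
        return self.clusters[self.clusters["significant"]].reset_index(drop=True)

    def significant_members(self, sign: int | None = None) -> list[np.ndarray]:
        out = []
        for i, row in self.clusters.iterrows():
            if row["significant"] and (sign is None or row["sign"] == sign):
                out.append(self.cluster_members[i])
        return out


def cluster_fwe_permutation(
    maps: list[MetricMap],
    design: GroupDesign,
    voxel_p: float = 1e-4,
    cluster_alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int = 0,
    connectivity: int = 26,
) -> ClusterInferenceResult:
    """Cluster-extent FWE control by group-label permutation.

    When the number of distinct relabelings is below ``n_perm`` the full
    set is enumerated instead (with a log message).  Deterministic given
    ``seed``; corrected p values are invariant to swapping the two group
    labels, since extents enter unsigned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y, geom = _stack_maps(maps)
    n = y.shape[0]
    if n != len(design.subject_ids):
        raise ValueError("number of maps must match design rows")
    pos, _ = design.group_names
    in_pos = design.labels.astype(str) == pos
    n1 = int(in_pos.sum())
    df = n - 2
    t_crit = float(stats.t.ppf(1.0 - voxel_p / 2.0, df))
    valid = np.all(np.isfinite(y), axis=0)
    # restrict to valid voxels for the permutation engine; NaN columns can
    # never enter a cluster
    yv = np.ascontiguousarray(y[:, valid])
    valid_idx = np.flatnonzero(valid)
    structure = _connectivity_structure(connectivity)
    scratch = np.zeros(geom.grid.dims, dtype=bool)

    def t_full(in_pos_vec: np.ndarray) -> np.ndarray:
        t = np.full(y.shape[1], np.nan)
        tv = _two_sample_t(yv, in_pos_vec)
        tv[~np.isfinite(tv)] = 0.0
        t[valid_idx] = tv
        return t

    t_obs = t_full(in_pos)
    obs_clusters = _clusters_from_t(
        np.nan_to_num(t_obs, nan=0.0), geom, t_crit, structure, scratch
    )

    n_distinct = comb(n, n1)
    rng = np.random.default_rng(seed)
    if n_distinct - 1 <= n_perm:
        logger.info(
            "only %d distinct relabelings; enumerating all instead of %d draws",
            n_distinct,
            n_perm,
        )
        perms = []
        observed_set = frozenset(np.flatnonzero(in_pos).tolist())
        for combo in combinations(range(n), n1):
            if frozenset(combo) == observed_set:
                continue
            vec = np.zeros(n, dtype=bool)
            vec[list(combo)] = True
            perms.append(vec)
    else:
        perms = []
        for _ in range(n_perm):
            vec = np.zeros(n, dtype=bool)
            vec[rng.choice(n, size=n1, replace=False)] = True
            perms.append(vec)

    null_max = np.empty(len(perms), dtype=np.int64)
    for k, vec in enumerate(perms):
        t_perm = _two_sample_t(yv, vec)
        t_perm[~np.isfinite(t_perm)] = 0.0
        tp = np.zeros(y.shape[1])
        tp[valid_idx] = t_perm
        null_max[k] = _max_extent(tp, geom, t_crit, structure, scratch)

    n_used = len(perms)
    rows = []
    members = []
    mm = geom.mm_coords
    for c in obs_clusters:
        p_corr = (1.0 + int((null_max >= c["extent"]).sum())) / (n_used + 1.0)
        peak_mm = mm[c["peak_index"]]
        rows.append(
            {
                "label": f"cluster_{len(rows) + 1}",
                "sign": c["sign"],
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_t": c["peak_t"],
                "extent_voxels": c["extent"],
                "p_corrected": p_corr,
                "significant": bool(p_corr < cluster_alpha),
            }
        )
        members.append(c["members"])
    clusters = pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)
    if len(clusters):
        order = np.argsort(-clusters["extent_voxels"].to_numpy(), kind="stable")
        clusters = clusters.iloc[order].reset_index(drop=True)
        members = [members[i] for i in order]
        clusters["label"] = [f"cluster_{i + 1}" for i in range(len(clusters))]
    return ClusterInferenceResult(
        t_map=MetricMap(geometry=geom, values=t_obs, kind="TSTAT"),
        clusters=clusters,
        cluster_members=members,
        null_max_extent=null_max,
        n_perm_used=n_used,
        t_critical=t_crit,
    )


def extract_sphere_mean(
    metric_map: MetricMap, center_mm: np.ndarray, radius_mm: float
) -> tuple[float, int]:
    """Mean of in-mask voxels whose centers fall within a sphere.

    Returns (mean, number of voxels included); raises if the sphere catches
    no in-mask voxel with a finite value.
    """
    center_mm = np.asarray(center_mm, dtype=float).reshape(3)
    mm = metric_map.geometry.mm_coords
    dist = np.linalg.norm(mm - center_mm, axis=1)
    inside = (dist <= radius_mm) & np.isfinite(metric_map.values)
    count = int(inside.sum())
    if count == 0:
        raise ValueError(
            f"no in-mask voxels within {radius_mm} mm of {center_mm.tolist()}"
        )
    return float(metric_map.values[inside].mean()), count


def extract_cluster_mean(metric_map: MetricMap, members: np.ndarray) -> float:
    """Mean map value over a cluster's member voxels (NaN-aware)."""
    vals = metric_map.values[np.asarray(members, dtype=int)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cluster has no finite values on this map")
    return float(vals.mean())


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Education-style covariate-adjusted Pearson correlation.

    Both variables are residualized on [intercept, covariates] by least
    squares; the correlation of the residuals is tested against t with
    df = n - 2 - k (two sided).  Collinear covariates fall back to the
    pseudoinverse with a logged warning.  Returns (r, p); r is NaN when a
    residual vector vanishes (e.g. y is exactly a covariate).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("collinear covariates; using pseudoinverse")
    pinv = np.linalg.pinv(design)
    rx = x - design @ (pinv @ x)
    ry = y - design @ (pinv @ y)
    sx = np.linalg.norm(rx)
    sy = np.linalg.norm(ry)
    # residual vanishing to rounding noise (e.g. y is exactly a covariate)
    if sx <= 1e-10 * max(np.linalg.norm(x), 1e-300) or sy <= 1e-10 * max(
        np.linalg.norm(y), 1e-300
    ):
        return float("nan"), float("nan")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
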