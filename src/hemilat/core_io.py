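"""Data model, volumetric/tabular I/O and hemisphere geometry.

Everything downstream works on masked two-dimensional ``time x voxel``
arrays tied to a :class:`HemisphereGeometry`, which records the voxel grid,
the analysis mask, per-voxel hemisphere labels and the structural mirror
(x -> -x in template mm space) of each voxel.  Voxel storage order is fixed
once — row-major over the (x, y, z) array axes restricted to the mask — and
every module relies on it (argmax tie-breaking in seed definition, cluster
peak tie-breaking, feature ordering).

Volumes are NIfTI-1 (plain or gzipped) via nibabel; tables are TSV with a
named header row.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LEFT",
    "RIGHT",
    "MIDLINE",
    "VolumeGrid",
    "HemisphereGeometry",
    "BoldSeries",
    "MetricMap",
    "GeometryError",
    "InsufficientDataError",
    "partition_hemispheres",
    "load_bold_series",
    "save_metric_map",
    "load_metric_map",
    "save_volume",
]

# hemisphere codes; MNI convention: negative x = left
LEFT = np.int8(0)
RIGHT = np.int8(1)
MIDLINE = np.int8(2)

METRIC_KINDS = ("AI", "CFH", "FC_Z", "TSTAT")


class GeometryError(ValueError):
    """Grid/affine/mask inconsistency."""


class InsufficientDataError(ValueError):
    """Too few time points (or frames left after scrubbing) to correlate."""


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with an affine mapping indices to template mm.

    Parameters
    ----------
    dims
        Voxels per axis, three positive integers.
    affine
        4x4 matrix mapping homogeneous voxel indices (i, j, k, 1) to
        template mm coordinates (the NIfTI qform/sform convention).
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if any(d <= 0 for d in dims):
            raise GeometryError(f"dims must be strictly positive, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Column norms of the affine's 3x3 block (mm per voxel per axis)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map integer voxel indices (..., 3) to mm coordinates of centers."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_mm` (continuous voxel coordinates)."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclasses.dataclass(frozen=True)
class HemisphereGeometry:
    """Mask geometry with hemisphere labels and structural mirror index.

    Attributes
    ----------
    grid : VolumeGrid
    mask : 3-D boolean array, the analysis mask.
    voxel_ijk : (V, 3) int array, in-mask voxel indices in storage order.
    side : (V,) int8, LEFT / RIGHT / MIDLINE per in-mask voxel.
    mirror_index : (V,) int, storage index of the structurally mirrored
        voxel (x -> -x in mm), or -1 where the mirror falls outside the mask.
    hi_left, hi_right : voxel counts per hemisphere within the mask
        (midline voxels counted in neither).
    """

    grid: VolumeGrid
    mask: np.ndarray
    voxel_ijk: np.ndarray
    side: np.ndarray
    mirror_index: np.ndarray
    hi_left: int
    hi_right: int

    @property
    def n_voxels(self) -> int:
        return self.voxel_ijk.shape[0]

    @property
    def mm_coords(self) -> np.ndarray:
        """(V, 3) mm coordinates of in-mask voxel centers."""
        return self.grid.voxel_to_mm(self.voxel_ijk)

    def scatter(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a per-in-mask-voxel vector back into the 3-D grid."""
        values = np.asarray(values)
        vol = np.full(self.grid.dims, fill, dtype=float)
        vol[tuple(self.voxel_ijk.T)] = values
        return vol

    def gather(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask values from a 3-D grid array, storage order."""
        if volume.shape != tuple(self.grid.dims):
            raise GeometryError(
                f"volume shape {volume.shape} != grid dims {self.grid.dims}"
            )
        return volume[tuple(self.voxel_ijk.T)]

    def swap_hemispheres(self) -> "HemisphereGeometry":
        """Return a geometry with LEFT and RIGHT labels exchanged.

        Used for the sign-flip symmetry of the autonomy index; mirror
        indices and counts are carried over with the roles swapped.
        """
        side = self.side.copy()
        left = self.side == LEFT
        right = self.side == RIGHT
        side[left] = RIGHT
        side[right] = LEFT
        return HemisphereGeometry(
            grid=self.grid,
            mask=self.mask,
            voxel_ijk=self.voxel_ijk,
            side=side,
            mirror_index=self.mirror_index,
            hi_left=self.hi_right,
            hi_right=self.hi_left,
        )


def partition_hemispheres(grid: VolumeGrid, mask: np.ndarray) -> HemisphereGeometry:
    """Label in-mask voxels by hemisphere and compute the mirror index.

    A voxel is MIDLINE exactly when the absolute mm x-coordinate of its
    center is below half an x voxel width; midline voxels belong to neither
    hemisphere count.  The mirror of a voxel negates its mm x-coordinate and
    takes the nearest voxel center; if that voxel is out of grid or out of
    mask the mirror is undefined (-1).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid.dims):
        raise GeometryError(f"mask shape {mask.shape} != grid dims {grid.dims}")
    voxel_ijk = np.argwhere(mask)  # row-major (x, y, z) order
    mm = grid.voxel_to_mm(voxel_ijk)
    half_vx = grid.voxel_size_mm[0] / 2.0
    x = mm[:, 0]
    side = np.where(x < 0, LEFT, RIGHT).astype(np.int8)
    side[np.abs(x) < half_vx - 1e-9] = MIDLINE

    # mirror: negate mm x, map back to nearest voxel index
    mirrored_mm = mm * np.array([-1.0, 1.0, 1.0])
    mirrored_ijk = np.rint(grid.mm_to_voxel(mirrored_mm)).astype(int)
    in_bounds = np.all(
        (mirrored_ijk >= 0) & (mirrored_ijk < np.array(grid.dims)), axis=1
    )
    flat_lookup = np.full(grid.dims, -1, dtype=np.int64)
    flat_lookup[tuple(voxel_ijk.T)] = np.arange(voxel_ijk.shape[0])
    mirror_index = np.full(voxel_ijk.shape[0], -1, dtype=np.int64)
    ok = in_bounds
    mirror_index[ok] = flat_lookup[tuple(mirrored_ijk[ok].T)]

    hi_left = int(np.count_nonzero(side == LEFT))
    hi_right = int(np.count_nonzero(side == RIGHT))
    return HemisphereGeometry(
        grid=grid,
        mask=mask,
        voxel_ijk=voxel_ijk,
        side=side,
        mirror_index=mirror_index,
        hi_left=hi_left,
        hi_right=hi_right,
    )


@dataclasses.dataclass
class BoldSeries:
    """One subject's masked BOLD data as a T x V matrix.

    ``kept_frames`` indexes retained time points relative to the original
    scan, so scrubbing leaves an audit trail.  Zero-variance columns are
    permitted but flagged in ``finite_variance``.
    """

    subject_id: str
    geometry: HemisphereGeometry
    data: np.ndarray
    tr_s: float
    kept_frames: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be T x V")
        if self.data.shape[1] != self.geometry.n_voxels:
            raise GeometryError(
                f"data has {self.data.shape[1]} columns, geometry has "
                f"{self.geometry.n_voxels} in-mask voxels"
            )
        if self.data.shape[0] < 10:
            raise InsufficientDataError(
                f"{self.data.shape[0]} time points < 10; too few to correlate"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        self.kept_frames = np.asarray(self.kept_frames, dtype=int)
        if self.kept_frames.shape[0] != self.data.shape[0]:
            raise ValueError("kept_frames length must equal T")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def finite_variance(self) -> np.ndarray:
        """Boolean flag per voxel: column has nonzero variance."""
        return self.data.std(axis=0) > 0

    def with_data(self, data: np.ndarray, kept_frames: np.ndarray | None = None) -> "BoldSeries":
        return BoldSeries(
            subject_id=self.subject_id,
            geometry=self.geometry,
            data=data,
            tr_s=self.tr_s,
            kept_frames=self.kept_frames if kept_frames is None else kept_frames,
        )


@dataclasses.dataclass
class MetricMap:
    """A per-in-mask-voxel scalar map (AI, CFH, Fisher-z FC or t)."""

    geometry: HemisphereGeometry
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"kind must be one of {METRIC_KINDS}")
        if self.values.shape != (self.geometry.n_voxels,):
            raise GeometryError("values length must equal in-mask voxel count")
        if self.kind in ("AI", "CFH"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError(f"{self.kind} values must lie in [-1, 1]")


def _load_img(path: str | Path) -> nib.Nifti1Image:
    img = nib.load(str(path))
    return img


def load_bold_series(
    path: str | Path,
    mask_path: str | Path,
    drop_initial: int = 10,
    subject_id: str | None = None,
    geometry: HemisphereGeometry | None = None,
) -> BoldSeries:
    """Load a 4-D NIfTI, drop initial volumes, mask, and flatten to T x V.

    The first ``drop_initial`` volumes are discarded (scanner equilibration);
    remaining frames are recorded in ``kept_frames``.  If ``geometry`` is
    given the mask file is only checked for grid agreement.
    """
    img = _load_img(path)
    if img.ndim != 4:
        raise GeometryError(f"expected a 4-D image, got shape {img.shape}")
    grid = VolumeGrid(dims=img.shape[:3], affine=img.affine)
    if geometry is None:
        mask_img = _load_img(mask_path)
        mask_grid = VolumeGrid(dims=mask_img.shape[:3], affine=mask_img.affine)
        if not grid.matches(mask_grid):
            raise GeometryError("mask grid does not match BOLD grid")
        geometry = partition_hemispheres(grid, np.asarray(mask_img.dataobj) > 0)
    elif not grid.matches(geometry.grid):
        raise GeometryError("BOLD grid does not match supplied geometry")

    n_vol = img.shape[3]
    drop_initial = int(drop_initial)
    if drop_initial < 0:
        raise ValueError("drop_initial must be nonnegative")
    if n_vol - drop_initial < 10:
        raise InsufficientDataError(
            f"{n_vol} volumes minus drop_initial={drop_initial} leaves fewer "
            "than 10 frames"
        )
    data4d = np.asarray(img.dataobj, dtype=float)[..., drop_initial:]
    data = data4d[tuple(geometry.voxel_ijk.T)].T  # T x V, storage order
    kept = np.arange(drop_initial, n_vol)
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return BoldSeries(
        subject_id=subject_id,
        geometry=geometry,
        data=np.ascontiguousarray(data),
        tr_s=float(img.header.get_zooms()[3]) if img.header.get_zooms()[3] > 0 else 2.0,
        kept_frames=kept,
    )


def save_volume(grid: VolumeGrid, volume: np.ndarray, path: str | Path) -> None:
    """Write a 3-D (or 4-D) array on ``grid`` as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), grid.affine)
    nib.save(img, str(path))


def save_metric_map(metric_map: MetricMap, path: str | Path) -> None:
    """Scatter a metric map into its grid (out-of-mask and NaN = 0) and save."""
    values = np.where(np.isfinite(metric_map.values), metric_map.values, 0.0)
    vol = metric_map.geometry.scatter(values, fill=0.0)
    save_volume(metric_map.geometry.grid, vol, path)


def load_metric_map(
    path: str | Path, geometry: HemisphereGeometry, kind: str
) -> MetricMap:
    img = _load_img(path)
    grid = VolumeGrid(dims=img.shape[:3], affine=img.affine)
    if not grid.matches(geometry.grid):
        raise GeometryError("map grid does not match geometry")
    vol = np.asarray(img.dataobj, dtype=float)
    return MetricMap(geometry=geometry, values=geometry.gather(vol), kind=kind)
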