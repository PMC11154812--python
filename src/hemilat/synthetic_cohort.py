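"""Synthetic two-group resting-state cohort with known ground truth.

The generator emulates the statistical structure the analysis is designed
to detect, on a desk-scale symmetric grid:

* **Homotopic coupling.**  Every left-hemisphere voxel and its structural
  mirror share a latent unit-variance source with mixing weight sqrt(rho),
  so the population correlation of a mirror pair is exactly rho (analytic
  and invertible).  Controls couple at ``base_homotopic_rho`` everywhere.
* **Planted CFH lesion.**  Inside ``cfh_roi`` the patient group's coupling
  drops by ``delta_rho``; a per-subject jitter on the ROI coupling (both
  groups) provides the individual differences that cognitive scores track.
* **Planted specialization (AI) effect.**  Inside ``ai_roi`` patients gain
  a shared ipsilateral source (weight sqrt(ipsilateral_gain)) raising
  within-hemisphere correlations, while mirror coupling of those voxels is
  attenuated by ``contralateral_loss`` — together raising the autonomy
  index.
* **Noise.**  Each latent source is an AR(1) process mixed with white
  noise, both unit variance; weak global WM/CSF signals leak into every
  voxel and are emitted as confound columns for the denoising stage.
* **Motion.**  Slow random-walk traces with occasional spike displacements
  that framewise-displacement scrubbing should remove.
* **Phenotype.**  Group, age, sex, education (group-shifted, as in the
  emulated cohort) and cognitive scores; MoCA- and AVLT-like scores are
  linear-Gaussian in the subject's planted-ROI coupling (Fisher z) with an
  education term.

All randomness flows from the single ``seed``; two runs of the same spec
are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core_io import (
    LEFT,
    BoldSeries,
    HemisphereGeometry,
    VolumeGrid,
    partition_hemispheres,
    save_volume,
)
from .denoise import MOTION_COLUMNS, ConfoundSet

__all__ = [
    "ScoreModel",
    "CohortSpec",
    "Cohort",
    "GroundTruth",
    "default_grid",
    "default_mask",
    "generate_cohort",
    "write_phenotype_table",
    "write_cohort",
    "load_cohort",
]

_BURN_IN = 50


@dataclasses.dataclass(frozen=True)
class ScoreModel:
    """Linear-Gaussian link from planted-ROI coupling (Fisher z) to scores.

    ``score = group_mean + slope * (z_subject - group_mean_z)
              + edu_beta * (education - group_mean_education) + noise``.
    """

    slope: float = 20.0
    noise_sd: float = 2.5
    edu_beta: float = 0.3
    moca_group_means: tuple[float, float] = (25.0, 9.4)  # (HC, AD)
    avlt_slope_factor: float = 0.3


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the seed determines everything."""

    n_per_group: int = 20
    dims: tuple[int, int, int] = (16, 20, 16)
    voxel_size_mm: float = 9.0
    n_frames: int = 160
    tr_s: float = 2.0
    ar1_phi: float = 0.3
    white_frac: float = 0.4
    base_homotopic_rho: float = 0.6
    delta_rho: float = 0.3
    cfh_roi_box: tuple = ((3, 6), (9, 12), (7, 9))
    ipsilateral_gain: float = 0.5
    contralateral_loss: float = 0.3
    ai_roi_box: tuple = ((3, 6), (4, 7), (7, 9))
    subject_rho_sd: float = 0.06
    motion_spike_rate: float = 0.03
    confound_weight: float = 0.15
    drop_initial: int = 10
    score_model: ScoreModel = ScoreModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        if not 0 <= self.base_homotopic_rho <= 1:
            raise ValueError("base_homotopic_rho must be in [0, 1]")
        if self.base_homotopic_rho - self.delta_rho < 0:
            raise ValueError("delta_rho cannot exceed base_homotopic_rho")
        if not 0 <= self.ipsilateral_gain < 1:
            raise ValueError("ipsilateral_gain must be in [0, 1)")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")


@dataclasses.dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    pair_left: np.ndarray
    pair_right: np.ndarray
    rho_map_by_group: dict[str, np.ndarray]
    cfh_roi: np.ndarray          # left-hemisphere ROI, storage indices
    cfh_effect: np.ndarray       # every voxel whose pair coupling differs
                                 # between groups (both hemispheres; includes
                                 # the contralateral_loss part of the AI ROI)
    ai_roi: np.ndarray           # left-hemisphere ROI with raised AI
    subject_roi_rho: dict[str, float]


@dataclasses.dataclass
class Cohort:
    spec: CohortSpec
    geometry: HemisphereGeometry
    subjects: list[BoldSeries]
    confounds: dict[str, ConfoundSet]
    phenotype: pd.DataFrame
    ground_truth: GroundTruth

    @property
    def labels(self) -> np.ndarray:
        return self.phenotype["group"].to_numpy()


def default_grid(
    dims: tuple[int, int, int], voxel_size_mm: float
) -> VolumeGrid:
    """Diagonal affine centered so the mid-sagittal plane sits at x = 0."""
    dims = tuple(int(d) for d in dims)
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size_mm
    affine[:3, 3] = -voxel_size_mm * (np.array(dims) - 1) / 2.0
    return VolumeGrid(dims=dims, affine=affine)


def default_mask(grid: VolumeGrid, fill: float = 0.9) -> np.ndarray:
    """Left-right symmetric ellipsoid mask (a brain-shaped stand-in)."""
    dims = np.array(grid.dims)
    idx = np.indices(grid.dims).astype(float)
    center = (dims - 1) / 2.0
    semi = fill * dims / 2.0
    dist2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return dist2 <= 1.0


def _box_indices(
    geometry: HemisphereGeometry, box: tuple, require_left: bool = True
) -> np.ndarray:
    """Storage indices of in-mask (left-hemisphere) voxels inside a voxel box."""
    (x0, x1), (y0, y1), (z0, z1) = box
    ijk = geometry.voxel_ijk
    sel = (
        (ijk[:, 0] >= x0) & (ijk[:, 0] < x1)
        & (ijk[:, 1] >= y0) & (ijk[:, 1] < y1)
        & (ijk[:, 2] >= z0) & (ijk[:, 2] < z1)
    )
    if require_left:
        sel &= geometry.side == LEFT
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError(f"ROI box {box} contains no in-mask voxels")
    return idx


def _unit_sources(rng: np.random.Generator, n_series: int, t: int, phi: float, white_frac: float) -> np.ndarray:
    """T x n unit-variance series: AR(1) mixed with white noise."""
    e = rng.standard_normal((t + _BURN_IN, n_series))
    ar = lfilter([1.0], [1.0, -phi], e, axis=0)[_BURN_IN:]
    ar *= np.sqrt(1.0 - phi * phi)
    w = rng.standard_normal((t, n_series))
    return np.sqrt(1.0 - white_frac) * ar + np.sqrt(white_frac) * w


def _motion_trace(rng: np.random.Generator, t: int, spike_rate: float) -> np.ndarray:
    """Random-walk 6-parameter motion with occasional spike displacements."""
    inc = np.hstack(
        [
            rng.normal(0.0, 0.02, size=(t, 3)),      # translations, mm
            rng.normal(0.0, 4e-4, size=(t, 3)),      # rotations, rad
        ]
    )
    spikes = rng.random(t) < spike_rate
    spikes[0] = False
    for k in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        inc[k, axis] += rng.uniform(0.7, 1.5) * rng.choice([-1.0, 1.0])
        inc[k, 3 + rng.integers(0, 3)] += rng.uniform(0.002, 0.006)
    return np.cumsum(inc, axis=0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the cohort described by ``spec`` (bit-reproducible)."""
    grid = default_grid(spec.dims, spec.voxel_size_mm)
    mask = default_mask(grid)
    geometry = partition_hemispheres(grid, mask)

    pair_left = np.flatnonzero((geometry.side == LEFT) & (geometry.mirror_index >= 0))
    pair_right = geometry.mirror_index[pair_left]
    n_pairs = pair_left.size
    if n_pairs == 0:
        raise ValueError("mask has no mirror pairs; cannot plant homotopic structure")
    paired = np.zeros(geometry.n_voxels, dtype=bool)
    paired[pair_left] = True
    paired[pair_right] = True

    cfh_roi = _box_indices(geometry, spec.cfh_roi_box)
    ai_roi = _box_indices(geometry, spec.ai_roi_box)
    if np.intersect1d(cfh_roi, ai_roi).size:
        raise ValueError("cfh_roi and ai_roi overlap")
    in_left = np.isin(cfh_roi, pair_left)
    if not in_left.all():
        raise ValueError("cfh_roi must consist of paired left-hemisphere voxels")
    # pair index of each ROI voxel
    pair_pos = {v: k for k, v in enumerate(pair_left)}
    cfh_pairs = np.array([pair_pos[v] for v in cfh_roi])
    ai_pairs = np.array([pair_pos[v] for v in ai_roi if v in pair_pos])

    sm = spec.score_model
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(2 * spec.n_per_group + 1)
    pheno_rng = np.random.default_rng(streams[-1])

    groups = ["HC"] * spec.n_per_group + ["AD"] * spec.n_per_group
    subjects: list[BoldSeries] = []
    confounds: dict[str, ConfoundSet] = {}
    rows = []
    subject_roi_rho: dict[str, float] = {}
    t = spec.n_frames

    # group-level target coupling per pair (the recoverable ground truth)
    rho_groups = {}
    for group in ("HC", "AD"):
        rho = np.full(n_pairs, spec.base_homotopic_rho)
        if group == "AD":
            rho[cfh_pairs] = spec.base_homotopic_rho - spec.delta_rho
            rho[ai_pairs] *= 1.0 - spec.contralateral_loss
        rho_groups[group] = rho

    for s_idx, group in enumerate(groups):
        rng = np.random.default_rng(streams[s_idx])
        sid = f"sub-{s_idx + 1:03d}"
        rho = rho_groups[group].copy()
        jitter = rng.normal(0.0, spec.subject_rho_sd)
        rho[cfh_pairs] = np.clip(rho[cfh_pairs] + jitter, 0.0, 1.0)
        subject_roi_rho[sid] = float(rho[cfh_pairs].mean())

        shared = _unit_sources(rng, n_pairs, t, spec.ar1_phi, spec.white_frac)
        noise = _unit_sources(rng, geometry.n_voxels, t, spec.ar1_phi, spec.white_frac)
        data = noise
        w = np.sqrt(rho)
        u = np.sqrt(1.0 - rho)
        data[:, pair_left] = w * shared + u * noise[:, pair_left]
        data[:, pair_right] = w * shared + u * noise[:, pair_right]

        if group == "AD" and spec.ipsilateral_gain > 0:
            g = _unit_sources(rng, 1, t, spec.ar1_phi, spec.white_frac)[:, 0]
            gain = spec.ipsilateral_gain
            data[:, ai_roi] = (
                np.sqrt(gain) * g[:, None] + np.sqrt(1.0 - gain) * data[:, ai_roi]
            )

        wm = _unit_sources(rng, 1, t, spec.ar1_phi, spec.white_frac)[:, 0]
        csf = _unit_sources(rng, 1, t, spec.ar1_phi, spec.white_frac)[:, 0]
        data = data + spec.confound_weight * (wm + csf)[:, None]

        motion = _motion_trace(rng, t, spec.motion_spike_rate)
        confounds[sid] = ConfoundSet(motion6=motion, wm_signal=wm, csf_signal=csf)
        subjects.append(
            BoldSeries(
                subject_id=sid,
                geometry=geometry,
                data=np.ascontiguousarray(data),
                tr_s=spec.tr_s,
                kept_frames=np.arange(spec.drop_initial, spec.drop_initial + t),
            )
        )

        # phenotype row (atanh capped so degenerate rho = 1 stays finite)
        z_roi = np.arctanh(np.clip(subject_roi_rho[sid], -0.99, 0.99))
        edu_mean = 10.0 if group == "HC" else 7.0
        education = float(np.round(np.clip(pheno_rng.normal(edu_mean, 3.0), 1, 20)))
        age_mu, age_sd = (63.4, 9.2) if group == "HC" else (64.9, 8.5)
        age = float(np.round(np.clip(pheno_rng.normal(age_mu, age_sd), 45, 90), 1))
        sex = "M" if pheno_rng.random() < 0.4 else "F"
        moca_mu = sm.moca_group_means[0] if group == "HC" else sm.moca_group_means[1]
        z_center = float(
            np.arctanh(np.clip(rho_groups[group][cfh_pairs].mean(), -0.99, 0.99))
        )
        moca = (
            moca_mu
            + sm.slope * (z_roi - z_center)
            + sm.edu_beta * (education - edu_mean)
            + pheno_rng.normal(0.0, sm.noise_sd)
        )
        avlt_mu = 8.3 if group == "HC" else 2.4
        avlt_i = (
            avlt_mu
            + sm.slope * sm.avlt_slope_factor * (z_roi - z_center)
            + pheno_rng.normal(0.0, 1.9)
        )
        mmse = pheno_rng.normal(29.0, 1.5) if group == "HC" else pheno_rng.normal(15.5, 6.0)
        avlt_d = pheno_rng.normal(9.0, 3.0) if group == "HC" else max(0.0, pheno_rng.normal(1.0, 1.5))
        avlt_r = pheno_rng.normal(14.0, 1.0) if group == "HC" else pheno_rng.normal(10.5, 4.0)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "sex": sex,
                "education": education,
                "MMSE": round(float(np.clip(mmse, 0, 30)), 2),
                "MoCA": round(float(np.clip(moca, 0, 30)), 2),
                "AVLT_I": round(float(np.clip(avlt_i, 0, 15)), 2),
                "AVLT_D": round(float(np.clip(avlt_d, 0, 15)), 2),
                "AVLT_R": round(float(np.clip(avlt_r, 0, 15)), 2),
            }
        )

    # every voxel whose pair-level coupling differs between groups carries
    # a true CFH group effect (the CFH ROI and the contralateral_loss part
    # of the AI ROI)
    diff_pairs = np.flatnonzero(rho_groups["HC"] != rho_groups["AD"])
    cfh_effect = np.union1d(pair_left[diff_pairs], pair_right[diff_pairs])

    rho_maps = {}
    for group, rho in rho_groups.items():
        m = np.full(geometry.n_voxels, np.nan)
        m[pair_left] = rho
        m[pair_right] = rho
        rho_maps[group] = m

    return Cohort(
        spec=spec,
        geometry=geometry,
        subjects=subjects,
        confounds=confounds,
        phenotype=pd.DataFrame(rows),
        ground_truth=GroundTruth(
            pair_left=pair_left,
            pair_right=pair_right,
            rho_map_by_group=rho_maps,
            cfh_roi=cfh_roi,
            cfh_effect=cfh_effect,
            ai_roi=ai_roi,
            subject_roi_rho=subject_roi_rho,
        ),
    )


def write_phenotype_table(cohort: Cohort, path) -> None:
    """Write the phenotype TSV (one row per subject, documented schema)."""
    cohort.phenotype.to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort as raw-looking NIfTI + TSV files.

    Each BOLD file is prefixed with ``drop_initial`` synthetic unsteady
    volumes (elevated variance) so that loading with the standard initial
    discard recovers exactly the generated frames; motion tables cover the
    full scan length.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = cohort.geometry
    spec = cohort.spec
    save_volume(geom.grid, geom.mask.astype(float), out / "mask.nii.gz")
    prefix_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9999]))
    manifest = []
    for series in cohort.subjects:
        sid = series.subject_id
        t_pre = spec.drop_initial
        pre = prefix_rng.standard_normal((t_pre, geom.n_voxels)) * 3.0
        full = np.vstack([pre, series.data])
        vol4d = np.zeros((*geom.grid.dims, full.shape[0]))
        vol4d[tuple(geom.voxel_ijk.T)] = full.T
        img = nib.Nifti1Image(vol4d, geom.grid.affine)
        img.header.set_zooms((*geom.grid.voxel_size_mm, spec.tr_s))
        bold_path = out / f"{sid}_bold.nii.gz"
        nib.save(img, str(bold_path))

        conf = cohort.confounds[sid]
        pre_motion = np.zeros((t_pre, 6))
        motion_full = np.vstack([pre_motion, conf.motion6])
        table = pd.DataFrame(motion_full, columns=MOTION_COLUMNS)
        table["wm"] = np.concatenate([np.zeros(t_pre), conf.wm_signal])
        table["csf"] = np.concatenate([np.zeros(t_pre), conf.csf_signal])
        motion_path = out / f"{sid}_motion.tsv"
        table.to_csv(motion_path, sep="\t", index=False)
        manifest.append(
            {
                "subject_id": sid,
                "bold": bold_path.name,
                "motion": motion_path.name,
                "group": cohort.phenotype.set_index("subject_id").loc[sid, "group"],
            }
        )
    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_phenotype_table(cohort, out / "phenotype.tsv")

    gt = cohort.ground_truth
    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    for group, rho_map in gt.rho_map_by_group.items():
        vals = np.where(np.isfinite(rho_map), rho_map, 0.0)
        save_volume(geom.grid, geom.scatter(vals), gt_dir / f"rho_{group}.nii.gz")
    with open(gt_dir / "rois.json", "w") as fh:
        json.dump(
            {
                "cfh_roi": gt.cfh_roi.tolist(),
                "cfh_effect": gt.cfh_effect.tolist(),
                "ai_roi": gt.ai_roi.tolist(),
                "subject_roi_rho": gt.subject_roi_rho,
            },
            fh,
            indent=1,
        )
    with open(out / "spec.json", "w") as fh:
        d = dataclasses.asdict(spec)
        json.dump(d, fh, indent=1)
    return out


def load_cohort(cohort_dir) -> Cohort:
    """Reload a written cohort from its NIfTI/TSV files."""
    from .core_io import load_bold_series

    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "spec.json") as fh:
        d = json.load(fh)
    d["score_model"] = ScoreModel(**d["score_model"])
    d["dims"] = tuple(d["dims"])
    d["cfh_roi_box"] = tuple(tuple(b) for b in d["cfh_roi_box"])
    d["ai_roi_box"] = tuple(tuple(b) for b in d["ai_roi_box"])
    spec = CohortSpec(**d)

    mask_img = nib.load(str(cohort_dir / "mask.nii.gz"))
    grid = VolumeGrid(dims=mask_img.shape[:3], affine=mask_img.affine)
    geometry = partition_hemispheres(grid, np.asarray(mask_img.dataobj) > 0)

    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t")
    subjects = []
    confounds = {}
    for _, row in manifest.iterrows():
        series = load_bold_series(
            cohort_dir / row["bold"],
            cohort_dir / "mask.nii.gz",
            drop_initial=spec.drop_initial,
            subject_id=row["subject_id"],
            geometry=geometry,
        )
        subjects.append(series)
        table = pd.read_csv(cohort_dir / row["motion"], sep="\t")
        table = table.iloc[spec.drop_initial :].reset_index(drop=True)
        confounds[row["subject_id"]] = ConfoundSet(
            motion6=table[MOTION_COLUMNS].to_numpy(),
            wm_signal=table["wm"].to_numpy(),
            csf_signal=table["csf"].to_numpy(),
        )
    phenotype = pd.read_csv(cohort_dir / "phenotype.tsv", sep="\t")

    with open(cohort_dir / "ground_truth" / "rois.json") as fh:
        rois = json.load(fh)
    rho_maps = {}
    for group in ("HC", "AD"):
        img = nib.load(str(cohort_dir / "ground_truth" / f"rho_{group}.nii.gz"))
        rho_maps[group] = geometry.gather(np.asarray(img.dataobj, dtype=float))
    pair_left = np.flatnonzero((geometry.side == LEFT) & (geometry.mirror_index >= 0))
    return Cohort(
        spec=spec,
        geometry=geometry,
        subjects=subjects,
        confounds=confounds,
        phenotype=phenotype,
        ground_truth=GroundTruth(
            pair_left=pair_left,
            pair_right=geometry.mirror_index[pair_left],
            rho_map_by_group=rho_maps,
            cfh_roi=np.array(rois["cfh_roi"], dtype=int),
            cfh_effect=np.array(rois["cfh_effect"], dtype=int),
            ai_roi=np.array(rois["ai_roi"], dtype=int),
            subject_roi_rho=rois["subject_roi_rho"],
        ),
    )
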