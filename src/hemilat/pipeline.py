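"""End-to-end orchestration: simulate/load -> denoise -> AI/CFH ->
group inference -> imaging-cognition correlation -> classification.

A :class:`PipelineConfig` carries every stage parameter with defaults
matching the reference analysis (drop 10 initial volumes, 0.01-0.1 Hz
band, FD 0.5 mm scrubbing, AI thresholds r > .25 / p < .001, 8 mm FWHM
smoothing, voxel p < 1e-4 with cluster alpha .05, 3.5 mm peak spheres,
5000 permutations, education covariate).  One master seed deterministically
derives per-stage seeds (simulation, AI/CFH cluster permutations, label
permutation), so two runs with equal config produce byte-identical tables
and reports; the run log alone carries timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import FeatureMatrix, label_permutation_test, svm_loocv_classify
from .cooperation_cfh import compute_cfh_map, define_homotopic_seeds
from .core_io import BoldSeries, MetricMap, save_metric_map
from .denoise import bandpass_filter, regress_confounds, scrub_high_motion
from .group_inference import (
    ClusterInferenceResult,
    GroupDesign,
    cluster_fwe_permutation,
    extract_cluster_mean,
    extract_sphere_mean,
    smooth_map,
    voxelwise_two_sample_t,
)
from .specialization_ai import compute_ai_map
from .synthetic_cohort import Cohort, CohortSpec, ScoreModel, generate_cohort, load_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "denoise_subject"]


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths and the master seed."""

    out_dir: str = "results/run"
    cohort_dir: str | None = None          # load an existing cohort ...
    simulate: dict | None = None           # ... or generate one (CohortSpec kwargs)
    drop_initial: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.5
    r_threshold: float = 0.25
    p_threshold: float = 0.001
    fwhm_mm: float = 8.0
    voxel_p: float = 1e-4
    cluster_alpha: float = 0.05
    n_perm: int = 5000
    connectivity: int = 26
    sphere_radius_mm: float = 3.5
    roi_form: str = "cluster"              # {"cluster", "sphere"} feature ROIs
    covariate: str = "education"
    scores: tuple = ("MoCA", "AVLT_I")
    correlation_group: str = "AD"
    svm_c: float = 1.0
    classify_n_perm: int = 5000
    save_maps: bool = True
    run_denoise: bool = True
    seed: int = 42

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scores"] = list(d["scores"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scores" in d:
            d["scores"] = tuple(d["scores"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        order = ["simulate", "ai_perm", "cfh_perm", "svm_perm"]
        state = np.random.SeedSequence(self.seed).generate_state(len(order))
        return int(state[order.index(stage)] % (2**31))


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    ai_maps: list[MetricMap]
    cfh_maps: list[MetricMap]
    ai_inference: ClusterInferenceResult
    cfh_inference: ClusterInferenceResult
    correlations: pd.DataFrame
    features: FeatureMatrix | None
    report: dict
    out_dir: Path


def denoise_subject(series, confounds, config: PipelineConfig) -> BoldSeries:
    """regress -> bandpass -> scrub, the fixed temporal-denoising order."""
    s = regress_confounds(series, confounds)
    s = bandpass_filter(s, config.low_hz, config.high_hz)
    return scrub_high_motion(s, confounds.motion6, config.fd_threshold_mm)


def compute_subject_maps(
    cohort: Cohort, config: PipelineConfig, denoised: list[BoldSeries] | None = None
) -> tuple[list[MetricMap], list[MetricMap]]:
    """Smoothed AI and CFH maps for every subject (seeds pooled across all)."""
    series = denoised if denoised is not None else cohort.subjects
    ai_maps = [
        smooth_map(
            compute_ai_map(
                s, r_threshold=config.r_threshold, p_threshold=config.p_threshold
            ),
            config.fwhm_mm,
        )
        for s in series
    ]
    seeds = define_homotopic_seeds(series)
    cfh_maps = [
        smooth_map(compute_cfh_map(s, seeds).metric, config.fwhm_mm) for s in series
    ]
    return ai_maps, cfh_maps


def _region_features(
    metric_name: str,
    maps: list[MetricMap],
    inference: ClusterInferenceResult,
    config: PipelineConfig,
) -> tuple[np.ndarray, list[str]]:
    """Per-subject regional summaries of each significant cluster."""
    cols = []
    names = []
    table = inference.table
    members = inference.significant_members()
    for k, (_, row) in enumerate(table.iterrows()):
        if config.roi_form == "sphere":
            center = np.array([row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"]])
            vals = [
                extract_sphere_mean(m, center, config.sphere_radius_mm)[0]
                for m in maps
            ]
        else:
            vals = [extract_cluster_mean(m, members[k]) for m in maps]
        cols.append(vals)
        names.append(f"{metric_name}_{row['label']}")
    if not cols:
        return np.empty((len(maps), 0)), []
    return np.array(cols).T, names


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write tables/maps/report under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root_logger = logging.getLogger("hemilat")
    root_logger.addHandler(log_handler)
    root_logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        logger.info("config hash %s; hemilat %s", config.config_hash, __version__)
        stage = "cohort"
        if config.cohort_dir:
            cohort = load_cohort(config.cohort_dir)
        elif config.simulate is not None:
            sim = dict(config.simulate)
            if "score_model" in sim and isinstance(sim["score_model"], dict):
                sim["score_model"] = ScoreModel(**sim["score_model"])
            sim.setdefault("seed", config.stage_seed("simulate"))
            cohort = generate_cohort(CohortSpec(**sim))
        else:
            raise ValueError("config must set cohort_dir or simulate")
        logger.info(
            "cohort: %d subjects, %d in-mask voxels",
            len(cohort.subjects),
            cohort.geometry.n_voxels,
        )

        stage = "denoise"
        if config.run_denoise:
            denoised = [
                denoise_subject(s, cohort.confounds[s.subject_id], config)
                for s in cohort.subjects
            ]
        else:
            denoised = cohort.subjects

        stage = "subject maps"
        ai_maps, cfh_maps = compute_subject_maps(cohort, config, denoised)
        if config.save_maps:
            maps_dir = out / "maps"
            maps_dir.mkdir(exist_ok=True)
            for s, ai, cfh in zip(denoised, ai_maps, cfh_maps):
                save_metric_map(ai, maps_dir / f"{s.subject_id}_ai.nii.gz")
                save_metric_map(cfh, maps_dir / f"{s.subject_id}_cfh.nii.gz")

        stage = "group inference"
        design = GroupDesign(
            subject_ids=list(cohort.phenotype["subject_id"]),
            labels=cohort.labels,
            covariates=cohort.phenotype.set_index("subject_id"),
        )
        inferences = {}
        for metric_name, maps, stage_name in (
            ("ai", ai_maps, "ai_perm"),
            ("cfh", cfh_maps, "cfh_perm"),
        ):
            inferences[metric_name] = cluster_fwe_permutation(
                maps,
                design,
                voxel_p=config.voxel_p,
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                seed=config.stage_seed(stage_name),
                connectivity=config.connectivity,
            )
        group_dir = out / "group"
        group_dir.mkdir(exist_ok=True)
        for metric_name, inf in inferences.items():
            _write_table(
                inf.clusters, group_dir / f"{metric_name}_clusters.tsv", config
            )
            logger.info(
                "%s: %d suprathreshold clusters, %d significant",
                metric_name,
                len(inf.clusters),
                int(inf.clusters["significant"].sum()),
            )

        stage = "correlation"
        corr_rows = []
        pheno = cohort.phenotype
        sel = pheno["group"] == config.correlation_group
        cov = pheno.loc[sel, config.covariate].to_numpy(dtype=float)
        for metric_name, maps in (("ai", ai_maps), ("cfh", cfh_maps)):
            values, names = _region_features(
                metric_name, maps, inferences[metric_name], config
            )
            for j, name in enumerate(names):
                x = values[sel.to_numpy(), j]
                for score in config.scores:
                    y = pheno.loc[sel, score].to_numpy(dtype=float)
                    from .group_inference import partial_correlation

                    r, p = partial_correlation(x, y, cov)
                    corr_rows.append(
                        {
                            "region": name,
                            "score": score,
                            "covariate": config.covariate,
                            "group": config.correlation_group,
                            "n": int(sel.sum()),
                            "r": round(r, 6),
                            "p": round(p, 6),
                        }
                    )
        correlations = pd.DataFrame(
            corr_rows, columns=["region", "score", "covariate", "group", "n", "r", "p"]
        )
        _write_table(correlations, out / "correlations.tsv", config)

        stage = "classification"
        feat_blocks = []
        feat_names = []
        for metric_name, maps in (("ai", ai_maps), ("cfh", cfh_maps)):
            values, names = _region_features(
                metric_name, maps, inferences[metric_name], config
            )
            feat_blocks.append(values)
            feat_names.extend(names)
        x = np.hstack(feat_blocks)
        if x.shape[1] == 0:
            logger.info("no significant clusters; classification skipped")
            features = None
            report = {
                "skipped": "no significant clusters provided features",
                "config_hash": config.config_hash,
            }
        else:
            features = FeatureMatrix(
                values=x,
                labels=cohort.labels,
                feature_names=feat_names,
                subject_ids=list(pheno["subject_id"]),
            )
            clf = svm_loocv_classify(features, c_param=config.svm_c)
            p_perm, _ = label_permutation_test(
                features,
                n_perm=config.classify_n_perm,
                seed=config.stage_seed("svm_perm"),
                c_param=config.svm_c,
                observed_accuracy=clf.accuracy,
            )
            clf.permutation_p = p_perm
            clf.n_perm = config.classify_n_perm
            report = clf.to_dict()
            report["feature_names"] = feat_names
            report["config_hash"] = config.config_hash
        with open(out / "classification.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)

        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "hemilat_version": __version__,
            "stage_seeds": {
                k: config.stage_seed(k)
                for k in ("simulate", "ai_perm", "cfh_perm", "svm_perm")
            },
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        logger.error("pipeline failed during stage '%s': %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        root_logger.removeHandler(log_handler)
        log_handler.close()

    return PipelineResult(
        config=config,
        cohort=cohort,
        ai_maps=ai_maps,
        cfh_maps=cfh_maps,
        ai_inference=inferences["ai"],
        cfh_inference=inferences["cfh"],
        correlations=correlations,
        features=features,
        report=report,
        out_dir=out,
    )


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    """TSV with a provenance comment line naming the producing config."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
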