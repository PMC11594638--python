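"""End-to-end orchestration: phantom cohort -> vesselness -> segmentation ->
quantification -> statistics, with a reproducibility manifest.

A run is driven by a :class:`RunConfig` that holds either a phantom
specification (synthetic cohort mode) or explicit per-subject input paths
(real-data mode), plus the filter, segmentation and statistics settings and
one seed. Every output file is checksummed into the manifest, so two runs
with the same config and seed can be compared bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import ImageVolume, RegionAtlas
from .phantom import (
    EffectConfig,
    PhantomSpec,
    REGIONS,
    generate_atlas,
    generate_lesion_masks,
    generate_pvs_tubes,
    render_sequences,
    generate_cohort_table,
)
from .vesselness import FrangiParams, multiscale_max
from .segment import SegmentationParams, calibrate_threshold, segment_pvs
from .quantify import compute_subject_metrics
from .stats import (
    DEFAULT_COVARIATES,
    fit_models,
    quartile_tests,
    select_transformation,
)

__all__ = ["RunConfig", "run_pipeline", "process_subject",
           "build_phantom_cohort", "reference_calibration"]

log = logging.getLogger(__name__)

DEFAULT_REGRESSORS = [
    "age", "female", "hypertension", "dyslipidemia", "diabetes", "bmi",
    "smoking", "alcohol", "psqi", "ess", "lacune_count", "microbleed_count",
    "wmh_ratio",
]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "pvsmap-run"
    seed: int = 0
    n_subjects: int = 20
    phantom: dict | None = field(default_factory=dict)  # PhantomSpec overrides
    inputs: list[dict] | None = None  # real-data mode: per-subject paths
    covariates_csv: str | None = None
    frangi: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    calibrate: bool = True
    threshold_grid: list[float] = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5])
    regressors: list[str] = field(default_factory=lambda: list(DEFAULT_REGRESSORS))
    stats_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    ladder: bool = True
    save_volumes: bool = False

    def __post_init__(self) -> None:
        if (self.phantom is None) == (self.inputs is None):
            raise ValueError("exactly one of phantom spec or real-input paths required")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _array_digest(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes() + str(a.shape).encode()).hexdigest()


def process_subject(
    t2: ImageVolume,
    flair: ImageVolume,
    atlas: RegionAtlas,
    wmh_mask: np.ndarray,
    lacune_mask: np.ndarray,
    stroke_mask: np.ndarray | None,
    frangi: FrangiParams,
    seg_params: SegmentationParams,
):
    """Vesselness + segmentation + metrics for one subject.

    Returns (PVSMask, SubjectMetrics, dict of vesselness maps).
    """
    bright = FrangiParams(scales_mm=frangi.scales_mm, alpha=frangi.alpha,
                          beta=frangi.beta, c=frangi.c, polarity="bright")
    dark = FrangiParams(scales_mm=frangi.scales_mm, alpha=frangi.alpha,
                        beta=frangi.beta, c=frangi.c, polarity="dark")
    v_t2 = multiscale_max(t2, bright)
    v_flair = multiscale_max(flair, dark)
    mask = segment_pvs(v_t2, v_flair, atlas, wmh_mask, lacune_mask, stroke_mask, seg_params)
    metrics = compute_subject_metrics(mask, atlas, wmh_mask)
    return mask, metrics, {"t2": v_t2, "flair_dark": v_flair}


def build_phantom_cohort(
    n_subjects: int = 12,
    seed: int = 7,
    noise_sigma: float = 0.0,
    tube_radius_mm: tuple[float, float] = (1.0, 1.3),
    caliber_spread_mm: float = 0.3,
    contrast_jitter: float = 20.0,
    densities: dict | None = None,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
):
    """Phantom cohort with inter-subject heterogeneity, for threshold work.

    Subjects differ in PVS caliber (each subject's radius range is the base
    range shifted by up to ``caliber_spread_mm``) and in PVS contrast
    (uniform jitter of the T2/FLAIR PVS levels). This heterogeneity mirrors
    a real cohort and is what gives the visual-rating calibration a
    well-defined optimum: subjects with fainter, thinner PVS lose their
    segmentations first as the threshold rises, breaking the rank order.

    Returns (subjects, truths) where each subject dict holds the vesselness
    maps, atlas and lesion masks expected by :func:`calibrate_threshold`.
    """
    from .phantom import DEFAULT_CONTRAST

    densities = densities or {"wm": 14.0, "bg": 4.0, "bs": 3.0}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    subjects, truths = [], []
    for i in range(n_subjects):
        u = rng.uniform()
        cj = rng.uniform(-contrast_jitter, contrast_jitter)
        contrast = {s: dict(v) for s, v in DEFAULT_CONTRAST.items()}
        contrast["t2"]["pvs"] += cj
        contrast["flair"]["pvs"] -= cj / 2
        spec = PhantomSpec(
            grid_shape=grid_shape,
            noise_sigma=noise_sigma,
            tube_radius_mm_range=(
                tube_radius_mm[0] + caliber_spread_mm * u,
                tube_radius_mm[1] + caliber_spread_mm * u,
            ),
            pvs_density_per_region=dict(densities),
            contrast_levels=contrast,
            seed=int(seed) * 1000 + i,
        )
        atlas = generate_atlas(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            truth = generate_pvs_tubes(spec, atlas)
        wmh, lacunes = generate_lesion_masks(spec, atlas)
        t2, flair = render_sequences(spec, atlas, truth, wmh, lacunes)
        subjects.append(dict(
            v_t2=multiscale_max(t2, FrangiParams()),
            v_flair_dark=multiscale_max(flair, FrangiParams(polarity="dark")),
            atlas=atlas, wmh_mask=wmh, lacune_mask=lacunes,
        ))
        truths.append(truth)
    return subjects, truths


REFERENCE_CALIBRATION_SEED = 7


def reference_calibration(grid=None) -> float:
    """Recompute the package's default vesselness threshold.

    Runs the visual-rating calibration on the fixed reference phantom
    cohort (5-grade scores assigned by quantile of the true per-region
    burden, for white matter and basal ganglia separately). The result is
    the cohort-wide operating point baked into
    :class:`~pvsmap.segment.SegmentationParams` defaults; rerun after
    changing filter scales, constants or acquisition geometry.
    """
    from .segment import calibrate_threshold

    subjects, truths = build_phantom_cohort(seed=REFERENCE_CALIBRATION_SEED)
    scores = {}
    for r in ("wm", "bg"):
        tf = np.array([t.per_region_true_fraction[r] for t in truths])
        scores[r] = np.searchsorted(np.quantile(tf, [0.2, 0.4, 0.6, 0.8]), tf)
    if grid is None:
        grid = np.round(np.arange(0.05, 0.55, 0.05), 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return calibrate_threshold(subjects, scores, np.asarray(grid))


def _phantom_subject(base: PhantomSpec, table_row: pd.Series, subject_seed: int):
    """Per-subject phantom: tube densities scaled to the subject's latent
    burden so imaged burden tracks the cohort covariate model."""
    eff_means = {"wm": 1.1, "bg": 4.0, "bs": 0.6}
    dens = {}
    for r in REGIONS:
        target = float(table_row[f"frac_{r}"])
        dens[r] = base.pvs_density_per_region.get(r, 0.0) * target / eff_means[r]
    spec = PhantomSpec(**{**base.to_dict(),
                          "pvs_density_per_region": dens,
                          "seed": subject_seed})
    atlas = generate_atlas(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        truth = generate_pvs_tubes(spec, atlas)
    wmh, lacunes = generate_lesion_masks(spec, atlas)
    t2, flair = render_sequences(spec, atlas, truth, wmh, lacunes)
    return spec, atlas, truth, wmh, lacunes, t2, flair


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables, masks and the manifest.

    Returns the manifest dict. Identical config + seed give identical
    per-stage content digests and output files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frangi = FrangiParams(**config.frangi)
    seg_params = SegmentationParams(**config.segmentation)
    manifest: dict = {
        "pvsmap_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "frangi": asdict(frangi),
        "segmentation": asdict(seg_params),
        "stages": {},
        "files": {},
    }

    if config.inputs is not None:
        subjects = _load_real_subjects(config)
        table = pd.read_csv(config.covariates_csv) if config.covariates_csv else None
    else:
        base = PhantomSpec(**{**config.phantom, "seed": config.seed})
        table = generate_cohort_table(config.n_subjects, EffectConfig(), seed=config.seed)
        subjects = []
        for i in range(config.n_subjects):
            spec, atlas, truth, wmh, lacunes, t2, flair = _phantom_subject(
                base, table.iloc[i], subject_seed=int(config.seed) * 100003 + i + 1
            )
            subjects.append(dict(
                subject_id=table.iloc[i]["subject_id"], spec=spec, atlas=atlas,
                truth=truth, wmh_mask=wmh, lacune_mask=lacunes,
                stroke_mask=None, t2=t2, flair=flair,
            ))
        manifest["stages"]["phantom"] = {
            "n_subjects": len(subjects),
            "truth_digest": [_array_digest(s["truth"].pvs_mask) for s in subjects],
        }

    # vesselness
    for s in subjects:
        bright = FrangiParams(**{**asdict(frangi), "polarity": "bright"})
        dark = FrangiParams(**{**asdict(frangi), "polarity": "dark"})
        s["v_t2"] = multiscale_max(s["t2"], bright)
        s["v_flair_dark"] = multiscale_max(s["flair"], dark)
    manifest["stages"]["vesselness"] = {
        "digest": [_array_digest(s["v_t2"].values) for s in subjects]
    }

    # threshold calibration against visual rating (phantom mode only)
    if config.calibrate and table is not None and "visual_wm" in table:
        scores = {
            "wm": table["visual_wm"].to_numpy()[: len(subjects)],
            "bg": table["visual_bg"].to_numpy()[: len(subjects)],
        }
        if all(len(np.unique(s)) >= 2 for s in scores.values()):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = calibrate_threshold(subjects, scores, np.asarray(config.threshold_grid),
                                        seg_params)
            seg_params = SegmentationParams(
                threshold_nawm=t, threshold_wmh=t,
                min_cluster_voxels=seg_params.min_cluster_voxels,
                connectivity=seg_params.connectivity,
                combine_rule=seg_params.combine_rule,
            )
            manifest["stages"]["calibration"] = {"threshold": t}
        else:
            warnings.warn("visual scores span a single grade; calibration skipped")
    elif config.calibrate:
        warnings.warn("no visual scores available; calibration skipped")

    # segmentation + quantification
    rows = []
    for s in subjects:
        mask = segment_pvs(s["v_t2"], s["v_flair_dark"], s["atlas"], s["wmh_mask"],
                           s["lacune_mask"], s.get("stroke_mask"), seg_params)
        s["mask"] = mask
        m = compute_subject_metrics(mask, s["atlas"], s["wmh_mask"])
        row = {"subject_id": s["subject_id"], **{f"seg_{k}": v for k, v in m.as_dict().items()}}
        rows.append(row)
        if config.save_volumes:
            ImageVolume(mask.mask, s["atlas"].voxel_size_mm).save(
                out / f"{s['subject_id']}_pvs.nii.gz")
    metrics_df = pd.DataFrame(rows)
    manifest["stages"]["segment"] = {
        "threshold_nawm": seg_params.threshold_nawm,
        "mask_digest": [_array_digest(s["mask"].mask) for s in subjects],
    }

    merged = metrics_df if table is None else table.merge(metrics_df, on="subject_id")
    merged_path = out / "cohort_metrics.csv"
    merged.to_csv(merged_path, index=False)

    # statistics
    stats_out: dict = {}
    outcome_cols = {r: f"seg_frac_{r}" for r in REGIONS}
    vec = {r: merged[c].to_numpy(dtype=float) for r, c in outcome_cols.items()}
    degenerate = any(np.ptp(v) == 0 for v in vec.values())
    if degenerate:
        warnings.warn("constant fractional volumes; statistics stage skipped")
        manifest["stages"]["stats"] = {"skipped": True}
    else:
        if config.ladder and all((v > 0).all() for v in vec.values()):
            ladder = select_transformation(vec)
        else:
            ladder = None
        chosen = ladder.chosen if ladder else "identity"
        stats_out["transformation"] = chosen
        if ladder:
            stats_out["ladder_scores"] = ladder.scores
        model_rows = []
        outcomes = dict(outcome_cols)
        ratio = merged["seg_wm_bg_ratio"].to_numpy(dtype=float)
        if np.all(np.isfinite(ratio)) and np.all(ratio > 0) and np.ptp(ratio) > 0:
            outcomes["wm_bg_ratio"] = "seg_wm_bg_ratio"
        else:
            warnings.warn("WM/BG ratio undefined or constant; ratio models skipped")
        regs = [r for r in config.regressors if r in merged.columns]
        for name, col in outcomes.items():
            for adjust in (False, True):
                res = fit_models(merged, col, regs, adjust=adjust,
                                 covariates=tuple(config.stats_covariates),
                                 transform=chosen)
                for m in res:
                    d = m.as_dict()
                    d["outcome"] = name
                    model_rows.append(d)
        models_df = pd.DataFrame(model_rows)
        models_path = out / "regression_models.csv"
        models_df.to_csv(models_path, index=False)
        qt = []
        for name, col in outcome_cols.items():
            if len(merged) >= 8:
                qt.append(quartile_tests(
                    merged, col,
                    continuous_vars=[c for c in ("age", "bmi") if c in merged],
                    ordinal_vars=[c for c in ("psqi", "ess", "lacune_count") if c in merged],
                ))
        if qt:
            pd.concat(qt).to_csv(out / "quartile_tests.csv", index=False)
        manifest["stages"]["stats"] = {"transformation": chosen, "n_models": len(model_rows)}

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_real_subjects(config: RunConfig) -> list[dict]:
    subjects = []
    for entry in config.inputs or []:
        atlas = RegionAtlas.load(entry["atlas"], entry.get("icv"))
        subjects.append(dict(
            subject_id=entry.get("subject_id", Path(entry["t2"]).stem),
            atlas=atlas,
            t2=ImageVolume.load(entry["t2"]),
            flair=ImageVolume.load(entry["flair"]),
            wmh_mask=ImageVolume.load(entry["wmh"]).data.astype(bool),
            lacune_mask=ImageVolume.load(entry["lacunes"]).data.astype(bool),
            stroke_mask=(ImageVolume.load(entry["stroke"]).data.astype(bool)
                         if entry.get("stroke") else None),
        ))
    return subjects
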