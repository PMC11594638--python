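"""Synthetic T2/FLAIR phantoms with known perivascular-space ground truth.

The generator builds, on a common voxel grid: a region atlas (white matter
shell, basal-ganglia ellipsoids, brainstem cylinder inside an intracranial
ellipsoid), capsule-shaped bright tubules standing in for enlarged PVS,
white-matter-hyperintensity blobs, lacunar cavities, and piecewise-constant
T2/FLAIR renders with additive noise. It also generates cohort covariate
tables whose latent PVS burdens follow a configurable log-scale linear
model, so the downstream regression layer has known effects to recover.

Everything is deterministic given the spec seed: each stage draws from its
own `numpy` SeedSequence stream spawned from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image import ImageVolume, RegionAtlas, WM, BG, BS

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "EffectConfig",
    "generate_atlas",
    "generate_pvs_tubes",
    "generate_lesion_masks",
    "render_sequences",
    "generate_cohort_table",
]

REGIONS = ("wm", "bg", "bs")

# Default tissue-class mean intensities per sequence. PVS are bright on T2
# and dark on FLAIR; WMHs are bright on FLAIR; lacunes follow CSF (bright
# T2, suppressed FLAIR).
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "t2": {"background": 0.0, "tissue": 100.0, "wmh": 115.0, "pvs": 180.0, "lacune": 190.0},
    "flair": {"background": 0.0, "tissue": 100.0, "wmh": 160.0, "pvs": 60.0, "lacune": 40.0},
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head phantom.

    ``pvs_density_per_region`` is the expected tube count per region (the
    realized count is Poisson); tube radii default to the sub-voxel-to-3-mm
    range conventional for enlarged PVS and are fully configurable.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.9
    pvs_density_per_region: dict[str, float] = field(
        default_factory=lambda: {"wm": 25.0, "bg": 8.0, "bs": 2.0}
    )
    tube_radius_mm_range: tuple[float, float] = (0.45, 1.0)
    tube_length_mm_range: tuple[float, float] = (3.0, 9.0)
    wmh_blob_count: int = 3
    wmh_radius_mm_range: tuple[float, float] = (1.8, 4.5)
    lacune_count: int = 1
    lacune_radius_mm_range: tuple[float, float] = (1.5, 3.0)
    contrast_levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_CONTRAST.items()}
    )
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        for name, rng_ in (
            ("tube_radius_mm_range", self.tube_radius_mm_range),
            ("tube_length_mm_range", self.tube_length_mm_range),
            ("wmh_radius_mm_range", self.wmh_radius_mm_range),
            ("lacune_radius_mm_range", self.lacune_radius_mm_range),
        ):
            lo, hi = rng_
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max, got {rng_}")
        if any(v < 0 for v in self.pvs_density_per_region.values()):
            raise ValueError("pvs densities must be >= 0")
        if self.wmh_blob_count < 0 or self.lacune_count < 0:
            raise ValueError("lesion counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.voxel_size_mm,) * 3

    # deterministic per-stage random streams
    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        for k in ("tube_radius_mm_range", "tube_length_mm_range",
                  "wmh_radius_mm_range", "lacune_radius_mm_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for k in ("grid_shape", "tube_radius_mm_range", "tube_length_mm_range",
                  "wmh_radius_mm_range", "lacune_radius_mm_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TubeRecord:
    p0_mm: tuple[float, float, float]
    p1_mm: tuple[float, float, float]
    radius_mm: float
    region: str


@dataclass
class GroundTruth:
    """True PVS mask plus exact per-region fractional volumes (%)."""

    pvs_mask: np.ndarray
    per_region_true_fraction: dict[str, float]
    tube_records: list[TubeRecord]

    def recompute_fractions(self, atlas: RegionAtlas) -> dict[str, float]:
        out = {}
        for region in REGIONS:
            rmask = atlas.region_mask(region)
            n = int(rmask.sum())
            out[region] = 100.0 * float((self.pvs_mask & rmask).sum()) / n if n else float("nan")
        return out


# ---------------------------------------------------------------------------
# atlas construction


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_atlas(spec: PhantomSpec) -> RegionAtlas:
    """Build the synthetic region atlas.

    Geometry: intracranial volume (ICV) as a large ellipsoid; white matter
    as a thick ellipsoidal shell; basal ganglia as two central ellipsoids;
    brainstem as an inferior cylinder. Regions are disjoint by construction
    and all lie inside the ICV. Raises if the grid is too small for all
    three regions to be non-empty.
    """
    nx, ny, nz = spec.grid_shape
    shape = spec.grid_shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    n = min(shape)

    icv = _ellipsoid(shape, (cx, cy, cz), (0.45 * nx, 0.45 * ny, 0.45 * nz))

    # brainstem: inferior cylinder along z
    zg = np.arange(nz).reshape(1, 1, -1)
    xg = np.arange(nx).reshape(-1, 1, 1)
    yg = np.arange(ny).reshape(1, -1, 1)
    bs_r = 0.08 * n
    bs = (((xg - cx) ** 2 + (yg - cy) ** 2) <= bs_r**2) & (zg >= 0.08 * nz) & (zg <= 0.30 * nz)
    bs &= icv

    # basal ganglia: two ellipsoids flanking the midline, mid-height
    bg = np.zeros(shape, dtype=bool)
    for sx in (-1, 1):
        bg |= _ellipsoid(
            shape,
            (cx + sx * 0.14 * nx, cy, cz),
            (0.10 * nx, 0.13 * ny, 0.11 * nz),
        )
    bg &= icv & ~bs

    # white matter: thick shell, slightly superior, minus BG/BS
    outer = _ellipsoid(shape, (cx, cy, cz + 0.06 * nz), (0.38 * nx, 0.38 * ny, 0.36 * nz))
    inner = _ellipsoid(shape, (cx, cy, cz + 0.06 * nz), (0.20 * nx, 0.20 * ny, 0.18 * nz))
    wm = outer & ~inner & icv & ~bg & ~bs

    labels = np.zeros(shape, dtype=np.int16)
    labels[wm] = WM
    labels[bg] = BG
    labels[bs] = BS
    for name, mask in (("WM", wm), ("BG", bg), ("BS", bs)):
        if not mask.any():
            raise ValueError(
                f"grid {shape} too small to place region {name}; use at least ~32 voxels per axis"
            )
    return RegionAtlas(labels, icv, spec.spacing)


# ---------------------------------------------------------------------------
# PVS tubes


def _capsule_voxels(shape, spacing, p0, p1, radius_mm):
    """Indices of voxels whose centers lie within `radius_mm` of segment p0-p1.

    Voxel centers sit at index * spacing (mm). Returns a boolean mask over
    the bounding box plus its offset, to avoid full-grid work per tube.
    """
    h = np.asarray(spacing, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.minimum(p0, p1) - radius_mm
    hi = np.maximum(p0, p1) + radius_mm
    i0 = np.maximum(np.floor(lo / h).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / h).astype(int) + 1, np.asarray(shape))
    if np.any(i0 >= i1):
        return None, None
    grids = np.meshgrid(
        *[np.arange(a, b) * s for a, b, s in zip(i0, i1, h)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        dist2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    return dist2 <= radius_mm**2, i0


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def generate_pvs_tubes(
    spec: PhantomSpec, atlas: RegionAtlas, max_attempts_per_tube: int = 200
) -> GroundTruth:
    """Plant capsule-shaped tubes wholly inside their assigned regions.

    The per-region tube count is Poisson with mean
    ``pvs_density_per_region[region]``. Each capsule (cylinder with
    hemispherical caps) gets a uniformly random orientation, a radius and
    centerline length drawn uniformly from the spec ranges, and is
    rasterized by voxel-center inclusion — which makes the true fractional
    volume an exact voxel count, the oracle for the quantification stage.
    Tubes that cannot be placed inside their region after
    ``max_attempts_per_tube`` tries are skipped with a warning.
    """
    rng = spec.rng(1)
    if spec.tube_radius_mm_range[0] < spec.voxel_size_mm / 2:
        warnings.warn(
            "tube radius below half a voxel: thin tubes may vanish under rasterization",
            stacklevel=2,
        )
    pvs = np.zeros(atlas.shape, dtype=bool)
    records: list[TubeRecord] = []
    h = np.asarray(atlas.voxel_size_mm)
    for region in REGIONS:
        density = float(spec.pvs_density_per_region.get(region, 0.0))
        count = int(rng.poisson(density)) if density > 0 else 0
        rmask = atlas.region_mask(region)
        ridx = np.argwhere(rmask)
        if count and len(ridx) == 0:
            warnings.warn(f"region {region} empty; skipping its tubes", stacklevel=2)
            continue
        placed = 0
        for _ in range(count):
            ok = False
            for _attempt in range(max_attempts_per_tube):
                radius = rng.uniform(*spec.tube_radius_mm_range)
                length = rng.uniform(*spec.tube_length_mm_range)
                center = ridx[rng.integers(len(ridx))] * h
                d = _random_unit_vector(rng)
                p0 = center - d * length / 2
                p1 = center + d * length / 2
                box, i0 = _capsule_voxels(atlas.shape, h, p0, p1, radius)
                if box is None or not box.any():
                    continue
                sl = tuple(slice(a, a + s) for a, s in zip(i0, box.shape))
                if np.all(rmask[sl][box]):
                    pvs[sl][box] = True
                    records.append(
                        TubeRecord(tuple(p0), tuple(p1), float(radius), region)
                    )
                    ok = True
                    break
            placed += ok
        if placed < count:
            warnings.warn(
                f"placed {placed}/{count} tubes in {region}: region too small for some draws",
                stacklevel=2,
            )
    fractions = {}
    for region in REGIONS:
        rmask = atlas.region_mask(region)
        n = int(rmask.sum())
        fractions[region] = 100.0 * float((pvs & rmask).sum()) / n if n else float("nan")
    return GroundTruth(pvs, fractions, records)


# ---------------------------------------------------------------------------
# lesions


def _place_spheres(rng, atlas, host_mask, count, radius_range) -> np.ndarray:
    mask = np.zeros(atlas.shape, dtype=bool)
    idx = np.argwhere(host_mask)
    if len(idx) == 0 or count == 0:
        return mask
    h = np.asarray(atlas.voxel_size_mm)
    for _ in range(count):
        r = rng.uniform(*radius_range)
        c = idx[rng.integers(len(idx))] * h
        box, i0 = _capsule_voxels(atlas.shape, h, c, c, r)
        if box is None:
            continue
        sl = tuple(slice(a, a + s) for a, s in zip(i0, box.shape))
        mask[sl] |= box & host_mask[sl]
    return mask


def generate_lesion_masks(
    spec: PhantomSpec, atlas: RegionAtlas
) -> tuple[np.ndarray, np.ndarray]:
    """WMH blobs (in white matter) and lacune cavities (WM or BG), as spheres
    clipped to their host region."""
    rng = spec.rng(2)
    wm = atlas.region_mask("wm")
    wmh = _place_spheres(rng, atlas, wm, spec.wmh_blob_count, spec.wmh_radius_mm_range)
    host = wm | atlas.region_mask("bg")
    lacunes = _place_spheres(rng, atlas, host, spec.lacune_count, spec.lacune_radius_mm_range)
    return wmh, lacunes


# ---------------------------------------------------------------------------
# rendering


def render_sequences(
    spec: PhantomSpec,
    atlas: RegionAtlas,
    truth: GroundTruth,
    wmh_mask: np.ndarray,
    lacune_mask: np.ndarray,
) -> tuple[ImageVolume, ImageVolume]:
    """Render T2 and FLAIR as piecewise-constant tissue classes plus noise.

    Overlapping masks resolve by precedence lacune > PVS > WMH > tissue.
    With ``noise_sigma == 0`` the volumes equal the contrast levels exactly.
    """
    classes = np.full(atlas.shape, "background", dtype=object)
    classes[atlas.icv_mask] = "tissue"
    classes[wmh_mask.astype(bool)] = "wmh"
    classes[truth.pvs_mask] = "pvs"
    classes[lacune_mask.astype(bool)] = "lacune"

    rng = spec.rng(3)
    out = []
    for seq in ("t2", "flair"):
        levels = spec.contrast_levels[seq]
        vol = np.zeros(atlas.shape, dtype=np.float64)
        for cls, level in levels.items():
            vol[classes == cls] = level
        if spec.noise_sigma > 0:
            if spec.noise_model == "rician":
                n1 = rng.normal(0.0, spec.noise_sigma, atlas.shape)
                n2 = rng.normal(0.0, spec.noise_sigma, atlas.shape)
                vol = np.sqrt((vol + n1) ** 2 + n2**2)
            else:
                vol = vol + rng.normal(0.0, spec.noise_sigma, atlas.shape)
        out.append(ImageVolume(vol, atlas.voxel_size_mm))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohort covariates


@dataclass
class EffectConfig:
    """Coefficients of the log-scale generative model for regional PVS burden.

    Each regional log-burden is a linear function of centered covariates
    plus Gaussian noise, then exponentiated — so the marginals are
    log-normal and the transformation ladder should pick the logarithm.
    ``psqi_ratio`` enters the white-matter equation only, so it appears in
    the WM/BG ratio (log-ratio = log WM − log BG) but cancels nowhere else.
    Default magnitudes are on the scale of the regression coefficients the
    study design targets. ``EffectConfig.null()`` zeroes every effect.
    """

    age_bg: float = 0.02
    htn_bg: float = 0.30
    lacune_bg: float = 0.05
    microbleed_bg: float = 0.06
    wmh_bg: float = 0.15
    age_wm: float = 0.02
    htn_wm: float = 0.50
    lacune_wm: float = 0.12
    psqi_ratio: float = 0.04
    mean_frac: dict[str, float] = field(
        default_factory=lambda: {"bg": 4.0, "wm": 1.1, "bs": 0.6}
    )
    shared_sd: float = 0.30  # latent per-subject SVD severity, common to all regions
    noise_sd: float = 0.35

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(
            age_bg=0, htn_bg=0, lacune_bg=0, microbleed_bg=0, wmh_bg=0,
            age_wm=0, htn_wm=0, lacune_wm=0, psqi_ratio=0,
        )


def _ordinal_quantile_score(x: np.ndarray, n_grades: int = 5) -> np.ndarray:
    """Monotone 0..n_grades-1 score by quantile binning (a stand-in for the
    visual PVS rating, driven directly by true burden)."""
    qs = np.quantile(x, np.linspace(0, 1, n_grades + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(int)


def generate_cohort_table(
    n_subjects: int,
    effect_config: EffectConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the clinical covariate table plus latent regional PVS burdens.

    Covariate marginals follow the study population (27% female, 66%
    hypertension, mean age 70, overdispersed lacune counts, mostly-zero
    microbleeds, ~1% WMH/ICV). Latent fractional volumes come from the
    log-scale model in :class:`EffectConfig`.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    eff = effect_config or EffectConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))
    n = int(n_subjects)

    age = rng.normal(70.2, 10.8, n)
    female = rng.binomial(1, 0.268, n)
    htn = rng.binomial(1, 0.662, n)
    dyslipidemia = rng.binomial(1, 0.549, n)
    diabetes = rng.binomial(1, 0.324, n)
    smoking = rng.binomial(1, 0.338, n)
    alcohol = rng.binomial(1, 0.394, n)
    bmi = rng.normal(27.5, 4.0, n)
    psqi = np.clip(np.round(rng.gamma(2.2, 3.2, n)), 0, 21).astype(int)
    ess = np.clip(np.round(rng.gamma(2.0, 2.6, n)), 0, 24).astype(int)
    p_nb = 1.2 / (1.2 + 1.9)
    lacunes = rng.negative_binomial(1.2, p_nb, n)
    microbleeds = rng.binomial(1, 0.25, n) * (1 + rng.poisson(1.5, n))
    wmh_ratio = rng.lognormal(-0.206, 0.776, n)

    def centered(x, m):
        return np.asarray(x, dtype=float) - m

    lin_bg = (
        eff.age_bg * centered(age, 70.0)
        + eff.htn_bg * centered(htn, 0.66)
        + eff.lacune_bg * centered(lacunes, 1.9)
        + eff.microbleed_bg * centered(microbleeds, 0.5)
        + eff.wmh_bg * centered(wmh_ratio, 1.1)
    )
    lin_wm = (
        eff.age_wm * centered(age, 70.0)
        + eff.htn_wm * centered(htn, 0.66)
        + eff.lacune_wm * centered(lacunes, 1.9)
        + eff.psqi_ratio * centered(psqi, 6.0)
    )
    severity = rng.normal(0, eff.shared_sd, n)  # couples the three regions, as in SVD
    log_bg = np.log(eff.mean_frac["bg"]) + lin_bg + severity + rng.normal(0, eff.noise_sd, n)
    log_wm = np.log(eff.mean_frac["wm"]) + lin_wm + severity + rng.normal(0, eff.noise_sd, n)
    log_bs = np.log(eff.mean_frac["bs"]) + severity + rng.normal(0, eff.noise_sd, n)

    frac_bg = np.exp(log_bg)
    frac_wm = np.exp(log_wm)
    frac_bs = np.exp(log_bs)

    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "female": female,
            "hypertension": htn,
            "dyslipidemia": dyslipidemia,
            "diabetes": diabetes,
            "bmi": bmi,
            "smoking": smoking,
            "alcohol": alcohol,
            "psqi": psqi,
            "ess": ess,
            "lacune_count": lacunes,
            "microbleed_count": microbleeds,
            "wmh_ratio": wmh_ratio,
            "frac_bg": frac_bg,
            "frac_wm": frac_wm,
            "frac_bs": frac_bs,
            "wm_bg_ratio": frac_wm / frac_bg,
            "visual_bg": _ordinal_quantile_score(frac_bg),
            "visual_wm": _ordinal_quantile_score(frac_wm),
            "visual_midbrain": rng.binomial(1, 0.747, n),
        }
    )
    return df
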