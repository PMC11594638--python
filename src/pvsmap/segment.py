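"""PVS segmentation: thresholding, dual-sequence combination, cluster and
lesion filtering.

Detection is region-aware in the NAWM-vs-WMH sense: in normal-appearing
white matter the T2 bright-tube vesselness alone is thresholded; inside the
WMH mask the T2 response is combined with the dark-tube FLAIR response by a
voxelwise minimum, so both sequences must agree before a voxel can survive
— the most false-positive-averse reading of dual-sequence detection. The
pipeline order is fixed: threshold -> lesion exclusion -> small-cluster
removal, so lesion remnants can never prop up a sub-threshold cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import spearmanr

from .image import RegionAtlas
from .vesselness import VesselnessMap

__all__ = [
    "SegmentationParams",
    "PVSMask",
    "combine_vesselness",
    "threshold_map",
    "calibrate_threshold",
    "cluster_filter",
    "apply_exclusions",
    "segment_pvs",
]

_CONNECTIVITY_STRUCT = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationParams:
    """Thresholds and cluster-filter settings.

    The default thresholds are the operating point produced by the
    visual-rating calibration on the reference phantom cohort
    (:func:`pvsmap.pipeline.reference_calibration`); recalibrate when the
    filter scales, constants or acquisition geometry change.
    ``min_cluster_voxels`` follows the convention that clusters of that many
    voxels *or fewer* are removed (default 5, i.e. 3.65 mm^3 at 0.9 mm
    isotropic resolution). 26-connectivity keeps obliquely oriented tubes
    connected.
    """

    threshold_nawm: float = 0.15
    threshold_wmh: float = 0.15
    min_cluster_voxels: int = 5
    connectivity: int = 26
    combine_rule: str = "min"
    # margin (voxels, 26-neighbourhood dilations) around lacune/stroke masks:
    # the bright rim of a cavity produces spurious curvilinear responses
    exclusion_dilation_voxels: int = 2

    def __post_init__(self) -> None:
        for name, t in (("threshold_nawm", self.threshold_nawm),
                        ("threshold_wmh", self.threshold_wmh)):
            if not (0 < t < 1):
                raise ValueError(f"{name} must be in (0, 1), got {t}")
        if self.min_cluster_voxels < 0:
            raise ValueError("min_cluster_voxels must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.combine_rule != "min":
            raise ValueError("only the voxelwise-min combine rule is implemented")
        if self.exclusion_dilation_voxels < 0:
            raise ValueError("exclusion_dilation_voxels must be >= 0")


@dataclass
class PVSMask:
    """Final binary PVS mask plus provenance and cluster bookkeeping.

    ``provenance`` is 1 where the NAWM rule fired and 2 where the WMH rule
    fired; ``cluster_labels``/``cluster_sizes`` describe the surviving
    connected components.
    """

    mask: np.ndarray
    provenance: np.ndarray
    cluster_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    cluster_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.cluster_labels is None:
            self.cluster_labels = np.zeros(self.mask.shape, dtype=np.int32)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def _check_same_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch between {what}: {a.shape} vs {b.shape}")


def combine_vesselness(
    v_t2: VesselnessMap, v_flair_dark: VesselnessMap, wmh_mask: np.ndarray
) -> np.ndarray:
    """Merge T2 and dark-tube FLAIR vesselness: T2 outside the WMH mask,
    voxelwise minimum of the two inside it."""
    _check_same_grid(v_t2.values, v_flair_dark.values, "T2 and FLAIR vesselness")
    _check_same_grid(v_t2.values, wmh_mask, "vesselness and WMH mask")
    wmh = wmh_mask.astype(bool)
    out = np.array(v_t2.values, dtype=np.float64, copy=True)
    out[wmh] = np.minimum(v_t2.values[wmh], v_flair_dark.values[wmh])
    return out


def threshold_map(
    combined: np.ndarray,
    atlas: RegionAtlas,
    wmh_mask: np.ndarray,
    params: SegmentationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary candidate mask: vesselness >= the NAWM or WMH threshold,
    restricted to the ICV. Returns (mask, provenance)."""
    _check_same_grid(combined, atlas.labels, "vesselness and atlas")
    _check_same_grid(combined, wmh_mask, "vesselness and WMH mask")
    wmh = wmh_mask.astype(bool)
    nawm_hit = (combined >= params.threshold_nawm) & ~wmh
    wmh_hit = (combined >= params.threshold_wmh) & wmh
    mask = (nawm_hit | wmh_hit) & atlas.icv_mask
    provenance = np.zeros(combined.shape, dtype=np.int8)
    provenance[nawm_hit & mask] = 1
    provenance[wmh_hit & mask] = 2
    return mask, provenance


def apply_exclusions(
    mask: np.ndarray,
    lacune_mask: np.ndarray,
    stroke_mask: np.ndarray | None = None,
    dilation_voxels: int = 0,
) -> np.ndarray:
    """Zero the mask inside lacune and subacute-stroke areas.

    ``dilation_voxels`` grows each exclusion mask by that many
    26-neighbourhood dilations first, removing the lesion rim as well —
    cavity rims are bright on T2 and otherwise leave spurious curvilinear
    responses around every excluded lesion.
    """
    mask = np.asarray(mask).astype(bool)
    _check_same_grid(mask, lacune_mask, "PVS and lacune masks")
    struct = _CONNECTIVITY_STRUCT[26]

    def grow(m):
        m = m.astype(bool)
        if dilation_voxels and m.any():
            m = ndimage.binary_dilation(m, structure=struct, iterations=dilation_voxels)
        return m

    out = mask & ~grow(lacune_mask)
    if stroke_mask is not None:
        _check_same_grid(mask, stroke_mask, "PVS and stroke masks")
        out &= ~grow(stroke_mask)
    return out


def cluster_filter(
    mask: np.ndarray, params: SegmentationParams, provenance: np.ndarray | None = None
) -> PVSMask:
    """Remove connected components with <= ``min_cluster_voxels`` voxels.

    Components are found under the configured 6/18/26 neighborhood. The
    returned mask carries relabelled (1..k) surviving clusters and their
    sizes. Idempotent: filtering a filtered mask changes nothing.
    """
    mask = np.asarray(mask).astype(bool)
    struct = _CONNECTIVITY_STRUCT[params.connectivity]
    labels, n = ndimage.label(mask, structure=struct)
    if n == 0:
        return PVSMask(mask=np.zeros_like(mask), provenance=_prov(mask, provenance))
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes > params.min_cluster_voxels)
    keep = keep[keep != 0]
    keep_lut = np.zeros(n + 1, dtype=np.int32)
    keep_lut[keep] = np.arange(1, len(keep) + 1)
    new_labels = keep_lut[labels]
    out_mask = new_labels > 0
    cluster_sizes = {int(keep_lut[k]): int(sizes[k]) for k in keep}
    return PVSMask(
        mask=out_mask,
        provenance=_prov(out_mask, provenance),
        cluster_labels=new_labels,
        cluster_sizes=cluster_sizes,
    )


def _prov(mask: np.ndarray, provenance: np.ndarray | None) -> np.ndarray:
    if provenance is None:
        return mask.astype(np.int8)
    return np.where(mask, provenance, 0).astype(np.int8)


def segment_pvs(
    v_t2: VesselnessMap,
    v_flair_dark: VesselnessMap,
    atlas: RegionAtlas,
    wmh_mask: np.ndarray,
    lacune_mask: np.ndarray,
    stroke_mask: np.ndarray | None,
    params: SegmentationParams,
) -> PVSMask:
    """Full segmentation chain: combine -> threshold -> ROI restriction ->
    exclusions -> cluster filter, in that fixed order.

    The candidate mask is restricted to the three quantification regions
    (WM, BG, BS): PVS are measured there, and the restriction suppresses
    spurious edge responses near the intracranial boundary, which lies
    outside every region.
    """
    combined = combine_vesselness(v_t2, v_flair_dark, wmh_mask)
    cand, provenance = threshold_map(combined, atlas, wmh_mask, params)
    cand &= atlas.labels > 0
    cand = apply_exclusions(cand, lacune_mask, stroke_mask,
                            dilation_voxels=params.exclusion_dilation_voxels)
    return cluster_filter(cand, params, provenance)


def calibrate_threshold(
    subjects: list[dict],
    visual_scores,
    candidate_thresholds: np.ndarray,
    params: SegmentationParams | None = None,
) -> float:
    """Choose one cohort-wide threshold against the visual rating.

    Each subject dict carries ``v_t2``, ``v_flair_dark`` (VesselnessMap),
    ``atlas`` (RegionAtlas), ``wmh_mask``, ``lacune_mask`` and optional
    ``stroke_mask``. ``visual_scores`` is either one score per subject, or
    a mapping of region name -> per-subject scores (as when basal-ganglia
    and white-matter ratings are available separately); in the mapped form
    each region's fractional volume is correlated with its own rating.

    For every candidate the full chain is run with that value as both the
    NAWM and WMH threshold, and the candidate maximizing the (mean)
    Spearman correlation between fractional volumes and visual scores
    wins; exact ties break toward the higher (more conservative)
    threshold. Correlating every available regional rating constrains the
    subject ordering in each region at once, which sharpens the optimum.
    """
    if isinstance(visual_scores, dict):
        score_map = {k: np.asarray(v, dtype=float) for k, v in visual_scores.items()}
    else:
        score_map = {None: np.asarray(visual_scores, dtype=float)}
    for s in score_map.values():
        if len(subjects) != len(s):
            raise ValueError("one visual score per subject required")
        if len(subjects) < 2 or len(np.unique(s)) < 2:
            raise ValueError("need >= 2 subjects spanning >= 2 visual grades")
    candidates = np.sort(np.asarray(candidate_thresholds, dtype=float))
    if candidates.size == 0:
        raise ValueError("empty candidate grid")
    if candidates.size == 1:
        return float(candidates[0])
    base = params or SegmentationParams()

    best_t, best_rho = None, -np.inf
    for t in candidates:
        p = SegmentationParams(
            threshold_nawm=float(t),
            threshold_wmh=float(t),
            min_cluster_voxels=base.min_cluster_voxels,
            connectivity=base.connectivity,
            combine_rule=base.combine_rule,
        )
        fracs: dict = {k: [] for k in score_map}
        for sub in subjects:
            seg = segment_pvs(
                sub["v_t2"], sub["v_flair_dark"], sub["atlas"],
                sub["wmh_mask"], sub["lacune_mask"], sub.get("stroke_mask"), p,
            )
            for key in score_map:
                rmask = (sub["atlas"].labels > 0 if key is None
                         else sub["atlas"].region_mask(key))
                fracs[key].append(
                    100.0 * float((seg.mask & rmask).sum()) / float(rmask.sum())
                )
        rhos = []
        for key, scores in score_map.items():
            f = np.asarray(fracs[key])
            if np.ptp(f) == 0:
                rhos = []
                break
            rho = spearmanr(f, scores).statistic
            if not np.isfinite(rho):
                rhos = []
                break
            rhos.append(rho)
        if not rhos:
            continue
        mean_rho = float(np.mean(rhos))
        if mean_rho >= best_rho:  # ties -> higher threshold (ascending grid)
            best_rho, best_t = mean_rho, float(t)
    if best_t is None:
        raise ValueError("no candidate threshold yields a defined correlation")
    if best_rho < 1.0:
        warnings.warn(
            f"calibrated threshold {best_t} reaches Spearman rho {best_rho:.3f} (< 1)",
            stacklevel=2,
        )
    return best_t
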