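"""Regional PVS metrics: fractional volumes, the WM/BG ratio, WMH/ICV.

Fractional PVS volume is 100 * (segmented PVS voxels in a region) /
(region voxels); the region denominator includes WMH areas, since PVS are
detected inside WMHs too. The WM/BG ratio contrasts lobar against deep
burden and is undefined (missing) when the BG fraction is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .image import RegionAtlas
from .phantom import REGIONS
from .segment import PVSMask

__all__ = ["SubjectMetrics", "fractional_volume", "wm_bg_ratio", "wmh_icv_ratio",
           "cluster_counts_per_region", "compute_subject_metrics"]

log = logging.getLogger(__name__)


@dataclass
class SubjectMetrics:
    """Per-subject quantitative PVS measures (all fractions in %)."""

    frac_wm: float
    frac_bg: float
    frac_bs: float
    wm_bg_ratio: float | None
    wmh_icv_pct: float
    pvs_count_wm: int = 0
    pvs_count_bg: int = 0
    pvs_count_bs: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def fractional_volume(mask: PVSMask | np.ndarray, atlas: RegionAtlas, region: str | int) -> float:
    """Percent of the region's voxels covered by the PVS mask."""
    m = mask.mask if isinstance(mask, PVSMask) else np.asarray(mask).astype(bool)
    rmask = atlas.region_mask(region)
    n = int(rmask.sum())
    if n == 0:
        raise ValueError(f"region {region!r} is empty in the atlas")
    return 100.0 * float((m & rmask).sum()) / n


def wm_bg_ratio(frac_wm: float, frac_bg: float) -> float | None:
    """WM fractional volume over BG fractional volume; None when undefined."""
    if frac_bg <= 0:
        log.warning("wm_bg_ratio undefined: frac_bg = %s", frac_bg)
        return None
    return frac_wm / frac_bg


def wmh_icv_ratio(wmh_mask: np.ndarray, icv_mask: np.ndarray) -> float:
    """WMH volume as a percentage of intracranial volume."""
    wmh = np.asarray(wmh_mask).astype(bool)
    icv = np.asarray(icv_mask).astype(bool)
    n_icv = int(icv.sum())
    if n_icv == 0:
        raise ValueError("ICV mask is empty")
    if np.any(wmh & ~icv):
        raise ValueError("WMH mask extends outside the ICV: registration fault")
    return 100.0 * float(wmh.sum()) / n_icv


def cluster_counts_per_region(mask: PVSMask, atlas: RegionAtlas) -> dict[str, int]:
    """Surviving-cluster count per region; a cluster belongs to the region
    holding the majority of its voxels, ties to WM."""
    counts = {r: 0 for r in REGIONS}
    labels = mask.cluster_labels
    if not mask.cluster_sizes:
        return counts
    region_of_label = {}
    for cid in mask.cluster_sizes:
        in_cluster = labels == cid
        votes = {r: int((in_cluster & atlas.region_mask(r)).sum()) for r in REGIONS}
        best = max(votes.values())
        if best == 0:
            continue
        winners = [r for r, v in votes.items() if v == best]
        region_of_label[cid] = "wm" if "wm" in winners else winners[0]
    for r in region_of_label.values():
        counts[r] += 1
    return counts


def compute_subject_metrics(
    mask: PVSMask, atlas: RegionAtlas, wmh_mask: np.ndarray
) -> SubjectMetrics:
    frac = {r: fractional_volume(mask, atlas, r) for r in REGIONS}
    counts = cluster_counts_per_region(mask, atlas)
    return SubjectMetrics(
        frac_wm=frac["wm"],
        frac_bg=frac["bg"],
        frac_bs=frac["bs"],
        wm_bg_ratio=wm_bg_ratio(frac["wm"], frac["bg"]),
        wmh_icv_pct=wmh_icv_ratio(wmh_mask, atlas.icv_mask),
        pvs_count_wm=counts["wm"],
        pvs_count_bg=counts["bg"],
        pvs_count_bs=counts["bs"],
    )
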