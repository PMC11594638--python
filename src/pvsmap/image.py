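"""Image containers and NIfTI I/O.

All volumes in the pipeline live on a common co-registered voxel grid; the
only geometry carried around is the voxel spacing in mm. NIfTI-1 reading and
writing is delegated to nibabel, with the spacing taken from / written to the
header zooms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RegionAtlas", "WM", "BG", "BS", "REGION_LABELS"]

# Atlas label values for the three PVS quantification regions.
WM = 1
BG = 2
BS = 3
REGION_LABELS = {"wm": WM, "bg": BG, "bs": BS}


@dataclass
class ImageVolume:
    """A 3D scalar grid plus isotropic-or-not voxel spacing in mm.

    Carrier for T2, FLAIR, vesselness maps and binary masks.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size_mm, (3,)))
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be positive, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(self.data), affine)
        img.header.set_zooms(self.voxel_size_mm)
        return img

    def save(self, path: str | Path) -> None:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        img = ImageVolume(data, self.voxel_size_mm).to_nifti()
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj), tuple(float(z) for z in zooms))


@dataclass
class RegionAtlas:
    """Integer label grid for the PVS quantification regions plus an ICV mask.

    Labels: 0 background / other intracranial tissue, 1 white matter,
    2 basal ganglia, 3 brainstem. The ICV mask is a superset of all three
    labelled regions.
    """

    labels: np.ndarray
    icv_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    region_labels: dict[str, int] = field(default_factory=lambda: dict(REGION_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.icv_mask = np.asarray(self.icv_mask).astype(bool)
        if self.labels.shape != self.icv_mask.shape:
            raise ValueError("label grid and ICV mask shapes differ")
        inside = self.labels > 0
        if np.any(inside & ~self.icv_mask):
            raise ValueError("labelled regions must lie inside the ICV mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def region_mask(self, region: str | int) -> np.ndarray:
        label = self.region_labels[region] if isinstance(region, str) else int(region)
        return self.labels == label

    def region_voxels(self, region: str | int) -> int:
        return int(self.region_mask(region).sum())

    def region_volume_mm3(self, region: str | int) -> float:
        return self.region_voxels(region) * self.voxel_volume_mm3

    def save(self, labels_path: str | Path, icv_path: str | Path | None = None) -> None:
        ImageVolume(self.labels.astype(np.int16), self.voxel_size_mm).save(labels_path)
        if icv_path is not None:
            ImageVolume(self.icv_mask, self.voxel_size_mm).save(icv_path)

    @classmethod
    def load(cls, labels_path: str | Path, icv_path: str | Path | None = None) -> "RegionAtlas":
        lab = ImageVolume.load(labels_path)
        labels = np.asarray(lab.data).astype(np.int32)
        if icv_path is not None:
            icv = ImageVolume.load(icv_path).data.astype(bool)
        else:
            icv = labels > 0
        return cls(labels, icv, lab.voxel_size_mm)
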