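"""Threshold-based hotspot segmentation and volumetric metrics.

A hotspot is the set of voxels inside a selection box whose intensity meets
a threshold (inclusive, >=). Thresholding at a reference-normalised cutoff
replaces the delicate segmentation step usual in quantitative nuclear
imaging: once the reference region fixes what "neutral bone" looks like,
"k times the reference mean" is a patient-independent definition of
clinically elevated uptake, and the mask it produces supports simple
volumetric readouts — voxel count, physical volume, max/mean uptake ratios,
an intensity-weighted centroid in anatomic coordinates and a Welch t-test
against the reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .frames import AnatomicFrame, world_to_anatomic
from .normalization import (
    IntensityStats,
    NormalizationModel,
    ReferenceRegion,
    hotspot_vs_reference_test,
    normalize,
    region_voxel_mask,
)
from .volume_io import ImageVolume

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelMask:
    """Boolean mask congruent with a parent volume's grid."""

    bits: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.bits.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def to_volume(self) -> ImageVolume:
        """uint8 ImageVolume view of the mask (for NIfTI export)."""
        return ImageVolume(self.bits.astype(np.uint8), self.affine.copy(), modality="CT")


@dataclass
class HotspotMetrics:
    voxel_count: int
    volume_mm3: float
    threshold_raw: float
    component_count: int
    max_ratio: float | None = None
    mean_ratio: float | None = None
    centroid_anatomic: np.ndarray | None = None
    t: float | None = None
    p: float | None = None

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    @property
    def defined(self) -> bool:
        """False when the mask was empty and intensity metrics are absent."""
        return self.voxel_count > 0

    def to_dict(self) -> dict:
        return {
            "voxel_count": self.voxel_count,
            "volume_mm3": self.volume_mm3,
            "volume_ml": self.volume_ml,
            "threshold_raw": self.threshold_raw,
            "component_count": self.component_count,
            "max_ratio": self.max_ratio,
            "mean_ratio": self.mean_ratio,
            "centroid_anatomic": None
            if self.centroid_anatomic is None
            else list(map(float, self.centroid_anatomic)),
            "t": self.t,
            "p": self.p,
        }


def select_box(
    bounds: Sequence[Sequence[float]],
    frame_tag: str = "world",
) -> ReferenceRegion:
    """Rectangular region selector: a box in world or anatomic coordinates."""
    return ReferenceRegion(bounds=np.asarray(bounds, dtype=float), frame_tag=frame_tag)


def max_fraction_threshold(spect: ImageVolume, fraction: float) -> float:
    """Threshold at a fraction of the global maximum (the non-normalised
    convention; 0.9 and 0.6 are the usual exemplar fractions)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vmax = float(np.max(spect.voxels))
    if vmax <= 0:
        raise ValueError("volume has no positive intensities")
    return fraction * vmax


def hotspot_mask(
    spect: ImageVolume,
    region: ReferenceRegion,
    threshold_raw: float,
    frame: AnatomicFrame | None = None,
) -> VoxelMask:
    """Voxels inside the region with intensity >= threshold (inclusive)."""
    in_region = region_voxel_mask(spect, region, frame)
    if not in_region.any():
        raise ValueError("region does not contain any voxel centre of the volume")
    bits = in_region & (np.asarray(spect.voxels) >= threshold_raw)
    return VoxelMask(bits, spect.affine.copy())


def connected_components(mask: VoxelMask) -> tuple[np.ndarray, list[int]]:
    """26-connected components, labelled 1..n by descending voxel count.

    Ties are broken by the smallest linear (C-order) voxel index in the
    component, so labelling is deterministic. Returns ``(labels, sizes)``.
    """
    raw, n = ndimage.label(mask.bits, structure=_STRUCT_26)
    if n == 0:
        return np.zeros_like(raw), []
    sizes = ndimage.sum_labels(np.ones_like(raw), raw, index=np.arange(1, n + 1)).astype(int)
    flat = raw.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # first occurrence per label (nz is ascending)
    np.minimum.at(first_idx, flat[nz], nz)
    order = sorted(range(1, n + 1), key=lambda lab: (-sizes[lab - 1], first_idx[lab]))
    remap = np.zeros(n + 1, dtype=raw.dtype)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[raw], [int(sizes[lab - 1]) for lab in order]


def hotspot_metrics(
    spect: ImageVolume,
    mask: VoxelMask,
    model: NormalizationModel,
    frame: AnatomicFrame,
    ref: IntensityStats,
    threshold_raw: float = float("nan"),
    weighted_centroid: bool = True,
) -> HotspotMetrics:
    """Volumetric and intensity metrics of a hotspot mask.

    ``max_ratio``/``mean_ratio`` are the masked max/mean intensities passed
    through the normalisation model; the centroid is the intensity-weighted
    mean of masked voxel centres, reported in anatomic (ML, AP, PROX)
    coordinates. An empty mask yields count 0 with intensity metrics flagged
    undefined (None).
    """
    bits = mask.bits
    if bits.shape != spect.voxels.shape:
        raise ValueError("mask shape does not match the SPECT grid")
    count = int(bits.sum())
    voxel_vol = float(abs(np.linalg.det(mask.affine[:3, :3])))
    _, sizes = connected_components(mask)
    if count == 0:
        return HotspotMetrics(
            voxel_count=0,
            volume_mm3=0.0,
            threshold_raw=threshold_raw,
            component_count=0,
        )

    values = np.asarray(spect.voxels, dtype=float)[bits]
    idx = np.argwhere(bits).astype(float)
    centres_world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    weights = values if weighted_centroid else np.ones_like(values)
    centroid_world = (centres_world * weights[:, None]).sum(axis=0) / weights.sum()

    hot_stats = IntensityStats.from_values(values) if count >= 2 else None
    if hot_stats is not None and ref.n >= 2:
        test = hotspot_vs_reference_test(hot_stats, ref)
    else:
        test = {"t": None, "p": None}

    return HotspotMetrics(
        voxel_count=count,
        volume_mm3=count * voxel_vol,
        threshold_raw=threshold_raw,
        component_count=len(sizes),
        max_ratio=float(normalize(float(values.max()), model)),
        mean_ratio=float(normalize(float(values.mean()), model)),
        centroid_anatomic=world_to_anatomic(centroid_world, frame),
        t=test["t"],
        p=test["p"],
    )
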