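"""Reading, writing and resampling of co-registered CT/SPECT volumes.

All world coordinates are the DICOM patient system (LPS) in millimetres.
Voxel indices are 0-based and the affine uses the index-centre convention:
index ``(0, 0, 0)`` maps to the centre of the first voxel. NIfTI files store
their affine in RAS; the LPS<->RAS flip (negate the first two world rows) is
applied symmetrically on write and read so a round trip is bit-exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

Modality = Literal["CT", "SPECT"]

#: Fill values used when sampling outside a volume's extent: "air" for CT,
#: "no counts" for SPECT.
FILL_VALUES = {"CT": -1024.0, "SPECT": 0.0}

# diag(-1,-1,1,1): LPS <-> RAS world-coordinate flip (involutory)
_LPS2RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class ImageVolume:
    """A 3D scalar grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    voxels
        3D array. CT values are Hounsfield-like; SPECT values are tracer
        counts and must be non-negative.
    affine
        4x4 homogeneous matrix mapping ``(i, j, k, 1)`` to world mm (LPS).
    modality
        ``"CT"`` or ``"SPECT"``.
    """

    voxels: np.ndarray
    affine: np.ndarray
    modality: Modality = "CT"
    #: set False for derived maps (e.g. z-scored SPECT) that may go negative
    validate: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D array with all dimensions >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.modality not in ("CT", "SPECT"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.validate and self.modality == "SPECT" and np.any(self.voxels < 0):
            raise ValueError("SPECT voxels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel pitch along each index axis, mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel (|det| of the linear part)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def fill_value(self) -> float:
        return FILL_VALUES[self.modality]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centres_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"),
            axis=-1,
        )
        return self.index_to_world(idx)


def _dicom_slice_geometry(ds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
        iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
        ps = np.asarray(ds.PixelSpacing, dtype=float)
    except AttributeError as exc:
        raise ValueError(f"missing DICOM geometry tag: {exc}") from exc
    return ipp, iop, ps


def read_dicom_series(directory: os.PathLike | str, modality: Modality | None = None) -> ImageVolume:
    """Read a single-frame-per-file DICOM series into an :class:`ImageVolume`.

    Slices are sorted by the projection of ImagePositionPatient onto the slice
    normal (not by InstanceNumber, which is unreliable on some exporters).
    RescaleSlope/Intercept are applied. The series must be geometrically
    uniform: one SeriesInstanceUID and a constant slice gap (1e-3 mm
    tolerance).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue  # non-DICOM clutter in the directory
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) != 1:
        raise ValueError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(uids)}")

    ipp0, iop, ps = _dicom_slice_geometry(datasets[0])
    row = iop[:3]
    col = iop[3:]
    normal = np.cross(row, col)

    order = sorted(datasets, key=lambda ds: float(np.dot(_dicom_slice_geometry(ds)[0], normal)))
    positions = np.array([np.dot(_dicom_slice_geometry(ds)[0], normal) for ds in order])
    if len(order) > 1:
        gaps = np.diff(positions)
        if np.ptp(gaps) > 1e-3:
            raise ValueError(f"non-uniform slice spacing: gaps range {gaps.min():.6f}..{gaps.max():.6f} mm")
        slice_gap = float(gaps.mean())
    else:
        slice_gap = float(getattr(order[0], "SliceThickness", 1.0))

    slices = []
    for ds in order:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pixel_array is (rows, cols): rows advance along `col`, cols along `row`.
    stack = np.stack(slices, axis=-1)  # (rows, cols, slice)
    vox = np.transpose(stack, (1, 0, 2))  # (i=cols, j=rows, k=slice)

    affine = np.eye(4)
    affine[:3, 0] = row * ps[1]
    affine[:3, 1] = col * ps[0]
    affine[:3, 2] = normal * slice_gap
    affine[:3, 3] = _dicom_slice_geometry(order[0])[0]

    if modality is None:
        modality = "CT" if getattr(datasets[0], "Modality", "CT") == "CT" else "SPECT"
    return ImageVolume(vox, affine, modality=modality)


def read_volume(path: os.PathLike | str, modality: Modality = "CT") -> ImageVolume:
    """Read a volume from ``.nii``/``.nii.gz`` (nibabel) or ``.nrrd`` (SimpleITK)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
        affine = _LPS2RAS @ np.asarray(img.affine)  # RAS (NIfTI native) -> LPS
        return ImageVolume(data, affine, modality=modality)
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D volume, got ndim={img.GetDimension()}")
        data = np.transpose(sitk.GetArrayFromImage(img).astype(float), (2, 1, 0))
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        affine = np.eye(4)
        affine[:3, :3] = direction * np.asarray(img.GetSpacing())  # ITK is LPS natively
        affine[:3, 3] = img.GetOrigin()
        return ImageVolume(data, affine, modality=modality)
    raise ValueError(f"unknown volume extension: {path.name}")


def write_volume(vol: ImageVolume, path: os.PathLike | str) -> None:
    """Write to NIfTI (sform, RAS) or NRRD (LPS); format chosen by extension."""
    path = Path(path)
    name = path.name.lower()
    if abs(np.linalg.det(vol.affine[:3, :3])) < 1e-12:
        raise ValueError("cannot write a volume with a non-invertible affine")
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64), _LPS2RAS @ vol.affine)
        img.set_sform(_LPS2RAS @ vol.affine, code=1)
        img.set_qform(None)
        nib.save(img, str(path))
        return
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(np.asarray(vol.voxels, dtype=np.float64), (2, 1, 0)))
        spacing = vol.spacing
        img.SetSpacing(tuple(spacing))
        img.SetDirection(tuple((vol.affine[:3, :3] / spacing).ravel()))
        img.SetOrigin(tuple(vol.affine[:3, 3]))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unknown volume extension: {path.name}")


def resample_to_frame(
    vol: ImageVolume,
    frame,
    spacing: Sequence[float],
    bounds: Sequence[Sequence[float]],
    order: int = 1,
) -> ImageVolume:
    """Resample onto a grid axis-aligned with an anatomic frame.

    Parameters
    ----------
    vol
        Input volume (any orientation).
    frame
        An :class:`~orthospect.frames.AnatomicFrame`; its axes must be
        orthonormal.
    spacing
        Output voxel pitch (mm) along the frame's ML, AP, PROX axes.
    bounds
        ``((ml_min, ml_max), (ap_min, ap_max), (prox_min, prox_max))`` in mm,
        frame coordinates.
    order
        Interpolation order: 1 (trilinear, default) or 0 (nearest, for masks).

    Output voxel ``(i, j, k)`` sits at frame coordinate
    ``bounds_min + (i, j, k) * spacing``; samples outside the input extent are
    set to the modality fill value (CT: -1024, SPECT: 0).
    """
    spacing = np.asarray(spacing, dtype=float)
    bounds = np.asarray(bounds, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive values")
    if bounds.shape != (3, 2) or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("bounds must be a non-degenerate (3, 2) box")
    axes = np.asarray(frame.axes, dtype=float)
    if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
        raise ValueError("frame axes must be orthonormal")

    shape = np.maximum(np.floor((bounds[:, 1] - bounds[:, 0]) / spacing).astype(int) + 1, 1)
    # affine of the output grid: index -> frame coords -> world
    out_affine = np.eye(4)
    out_affine[:3, :3] = axes.T * spacing
    out_affine[:3, 3] = np.asarray(frame.origin) + axes.T @ bounds[:, 0]

    idx = np.stack(np.meshgrid(*(np.arange(n) for n in shape), indexing="ij"), axis=-1)
    world = idx @ out_affine[:3, :3].T + out_affine[:3, 3]
    src_idx = vol.world_to_index(world)
    sampled = ndimage.map_coordinates(
        np.asarray(vol.voxels, dtype=float),
        np.moveaxis(src_idx, -1, 0),
        order=order,
        mode="constant",
        cval=vol.fill_value,
    )
    if vol.modality == "SPECT":
        np.maximum(sampled, 0.0, out=sampled)  # guard tiny negative interpolants
    return ImageVolume(sampled, out_affine, modality=vol.modality)
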