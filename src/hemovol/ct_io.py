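"""CT volume and mask I/O, HU calibration, and slice-thickness resampling.

Internal conventions
--------------------
* Voxel arrays are ordered ``(slice, row, col)`` = ``(z, y, x)``.
* The axial slice index increases inferior -> superior; volumes read from
  disk are normalised to this on load.
* ``spacing`` is ``(row_mm, col_mm, slice_mm)``.
* HU values are stored as float64 after rescale, even when integral,
  because downstream medians and slab averages are fractional.

Gantry tilt is never corrected; tilt metadata, when present in a DICOM
series, is recorded in ``CTVolume.meta`` only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pydicom

from .errors import CTReadError, GridMismatchError

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "read_ct",
    "write_ct",
    "read_mask",
    "write_mask",
    "resample_thickness",
]

#: Default analysis slice thickness in mm.
ANALYSIS_THICKNESS_MM = 5.0

#: Relative tolerance on slice-spacing uniformity for DICOM series.
SPACING_TOLERANCE = 0.05

_HU_PLAUSIBLE = (-1024.0, 4000.0)


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield-unit values with voxel spacing metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        HU values, float64. The slice axis runs inferior -> superior.
    spacing : tuple of float
        ``(row_mm, col_mm, slice_mm)``, each strictly positive.
    meta : dict
        Free-form provenance: source path, original thickness, rescale
        applied, warnings emitted, gantry tilt if recorded.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or not all(
            math.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < _HU_PLAUSIBLE[0] or hi > _HU_PLAUSIBLE[1]:
            msg = (
                f"HU range [{lo:.1f}, {hi:.1f}] outside plausible CT range "
                f"[{_HU_PLAUSIBLE[0]:.0f}, {_HU_PLAUSIBLE[1]:.0f}]"
            )
            self.meta.setdefault("warnings", []).append(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def slice_mm(self) -> float:
        return self.spacing[2]

    @property
    def voxel_volume_mm3(self) -> float:
        r, c, s = self.spacing
        return r * c * s


@dataclass
class SegmentationMask:
    """A binary 3D mask sharing a :class:`CTVolume`'s voxel grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        r, c, s = self.spacing
        return self.voxel_count * r * c * s / 1000.0

    def check_grid(self, vol: "CTVolume | SegmentationMask") -> None:
        """Raise :class:`GridMismatchError` unless grids are identical."""
        if self.shape != vol.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} does not match volume shape {vol.shape}"
            )
        if not np.allclose(self.spacing, vol.spacing, rtol=1e-6):
            raise GridMismatchError(
                f"mask spacing {self.spacing} does not match volume spacing {vol.spacing}"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
#
# On disk nibabel uses (x, y, z) data ordering; internally we use (z, y, x).
# Volumes are passed through as_closest_canonical so the slice axis always
# increases toward the vertex regardless of how the file was stored.
# ---------------------------------------------------------------------------


def _nifti_to_internal(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise CTReadError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    zx, zy, zz = (float(z) for z in img.header.get_zooms()[:3])
    voxels = np.transpose(data, (2, 1, 0))  # (x,y,z) -> (z,y,x)
    return voxels, (zy, zx, zz)


def _internal_to_nifti(voxels: np.ndarray, spacing: tuple[float, float, float]) -> nib.Nifti1Image:
    row_mm, col_mm, slice_mm = spacing
    data = np.transpose(voxels, (2, 1, 0))  # (z,y,x) -> (x,y,z)
    affine = np.diag([col_mm, row_mm, slice_mm, 1.0])
    return nib.Nifti1Image(data, affine)


def _read_nifti(path: Path) -> CTVolume:
    voxels, spacing = _nifti_to_internal(nib.load(str(path)))
    return CTVolume(
        voxels.astype(np.float64),
        spacing,
        meta={"source": str(path), "format": "nifti", "original_slice_mm": spacing[2]},
    )


# ---------------------------------------------------------------------------
# DICOM series I/O
# ---------------------------------------------------------------------------


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:  # skip non-DICOM clutter (e.g. DICOMDIR-less dirs)
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise CTReadError(f"no DICOM image files found under {path}")

    modality = getattr(datasets[0], "Modality", None)
    if modality != "CT":
        raise CTReadError(f"modality {modality!r} is not HU-calibrated CT")

    orientations = {tuple(round(float(v), 4) for v in ds.ImageOrientationPatient) for ds in datasets}
    if len(orientations) > 1:
        raise CTReadError(f"series mixes {len(orientations)} image orientations")

    # Sort inferior -> superior by the z component of ImagePositionPatient.
    zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
    order = np.argsort(zs, kind="stable")
    datasets = [datasets[i] for i in order]
    zs = [zs[i] for i in order]

    if len(datasets) > 1:
        diffs = np.diff(zs)
        if np.any(diffs < 1e-6):
            i = int(np.argmin(diffs))
            raise CTReadError(f"duplicate slice position at z={zs[i]:.3f} mm")
        mean_d = float(diffs.mean())
        if np.any(np.abs(diffs - mean_d) > SPACING_TOLERANCE * mean_d):
            i = int(np.argmax(np.abs(diffs - mean_d)))
            raise CTReadError(
                f"non-uniform slice spacing: gap of {diffs[i]:.3f} mm between "
                f"z={zs[i]:.3f} and z={zs[i + 1]:.3f} (expected ~{mean_d:.3f} mm)"
            )
        slice_mm = mean_d
    else:
        slice_mm = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    row_mm, col_mm = (float(v) for v in datasets[0].PixelSpacing)
    meta: dict[str, Any] = {
        "source": str(path),
        "format": "dicom_series",
        "original_slice_mm": slice_mm,
        "rescale_applied": True,
    }
    tilt = getattr(datasets[0], "GantryDetectorTilt", None)
    if tilt is not None:
        meta["gantry_tilt_deg"] = float(tilt)
    return CTVolume(voxels, (row_mm, col_mm, slice_mm), meta=meta)


def read_ct(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        A ``.nii``/``.nii.gz`` file or a directory of DICOM Part-10 files.
    format : {"dicom_series", "nifti"}, optional
        Inferred from the path when omitted.

    Returns
    -------
    CTVolume
        HU-calibrated volume with the slice axis inferior -> superior.
    """
    path = Path(path)
    if not path.exists():
        raise CTReadError(f"path does not exist: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_ct(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float64 HU)."""
    nib.save(_internal_to_nifti(vol.voxels, vol.spacing), str(path))


def read_mask(path: str | Path, companion: CTVolume | None = None) -> SegmentationMask:
    """Read a binary mask from NIfTI; voxels > 0.5 are foreground.

    When ``companion`` is given, the mask grid must match it exactly.
    """
    voxels, spacing = _nifti_to_internal(nib.load(str(Path(path))))
    mask = SegmentationMask(voxels > 0.5, spacing)
    if companion is not None:
        mask.check_grid(companion)
    return mask


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as NIfTI-1, uint8 {0, 1}."""
    nib.save(
        _internal_to_nifti(mask.voxels.astype(np.uint8), mask.spacing), str(Path(path))
    )


# ---------------------------------------------------------------------------
# Slice-thickness resampling
# ---------------------------------------------------------------------------


def resample_thickness(vol: CTVolume, target_mm: float = ANALYSIS_THICKNESS_MM) -> CTVolume:
    """Merge-and-average axial slices down to ``target_mm`` thickness.

    Each output slice is the thickness-weighted mean of the input slices it
    spans; fractional edge slices get fractional weights, so the HU mass
    ``sum(voxels) * slice_mm`` is conserved exactly when the target is an
    integer multiple of the source thickness. The in-plane grid is never
    touched, and thin->thick is the only allowed direction (the analysis
    never interpolates thicker data to a finer grid).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    t = vol.slice_mm
    if abs(t - target_mm) <= 1e-9:
        return vol
    if t > target_mm:
        raise ValueError(
            f"cannot resample {t:g} mm slices to thinner/finer {target_mm:g} mm: "
            "downsampling only"
        )
    n_in = vol.shape[0]
    total = n_in * t
    n_out = int(math.ceil(total / target_mm - 1e-9))
    out = np.empty((n_out,) + vol.shape[1:], dtype=np.float64)
    for j in range(n_out):
        z0 = j * target_mm
        z1 = min((j + 1) * target_mm, total)
        i0 = int(math.floor(z0 / t + 1e-9))
        i1 = min(int(math.ceil(z1 / t - 1e-9)), n_in)
        w = np.array(
            [min(z1, (i + 1) * t) - max(z0, i * t) for i in range(i0, i1)], dtype=np.float64
        )
        out[j] = np.tensordot(w, vol.voxels[i0:i1], axes=(0, 0)) / w.sum()
    meta = dict(vol.meta)
    meta["original_slice_mm"] = meta.get("original_slice_mm", t)
    meta["resampled_to_mm"] = float(target_mm)
    return CTVolume(out, (vol.spacing[0], vol.spacing[1], float(target_mm)), meta=meta)
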