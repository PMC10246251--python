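"""Intracranial masking and anatomical false-positive exclusion geometry.

Threshold-based hyperdensity detection on head CT is confounded by normal
structures that are physiologically dense: the dural venous sinuses
(torcular Herophili, straight / sagittal / transverse sinuses) hug the
inner table of the skull, and the falx cerebri runs along the posterior
mid-sagittal plane. This module builds

1. the *intracranial mask* — the brain cavity enclosed by the skull, over
   which the reference median HU is computed, and
2. the *exclusion zone* — a geometric surrogate for those dural/falcine
   structures: a thin peripheral shell just inside the skull plus a narrow
   posterior midline band.

The zone is a deterministic geometric construction, not an anatomical
atlas; it is functionally analogous to (not a reimplementation of)
commercial sinus/falx rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume, SegmentationMask
from .errors import EmptyMaskError, NotHeadCTError

__all__ = [
    "MaskingParams",
    "intracranial_mask",
    "slice_range_filter",
    "exclusion_zone",
]


@dataclass(frozen=True)
class MaskingParams:
    """Parameters of the intracranial / exclusion-zone geometry.

    Attributes
    ----------
    bone_hu : float
        HU above which a voxel is called skull (default 300).
    brain_hu_window : tuple of float
        ``(low, high)`` HU window for parenchyma candidates (default 0-100).
        Voxels between ``high`` and ``bone_hu`` (acute blood, dense dura)
        are *also* kept inside the cavity so hematoma is never carved out
        of the brain mask.
    dural_margin_mm : float
        Thickness of the peripheral shell, just inside the skull, presumed
        dural (default 3.0 mm).
    midline_band_mm : float
        Half-width of the posterior mid-sagittal exclusion band covering
        the falx and midline sinuses (default 2.0 mm).
    """

    bone_hu: float = 300.0
    brain_hu_window: tuple[float, float] = (0.0, 100.0)
    dural_margin_mm: float = 3.0
    midline_band_mm: float = 2.0

    def __post_init__(self) -> None:
        low, high = self.brain_hu_window
        if not low < high:
            raise ValueError("brain_hu_window must satisfy low < high")
        if self.bone_hu <= high:
            raise ValueError("bone_hu must exceed brain_hu_window.high")
        if self.dural_margin_mm < 0 or self.midline_band_mm < 0:
            raise ValueError("margins must be >= 0")


def intracranial_mask(vol: CTVolume, params: MaskingParams = MaskingParams()) -> SegmentationMask:
    """Extract the brain cavity enclosed by the skull.

    Procedure: threshold the skull (HU > ``bone_hu``), fill the cavity it
    encloses slice-by-slice, keep the largest 3D connected cavity
    component, then keep cavity voxels whose HU lies in
    ``[brain_hu_window.low, bone_hu)`` — the union of the parenchyma
    window and the hyperdense (blood) range — so hematoma voxels remain
    part of the brain mask. Bone voxels are never included.
    """
    skull = vol.voxels > params.bone_hu
    if not skull.any():
        raise NotHeadCTError(
            f"not a head CT: no voxel exceeds the bone threshold {params.bone_hu:g} HU"
        )
    filled = np.empty_like(skull)
    for z in range(skull.shape[0]):
        filled[z] = ndimage.binary_fill_holes(skull[z])
    cavity = filled & ~skull
    labels, n = ndimage.label(cavity, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise NotHeadCTError("skull found but it encloses no cavity")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    cavity = labels == (1 + int(np.argmax(sizes)))
    low = params.brain_hu_window[0]
    keep = cavity & (vol.voxels >= low) & (vol.voxels < params.bone_hu)
    if not keep.any():
        raise NotHeadCTError("intracranial cavity contains no tissue-range voxels")
    return SegmentationMask(keep, vol.spacing)


def slice_range_filter(mask: SegmentationMask) -> SegmentationMask:
    """Drop axial slices below the skull base and above the vertex.

    The scan range below the brain stem is identified as every slice whose
    cavity cross-section is under 25% of the maximum cross-section; the top
    of the range is the highest slice containing any cavity voxel. Slices
    outside ``[lowest qualifying, highest]`` are zeroed. A mask already
    within range is returned unchanged in content (idempotent).
    """
    areas = mask.voxels.sum(axis=(1, 2))
    if areas.sum() == 0:
        raise EmptyMaskError("cannot range-filter an empty mask")
    cutoff = 0.25 * areas.max()
    qualifying = np.nonzero(areas >= cutoff)[0]
    z_low = int(qualifying[0])
    z_high = int(np.nonzero(areas > 0)[0][-1])
    out = mask.voxels.copy()
    out[:z_low] = False
    out[z_high + 1 :] = False
    return SegmentationMask(out, mask.spacing)


def _shell_structure(spacing: tuple[float, float, float], margin_mm: float) -> np.ndarray:
    """Ellipsoidal structuring element reaching ``margin_mm`` in-plane.

    Through-plane the reach is at least one slice: with 5 mm analysis
    slices and a 3 mm margin a purely metric element would never erode in
    z, leaving the cavity's top and bottom faces — where partial-volume
    averaging with bone is strongest — outside the peripheral shell.
    """
    row_mm, col_mm, slice_mm = spacing
    margin_z = max(margin_mm, slice_mm)
    rz = int(margin_z / slice_mm + 1e-9)
    ry = int(margin_mm / row_mm + 1e-9)
    rx = int(margin_mm / col_mm + 1e-9)
    dz, dy, dx = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (
        (dz * slice_mm / margin_z) ** 2
        + (dy * row_mm / margin_mm) ** 2
        + (dx * col_mm / margin_mm) ** 2
    ) <= 1.0 + 1e-9


def exclusion_zone(mask: SegmentationMask, params: MaskingParams = MaskingParams()) -> SegmentationMask:
    """Mark where a hyperdense voxel is presumed dural/falcine, not blood.

    The zone is the union of

    * the peripheral shell: ``mask`` minus its 3D erosion by
      ``dural_margin_mm`` (where the venous sinuses run along the inner
      table), and
    * the posterior midline band: voxels within ``midline_band_mm`` of the
      per-slice mid-sagittal column, posterior to the per-slice in-plane
      centroid (where the falx and midline sinuses sit).

    Both margins at zero give an empty zone. The zone is always a subset
    of ``mask``.
    """
    zone = np.zeros(mask.shape, dtype=bool)
    row_mm, col_mm, _ = mask.spacing

    if params.dural_margin_mm > 0 and mask.voxels.any():
        struct = _shell_structure(mask.spacing, params.dural_margin_mm)
        eroded = ndimage.binary_erosion(mask.voxels, structure=struct)
        zone |= mask.voxels & ~eroded

    if params.midline_band_mm > 0:
        half_cols = params.midline_band_mm / col_mm
        cols = np.arange(mask.shape[2], dtype=np.float64)
        rows = np.arange(mask.shape[1], dtype=np.float64)
        for z in range(mask.shape[0]):
            sl = mask.voxels[z]
            if not sl.any():
                continue
            ys, xs = np.nonzero(sl)
            x_mid = xs.mean()  # mid-sagittal estimated per slice, no registration
            y_mid = ys.mean()
            band = (
                sl
                & (np.abs(cols[None, :] - x_mid) <= half_cols)
                & (rows[:, None] > y_mid)  # posterior half only
            )
            zone[z] |= band

    return SegmentationMask(zone, mask.spacing)
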