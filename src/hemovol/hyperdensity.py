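"""Hyperdensity detection: median-relative thresholding and volumetry.

The core detection rule: a voxel is a hyperdensity candidate when its HU
strictly exceeds the brain-tissue median by more than a fixed offset
(default 15 HU). Candidates are grouped into 3D connected components,
components are screened against a size floor (default 1 cc, the detection
limit) and against the anatomical exclusion zone (dural/falcine
structures), and the surviving volume is voxel count x voxel volume.

The median is computed over the whole intracranial mask *including* any
lesion voxels; for a very large hemorrhage this biases the reference
median upward slightly, a documented property of the single-pass rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage

from . import brain_masking
from .brain_masking import MaskingParams
from .ct_io import ANALYSIS_THICKNESS_MM, CTVolume, SegmentationMask, resample_thickness
from .errors import EmptyMaskError

__all__ = [
    "DetectionParams",
    "Component",
    "LesionReport",
    "brain_median",
    "threshold_hyperdense",
    "label_components",
    "filter_false_positives",
    "volume_cc",
    "detect_ich",
]

logger = logging.getLogger(__name__)

#: Component rejection reasons.
REASON_FLOOR = "below_detection_floor"
REASON_DURAL = "dural_structure"


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the hyperdensity detector.

    hu_offset
        Margin above the brain median, HU (default 15). Strict inequality:
        a voxel at exactly median + offset is excluded.
    min_component_cc
        Per-component volume floor in cc (default 1.0, the detection
        limit); smaller components are rejected.
    connectivity
        3D neighbourhood for component labeling: 6, 18 or 26 (default 26).
    dural_overlap_fraction
        Reject a component when more than this fraction of its voxels lie
        inside the exclusion zone (default 0.5).
    """

    hu_offset: float = 15.0
    min_component_cc: float = 1.0
    connectivity: int = 26
    dural_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.hu_offset <= 0:
            raise ValueError("hu_offset must be positive")
        if self.min_component_cc < 0:
            raise ValueError("min_component_cc must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class Component:
    """One connected hyperdense component and its screening outcome."""

    component_id: int
    volume_cc: float
    centroid_mm: tuple[float, float, float]  # (z, y, x) mm
    rejected: bool
    reason: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "id": self.component_id,
            "volume_cc": self.volume_cc,
            "centroid_mm": list(self.centroid_mm),
            "kept": not self.rejected,
            "reason": self.reason,
        }


@dataclass
class LesionReport:
    """Result of end-to-end hyperdensity detection on one scan.

    ``total_volume_cc`` is exactly the sum of kept component volumes;
    ``threshold_hu`` is exactly ``brain_median_hu + params.hu_offset``.
    ``mask`` is the kept-lesion mask on the analysis grid.
    """

    total_volume_cc: float
    components: list[Component]
    brain_median_hu: float
    threshold_hu: float
    params: DetectionParams
    mask: SegmentationMask | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "total_volume_cc": self.total_volume_cc,
            "brain_median_hu": self.brain_median_hu,
            "threshold_hu": self.threshold_hu,
            "components": [c.to_dict() for c in self.components],
            "params": {
                "hu_offset": self.params.hu_offset,
                "min_component_cc": self.params.min_component_cc,
                "connectivity": self.params.connectivity,
                "dural_overlap_fraction": self.params.dural_overlap_fraction,
            },
            "input_provenance": self.provenance,
        }


def brain_median(vol: CTVolume, brain_mask: SegmentationMask) -> float:
    """Median HU over the masked voxels.

    Even-count ties resolve to the mean of the two central order
    statistics (numpy's convention).
    """
    brain_mask.check_grid(vol)
    if not brain_mask.voxels.any():
        raise EmptyMaskError("brain median undefined for an empty mask")
    return float(np.median(vol.voxels[brain_mask.voxels]))


def threshold_hyperdense(
    vol: CTVolume,
    brain_mask: SegmentationMask,
    median_hu: float,
    params: DetectionParams = DetectionParams(),
) -> SegmentationMask:
    """Voxels in the brain mask with HU strictly above median + offset."""
    if not np.isfinite(median_hu):
        raise ValueError("median_hu must be finite")
    brain_mask.check_grid(vol)
    sel = brain_mask.voxels & (vol.voxels > median_hu + params.hu_offset)
    return SegmentationMask(sel, vol.spacing)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def label_components(mask: SegmentationMask, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label maximal connected components under 6/18/26-connectivity.

    Returns ``(labels, n)`` where labels is an int array (0 = background)
    and components are numbered 1..n. An empty mask yields n = 0.
    """
    labels, n = ndimage.label(mask.voxels, structure=_structure(connectivity))
    return labels, int(n)


def volume_cc(mask: SegmentationMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Mask volume: voxel count x row_mm x col_mm x slice_mm / 1000."""
    if spacing is None:
        spacing = mask.spacing
    r, c, s = spacing
    return int(mask.voxels.sum()) * r * c * s / 1000.0


def filter_false_positives(
    labels: np.ndarray,
    n: int,
    spacing: tuple[float, float, float],
    exclusion: SegmentationMask,
    params: DetectionParams = DetectionParams(),
) -> list[Component]:
    """Screen labeled components against the size floor and the exclusion zone.

    A component is rejected with reason ``below_detection_floor`` when its
    volume is under ``min_component_cc``, or ``dural_structure`` when more
    than ``dural_overlap_fraction`` of its voxels fall inside the
    exclusion zone. The size floor is evaluated first.
    """
    r, c, s = spacing
    vox_cc = r * c * s / 1000.0
    out: list[Component] = []
    if n == 0:
        return out
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64), labels, index=idx)
    in_zone = ndimage.sum_labels(exclusion.voxels.astype(np.float64), labels, index=idx)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, index=idx)
    for i, count, zone_count, cen in zip(idx, counts, in_zone, centroids):
        vol = float(count) * vox_cc
        centroid_mm = (float(cen[0]) * s, float(cen[1]) * r, float(cen[2]) * c)
        if vol < params.min_component_cc:
            out.append(Component(int(i), vol, centroid_mm, True, REASON_FLOOR))
        elif zone_count / count > params.dural_overlap_fraction:
            out.append(Component(int(i), vol, centroid_mm, True, REASON_DURAL))
        else:
            out.append(Component(int(i), vol, centroid_mm, False))
    return out


def detect_ich(
    vol: CTVolume,
    masking: MaskingParams = MaskingParams(),
    detection: DetectionParams = DetectionParams(),
    analysis_thickness_mm: float = ANALYSIS_THICKNESS_MM,
) -> LesionReport:
    """End-to-end hemorrhage detection on one head NCCT.

    Pipeline: resample to the analysis thickness -> intracranial mask ->
    axial range filter -> exclusion zone -> brain median -> median+offset
    threshold -> connected components -> false-positive screening ->
    volumetry. Deterministic for a fixed input.
    """
    work = resample_thickness(vol, analysis_thickness_mm)
    brain = brain_masking.intracranial_mask(work, masking)
    brain = brain_masking.slice_range_filter(brain)
    zone = brain_masking.exclusion_zone(brain, masking)
    median_hu = brain_median(work, brain)
    candidates = threshold_hyperdense(work, brain, median_hu, detection)
    labels, n = label_components(candidates, detection.connectivity)
    components = filter_false_positives(labels, n, work.spacing, zone, detection)

    kept_ids = [c.component_id for c in components if not c.rejected]
    kept_mask = np.isin(labels, kept_ids) if kept_ids else np.zeros(labels.shape, dtype=bool)
    total = float(sum(c.volume_cc for c in components if not c.rejected))
    logger.info(
        "detect_ich: median=%.2f HU threshold=%.2f HU, %d/%d components kept, %.2f cc",
        median_hu, median_hu + detection.hu_offset, len(kept_ids), n, total,
    )
    return LesionReport(
        total_volume_cc=total,
        components=components,
        brain_median_hu=median_hu,
        threshold_hu=median_hu + detection.hu_offset,
        params=detection,
        mask=SegmentationMask(kept_mask, work.spacing),
        provenance={
            "source": vol.meta.get("source", "<in-memory>"),
            "original_slice_mm": vol.meta.get("original_slice_mm", vol.slice_mm),
            "analysis_thickness_mm": analysis_thickness_mm,
            "masking": {
                "bone_hu": masking.bone_hu,
                "brain_hu_window": list(masking.brain_hu_window),
                "dural_margin_mm": masking.dural_margin_mm,
                "midline_band_mm": masking.midline_band_mm,
            },
        },
    )
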