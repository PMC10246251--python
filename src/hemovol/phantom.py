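"""Synthetic non-contrast head-CT phantom with ground-truthed hemorrhages.

The phantom emulates the features of a head NCCT that the detection
pipeline actually consumes: an ellipsoidal skull shell (~1200 HU) around
a brain cavity (~35 HU with Gaussian noise), optional ellipsoidal
hemorrhages (~70 HU) with analytically known volumes, and two optional
hyperdense-but-benign distractors — a thin posterior mid-sagittal plate
standing in for the falx cerebri and a posterior dural blob standing in
for the torcular/straight-sinus confluence, both at 60 HU. The distractor
HU is deliberately above the detection threshold so they can only be
removed by the anatomical rejection path, never by HU alone.

Voxelization uses partial-volume compositing: each structure contributes
its fractional occupancy of every voxel (2x2x2 supersampling), so
boundary voxels carry intermediate HU exactly as slab-averaged CT does.
A voxel belongs to a structure's *truth mask* when the structure fills at
least half of it.

Noise is i.i.d. Gaussian per voxel; CT streak and beam-hardening physics
are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .brain_masking import MaskingParams
from .ct_io import CTVolume, SegmentationMask
from .errors import PhantomSpecError
from .expansion import ExpansionCriteria, SerialComparison, compare_serial
from .hyperdensity import DetectionParams, detect_ich

__all__ = [
    "Lesion",
    "PhantomSpec",
    "PhantomTruth",
    "SerialPhantomPair",
    "generate_phantom",
    "generate_serial_pair",
    "simulate_cohort",
    "detect_cohort",
    "sphere_semi_axes",
    "default_lesion_center",
]

# Head geometry (mm). Outer skull ellipsoid semi-axes in (z, y, x) order
# and the shell thickness; the brain interior is the inner ellipsoid.
OUTER_SEMI_MM = (45.0, 85.0, 70.0)
SKULL_SHELL_MM = 6.0
INNER_SEMI_MM = tuple(a - SKULL_SHELL_MM for a in OUTER_SEMI_MM)

_SUPERSAMPLE = 2  # subdivisions per axis for partial-volume occupancy


@dataclass(frozen=True)
class Lesion:
    """An ellipsoidal hemorrhage: center and semi-axes in mm, (z, y, x) order."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    hu: float = 70.0

    @property
    def analytic_volume_cc(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


def sphere_semi_axes(volume_cc: float) -> tuple[float, float, float]:
    """Semi-axes (mm) of the sphere with the given volume in cc."""
    r = (volume_cc * 1000.0 * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return (r, r, r)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head scan.

    The default grid is 192x192 in-plane at 1 mm with 40 slices of
    2.5 mm — a sub-analysis thickness acquisition that exercises the
    merge-and-average resampling step. ``neck_slices`` sub-skull slices
    of soft tissue sit below the skull base.
    """

    shape: tuple[int, int, int] = (40, 192, 192)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)  # (row, col, slice) mm
    skull_hu: float = 1200.0
    brain_hu: float = 35.0
    air_hu: float = -1000.0
    noise_sigma: float = 4.0
    lesions: tuple[Lesion, ...] = ()
    falx_plate: bool = False
    sinus_blob: bool = False
    distractor_hu: float = 60.0
    neck_slices: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for les in self.lesions:
            if les.hu <= self.brain_hu:
                raise PhantomSpecError(
                    f"lesion HU {les.hu:g} must exceed brain HU {self.brain_hu:g}"
                )
        _validate_lesions_inside(self)

    # -- derived geometry -------------------------------------------------
    @property
    def neck_mm(self) -> float:
        return self.neck_slices * self.spacing[2]

    @property
    def head_center_mm(self) -> tuple[float, float, float]:
        """Center of the skull ellipsoids, (z, y, x) mm."""
        return (
            self.neck_mm + OUTER_SEMI_MM[0],
            self.shape[1] * self.spacing[0] / 2.0,
            self.shape[2] * self.spacing[1] / 2.0,
        )


def default_lesion_center(spec: PhantomSpec) -> tuple[float, float, float]:
    """A deep, slightly anterior, midline-crossing lesion site (z, y, x) mm.

    Anterior of the head center so even large lesions stay clear of the
    posterior falx-plate distractor.
    """
    cz, cy, cx = spec.head_center_mm
    return (cz, cy - 25.0, cx)


def _validate_lesions_inside(spec: PhantomSpec) -> None:
    """Every lesion ellipsoid must lie inside the brain interior."""
    cz, cy, cx = spec.head_center_mm
    az, ay, ax = INNER_SEMI_MM
    # sample the lesion surface densely; reject if any point leaves the
    # inner ellipsoid (small safety factor for sampling gaps)
    n = 512
    idx = np.arange(n, dtype=np.float64)
    phi = np.arccos(1 - 2 * (idx + 0.5) / n)
    theta = np.pi * (1 + 5**0.5) * idx
    uz, uy, ux = np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)
    for les in spec.lesions:
        lz, ly, lx = les.center_mm
        sz, sy, sx = les.semi_axes_mm
        pz, py, px = lz + sz * uz, ly + sy * uy, lx + sx * ux
        q = ((pz - cz) / az) ** 2 + ((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2
        if float(q.max()) > 0.995:
            raise PhantomSpecError(
                f"lesion at {les.center_mm} with semi-axes {les.semi_axes_mm} mm "
                "protrudes outside the brain interior"
            )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    lesion_masks: list[SegmentationMask]
    lesion_volumes_cc: list[float]  # analytic 4/3*pi*abc volumes
    distractor_masks: dict[str, SegmentationMask]
    cavity_mask: SegmentationMask
    brain_hu: float

    @property
    def total_lesion_cc(self) -> float:
        return float(sum(self.lesion_volumes_cc))


# ---------------------------------------------------------------------------
# Occupancy rasterisation
# ---------------------------------------------------------------------------


def _subcenters(n: int, step: float) -> np.ndarray:
    return (np.arange(n * _SUPERSAMPLE, dtype=np.float64) + 0.5) * (step / _SUPERSAMPLE)


def _pool(fine: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    s = _SUPERSAMPLE
    return fine.reshape(shape[0], s, shape[1], s, shape[2], s).mean(axis=(1, 3, 5))


def _ellipsoid_occupancy(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    semi: tuple[float, float, float],
) -> np.ndarray:
    """Fractional per-voxel occupancy of an axis-aligned ellipsoid."""
    row_mm, col_mm, slice_mm = spacing
    z = _subcenters(shape[0], slice_mm)
    y = _subcenters(shape[1], row_mm)
    x = _subcenters(shape[2], col_mm)
    qz = ((z - center[0]) / semi[0]) ** 2
    qy = ((y - center[1]) / semi[1]) ** 2
    qx = ((x - center[2]) / semi[2]) ** 2
    inside = qz[:, None, None] + qy[None, :, None] + qx[None, None, :] <= 1.0
    return _pool(inside, shape)


def _box_occupancy(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    lo_mm: tuple[float, float, float],
    hi_mm: tuple[float, float, float],
) -> np.ndarray:
    """Exact fractional occupancy of an axis-aligned box (z, y, x bounds in mm)."""
    row_mm, col_mm, slice_mm = spacing
    steps = (slice_mm, row_mm, col_mm)
    fracs = []
    for ax in range(3):
        edges = np.arange(shape[ax] + 1, dtype=np.float64) * steps[ax]
        overlap = np.clip(np.minimum(edges[1:], hi_mm[ax]) - np.maximum(edges[:-1], lo_mm[ax]), 0.0, None)
        fracs.append(overlap / steps[ax])
    return fracs[0][:, None, None] * fracs[1][None, :, None] * fracs[2][None, None, :]


@lru_cache(maxsize=8)
def _head_fields(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    neck_slices: int,
    falx_plate: bool,
    sinus_blob: bool,
) -> dict[str, np.ndarray]:
    """Lesion-independent occupancy fields, cached per geometry."""
    neck_mm = neck_slices * spacing[2]
    center = (
        neck_mm + OUTER_SEMI_MM[0],
        shape[1] * spacing[0] / 2.0,
        shape[2] * spacing[1] / 2.0,
    )
    f_outer = _ellipsoid_occupancy(shape, spacing, center, OUTER_SEMI_MM)
    f_inner = _ellipsoid_occupancy(shape, spacing, center, INNER_SEMI_MM)
    f_shell = np.clip(f_outer - f_inner, 0.0, 1.0)

    f_neck = np.zeros(shape)
    if neck_slices > 0:
        yy = (np.arange(shape[1]) + 0.5) * spacing[0]
        xx = (np.arange(shape[2]) + 0.5) * spacing[1]
        disc = ((yy[:, None] - center[1]) ** 2 + (xx[None, :] - center[2]) ** 2) <= 60.0**2
        f_neck[:neck_slices] = disc.astype(np.float64)

    cz, cy, cx = center
    f_falx = np.zeros(shape)
    if falx_plate:
        f_falx = _box_occupancy(
            shape,
            spacing,
            (cz - 20.0, cy + 15.0, cx - 0.75),
            (cz + 20.0, cy + 70.0, cx + 0.75),
        )
        f_falx = np.minimum(f_falx, f_inner)  # clip to the brain interior

    f_blob = np.zeros(shape)
    if sinus_blob:
        blob_center = (cz, cy + INNER_SEMI_MM[1] - 3.0, cx)
        f_blob = _ellipsoid_occupancy(shape, spacing, blob_center, (3.5, 3.5, 3.5))
        f_blob = np.minimum(f_blob, f_inner)

    return {"inner": f_inner, "shell": f_shell, "neck": f_neck, "falx": f_falx, "blob": f_blob}


def _mix(hu: np.ndarray, material_hu: float, f: np.ndarray) -> np.ndarray:
    return hu * (1.0 - f) + material_hu * f


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Rasterise a phantom spec into a CT volume plus its ground truth.

    Deterministic for a fixed seed; exactly noiseless when
    ``noise_sigma = 0``. Lesion truth masks must be pairwise disjoint.
    """
    fields = _head_fields(
        spec.shape, spec.spacing, spec.neck_slices, spec.falx_plate, spec.sinus_blob
    )
    f_inner = fields["inner"]

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    hu = _mix(hu, 40.0, fields["neck"])  # sub-skull soft tissue
    hu = _mix(hu, spec.skull_hu, fields["shell"])
    hu = _mix(hu, spec.brain_hu, f_inner)
    hu = _mix(hu, spec.distractor_hu, fields["falx"])
    hu = _mix(hu, spec.distractor_hu, fields["blob"])

    lesion_masks: list[SegmentationMask] = []
    occupied = np.zeros(spec.shape, dtype=bool)
    for les in spec.lesions:
        f_l = _ellipsoid_occupancy(spec.shape, spec.spacing, les.center_mm, les.semi_axes_mm)
        truth = f_l >= 0.5
        if (truth & occupied).any():
            raise PhantomSpecError("lesion truth masks overlap; move the lesions apart")
        occupied |= truth
        hu = _mix(hu, les.hu, f_l)
        lesion_masks.append(SegmentationMask(truth, spec.spacing))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, spec.shape)

    vol = CTVolume(
        hu,
        spec.spacing,
        meta={
            "source": "<phantom>",
            "original_slice_mm": spec.spacing[2],
            "seed": spec.seed,
            "noise_sigma": spec.noise_sigma,
        },
    )
    truth = PhantomTruth(
        lesion_masks=lesion_masks,
        lesion_volumes_cc=[l.analytic_volume_cc for l in spec.lesions],
        distractor_masks={
            name: SegmentationMask(fields[name] >= 0.5, spec.spacing)
            for name in ("falx", "blob")
            if fields[name].any()
        },
        cavity_mask=SegmentationMask(f_inner >= 0.5, spec.spacing),
        brain_hu=spec.brain_hu,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Serial pairs and cohorts
# ---------------------------------------------------------------------------


@dataclass
class SerialPhantomPair:
    """A baseline/follow-up phantom pair with its analytic-truth comparison."""

    baseline: tuple[CTVolume, PhantomTruth]
    followup: tuple[CTVolume, PhantomTruth]
    truth: SerialComparison


def generate_serial_pair(
    spec: PhantomSpec,
    followup_volume_cc: float,
    seed: int | None = None,
    criteria: ExpansionCriteria = ExpansionCriteria(),
) -> SerialPhantomPair:
    """Generate a baseline scan and a follow-up with a rescaled hematoma.

    The head geometry and the noise process are shared; the noise draws
    differ between the two scans. The single lesion is scaled
    isotropically so its analytic volume hits ``followup_volume_cc``; a
    follow-up lesion that would leave the brain raises
    :class:`~hemovol.errors.PhantomSpecError`. The truth label comes from
    the analytic volumes.
    """
    if len(spec.lesions) != 1:
        raise PhantomSpecError("serial pairs require a spec with exactly one lesion")
    les = spec.lesions[0]
    base_cc = les.analytic_volume_cc
    if base_cc < 1.0 or followup_volume_cc < 1.0:
        raise PhantomSpecError("both serial volumes must be >= 1 cc")
    scale = (followup_volume_cc / base_cc) ** (1.0 / 3.0)
    followup_lesion = dataclasses.replace(
        les, semi_axes_mm=tuple(a * scale for a in les.semi_axes_mm)
    )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    seed_b, seed_f = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    spec_b = dataclasses.replace(spec, seed=seed_b)
    spec_f = dataclasses.replace(spec, lesions=(followup_lesion,), seed=seed_f)
    truth = compare_serial(base_cc, followup_lesion.analytic_volume_cc, criteria)
    return SerialPhantomPair(
        baseline=generate_phantom(spec_b),
        followup=generate_phantom(spec_f),
        truth=truth,
    )


def simulate_cohort(
    n: int,
    growth_fraction: float = 0.25,
    seed: int = 0,
    criteria: ExpansionCriteria = ExpansionCriteria(),
) -> pd.DataFrame:
    """Draw a reproducible cohort of ``n`` serial-pair prescriptions.

    Baseline volumes are log-uniform on [2, 60] cc. A ``growth_fraction``
    share of pairs (rounded) are true expanders, drawn to clear *both*
    criteria with margin: the absolute increase is at least 8 cc and at
    least 55% of baseline. Non-expanders change by at most +/-2 cc, so at
    least one criterion is violated with margin. Columns: ``id,
    baseline_cc, followup_cc, abs_diff_cc, pct_diff, he_true, pair_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= growth_fraction <= 1.0:
        raise ValueError("growth_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_growth = int(round(n * growth_fraction))
    is_growth = np.zeros(n, dtype=bool)
    is_growth[:n_growth] = True
    is_growth = rng.permutation(is_growth)

    rows = []
    for i in range(n):
        baseline = float(np.exp(rng.uniform(np.log(2.0), np.log(60.0))))
        if is_growth[i]:
            inc = max(8.0, 0.55 * baseline) * rng.uniform(1.0, 1.4)
            followup = baseline + inc
        else:
            followup = max(baseline + rng.uniform(-2.0, 2.0), 1.05)
        cmp = compare_serial(baseline, followup, criteria)
        assert cmp.he_positive == bool(is_growth[i])  # construction guarantee
        rows.append(
            {
                "id": f"pair{i:03d}",
                "baseline_cc": baseline,
                "followup_cc": followup,
                "abs_diff_cc": cmp.abs_diff_cc,
                "pct_diff": cmp.pct_diff,
                "he_true": cmp.he_positive,
                "pair_seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    return pd.DataFrame(rows)


def detect_cohort(
    cohort: pd.DataFrame,
    spec: PhantomSpec | None = None,
    masking: MaskingParams = MaskingParams(),
    detection: DetectionParams = DetectionParams(),
    criteria: ExpansionCriteria = ExpansionCriteria(),
) -> pd.DataFrame:
    """Run the full pipeline over a simulated cohort, pair by pair.

    For each row a serial phantom pair is generated (distractors enabled),
    both members pass through :func:`~hemovol.hyperdensity.detect_ich`,
    and the detected volumes are classified with the conjunction rule.
    Returns the cohort with ``detected_baseline_cc, detected_followup_cc,
    he_detected`` appended. Volumes are generated lazily so memory stays
    flat.
    """
    if spec is None:
        spec = PhantomSpec(falx_plate=True, sinus_blob=True)
    out_rows = []
    for row in cohort.itertuples(index=False):
        lesion = Lesion(
            center_mm=default_lesion_center(spec),
            semi_axes_mm=sphere_semi_axes(row.baseline_cc),
        )
        pair_spec = dataclasses.replace(spec, lesions=(lesion,))
        pair = generate_serial_pair(
            pair_spec, row.followup_cc, seed=int(row.pair_seed), criteria=criteria
        )
        rep_b = detect_ich(pair.baseline[0], masking, detection)
        rep_f = detect_ich(pair.followup[0], masking, detection)
        cmp = compare_serial(rep_b.total_volume_cc, rep_f.total_volume_cc, criteria)
        d = row._asdict()
        d.update(
            detected_baseline_cc=rep_b.total_volume_cc,
            detected_followup_cc=rep_f.total_volume_cc,
            he_detected=cmp.he_positive,
        )
        out_rows.append(d)
    return pd.DataFrame(out_rows)
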