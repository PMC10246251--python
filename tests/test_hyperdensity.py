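"""Median-relative thresholding, component labeling, screening, volumetry."""

import numpy as np
import pytest

import hemovol as hv
from hemovol.errors import EmptyMaskError
from hemovol.hyperdensity import REASON_DURAL, REASON_FLOOR, filter_false_positives

from _oracles import flood_fill_components


def _vol(voxels, spacing=(1.0, 1.0, 1.0)):
    return hv.CTVolume(np.asarray(voxels, dtype=float), spacing)


def _mask(voxels, spacing=(1.0, 1.0, 1.0)):
    return hv.SegmentationMask(np.asarray(voxels, dtype=bool), spacing)


class TestBrainMedian:
    def test_uniform_brain(self):
        vol = _vol(np.full((2, 4, 4), 35.0))
        assert hv.brain_median(vol, _mask(np.ones((2, 4, 4)))) == 35.0

    def test_even_count_ties_take_the_midpoint(self):
        vox = np.concatenate([np.full(8, 30.0), np.full(8, 40.0)]).reshape(1, 4, 4)
        assert hv.brain_median(_vol(vox), _mask(np.ones((1, 4, 4)))) == 35.0

    def test_noisy_phantom_median_near_nominal(self, noisy_25cc_phantom):
        _, vol, _ = noisy_25cc_phantom
        brain = hv.slice_range_filter(hv.intracranial_mask(vol))
        med = hv.brain_median(vol, brain)
        assert med == pytest.approx(35.0, abs=1.0)
        # oracle: direct median over the same voxels
        assert med == np.median(vol.voxels[brain.voxels])

    def test_empty_mask_rejected(self):
        vol = _vol(np.zeros((2, 2, 2)))
        with pytest.raises(EmptyMaskError):
            hv.brain_median(vol, _mask(np.zeros((2, 2, 2))))


class TestThresholdHyperdense:
    def test_strict_inequality_at_the_boundary(self):
        """With median 35 and offset 15, a 50 HU voxel is out, 51 HU is in."""
        vox = np.array([[[50.0, 51.0]]])
        mask = _mask(np.ones((1, 1, 2)))
        out = hv.threshold_hyperdense(_vol(vox), mask, 35.0)
        np.testing.assert_array_equal(out.voxels, [[[False, True]]])

    def test_huge_offset_selects_nothing(self, noisy_25cc_phantom):
        _, vol, _ = noisy_25cc_phantom
        brain = hv.intracranial_mask(vol)
        out = hv.threshold_hyperdense(
            vol, brain, 35.0, hv.DetectionParams(hu_offset=1e9)
        )
        assert out.voxel_count == 0

    def test_selected_count_non_increasing_in_offset(self, noisy_25cc_phantom):
        _, vol, _ = noisy_25cc_phantom
        brain = hv.intracranial_mask(vol)
        med = hv.brain_median(vol, brain)
        counts = [
            hv.threshold_hyperdense(vol, brain, med, hv.DetectionParams(hu_offset=o)).voxel_count
            for o in (10.0, 15.0, 20.0)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        vox = np.zeros((6, 6, 6), bool)
        vox[0:2, 0:2, 0:2] = True  # 8 voxels
        vox[4:6, 4:6, 4:6] = True
        labels, n = hv.label_components(_mask(vox))
        assert n == 2
        assert sorted(np.bincount(labels.ravel())[1:]) == [8, 8]

    def test_corner_contact_depends_on_connectivity(self):
        vox = np.zeros((2, 2, 2), bool)
        vox[0, 0, 0] = vox[1, 1, 1] = True
        assert hv.label_components(_mask(vox), connectivity=26)[1] == 1
        assert hv.label_components(_mask(vox), connectivity=6)[1] == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_flood_fill_on_random_masks(self, connectivity):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            vox = rng.random((9, 11, 10)) < 0.08
            labels, n = hv.label_components(_mask(vox), connectivity)
            oracle = flood_fill_components(vox, connectivity)
            assert n == len(oracle)
            for comp in oracle:  # each oracle component carries one label
                got = {labels[idx] for idx in comp}
                assert len(got) == 1


class TestFilterFalsePositives:
    def _components(self, vox, zone_vox, params=hv.DetectionParams()):
        labels, n = hv.label_components(_mask(vox))
        spacing = (1.0, 1.0, 5.0)
        zone = hv.SegmentationMask(zone_vox, spacing)
        return filter_false_positives(labels, n, spacing, zone, params)

    def test_small_component_rejected_below_detection_floor(self):
        vox = np.zeros((4, 10, 10), bool)
        vox[1, 2:7, 2:6] = True  # 20 voxels x 5 mm3 = 0.1 cc < 1 cc
        comps = self._components(vox, np.zeros_like(vox))
        assert len(comps) == 1 and comps[0].rejected and comps[0].reason == REASON_FLOOR

    def test_large_parenchymal_component_kept(self):
        vox = np.zeros((6, 30, 30), bool)
        vox[1:5, 5:25, 5:25] = True  # 1600 voxels = 8 cc
        comps = self._components(vox, np.zeros_like(vox))
        assert not comps[0].rejected
        assert comps[0].volume_cc == pytest.approx(8.0)

    def test_component_mostly_in_zone_rejected_as_dural(self):
        vox = np.zeros((4, 20, 20), bool)
        vox[1:3, 2:18, 2:10] = True  # 256 voxels = 1.28 cc
        zone = np.zeros_like(vox)
        zone[1:3, 2:18, 2:7] = True  # 62.5% of the component
        comps = self._components(vox, zone)
        assert comps[0].rejected and comps[0].reason == REASON_DURAL

    def test_phantom_falx_component_rejected_as_dural(self, distractor_only_phantom):
        _, vol, _ = distractor_only_phantom
        report = hv.detect_ich(vol)
        assert any(c.reason == REASON_DURAL for c in report.components)


class TestVolumeCc:
    def test_voxel_count_times_spacing_product(self):
        vox = np.zeros((10, 40, 40), bool)
        vox.ravel()[:8000] = True
        assert hv.volume_cc(hv.SegmentationMask(vox, (0.5, 0.5, 5.0))) == pytest.approx(10.0)

    def test_empty_mask_is_zero(self):
        assert hv.volume_cc(_mask(np.zeros((2, 2, 2)))) == 0.0

    def test_voxelized_sphere_volume_near_analytic(self):
        spec = hv.PhantomSpec(
            noise_sigma=0.0,
            lesions=(hv.Lesion(center_mm=(55.0, 71.0, 96.0), semi_axes_mm=hv.sphere_semi_axes(20.0)),),
        )
        _, truth = hv.generate_phantom(spec)
        assert hv.volume_cc(truth.lesion_masks[0]) == pytest.approx(20.0, rel=0.05)


class TestDetectIch:
    def test_recovers_25cc_lesion_within_five_percent(self, noisy_25cc_phantom):
        _, vol, truth = noisy_25cc_phantom
        report = hv.detect_ich(vol)
        assert report.total_volume_cc == pytest.approx(truth.lesion_masks[0].volume_cc, rel=0.05)
        assert report.total_volume_cc == pytest.approx(25.0, rel=0.05)

    def test_total_equals_sum_of_kept_components(self, noisy_25cc_phantom):
        _, vol, _ = noisy_25cc_phantom
        report = hv.detect_ich(vol)
        kept = sum(c.volume_cc for c in report.components if not c.rejected)
        assert report.total_volume_cc == kept
        assert report.threshold_hu == report.brain_median_hu + report.params.hu_offset

    def test_lesion_free_phantom_detects_nothing(self, distractor_only_phantom):
        _, vol, _ = distractor_only_phantom
        assert hv.detect_ich(vol).total_volume_cc == 0.0

    def test_two_lesions_reported_as_two_kept_components(self):
        spec = hv.PhantomSpec(
            seed=9,
            lesions=(
                hv.Lesion(center_mm=(55.0, 60.0, 75.0), semi_axes_mm=hv.sphere_semi_axes(10.0)),
                hv.Lesion(center_mm=(55.0, 110.0, 115.0), semi_axes_mm=hv.sphere_semi_axes(3.0)),
            ),
        )
        vol, truth = hv.generate_phantom(spec)
        report = hv.detect_ich(vol)
        kept = [c for c in report.components if not c.rejected]
        assert len(kept) == 2
        assert report.total_volume_cc == pytest.approx(sum(truth.lesion_volumes_cc), rel=0.08)

    def test_detected_volume_monotone_in_offset_and_floor(self, noisy_25cc_phantom):
        _, vol, _ = noisy_25cc_phantom
        by_offset = [
            hv.detect_ich(vol, detection=hv.DetectionParams(hu_offset=o)).total_volume_cc
            for o in (10.0, 15.0, 20.0)
        ]
        assert by_offset[0] >= by_offset[1] >= by_offset[2]
        by_floor = [
            hv.detect_ich(vol, detection=hv.DetectionParams(min_component_cc=f)).total_volume_cc
            for f in (0.5, 1.0, 30.0)
        ]
        assert by_floor[0] >= by_floor[1] >= by_floor[2]

    def test_report_invariant_to_slice_order_on_disk(self, tmp_path, noiseless_5mm_phantom):
        """A superior->inferior NIfTI normalises on read to the same report."""
        import nibabel as nib

        _, vol, _ = noiseless_5mm_phantom
        data = np.transpose(vol.voxels, (2, 1, 0))[:, :, ::-1]
        affine = np.diag([1.0, 1.0, -5.0, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(tmp_path / "flip.nii.gz"))
        flipped = hv.read_ct(tmp_path / "flip.nii.gz")
        ref = hv.detect_ich(vol)
        out = hv.detect_ich(flipped)
        assert out.total_volume_cc == ref.total_volume_cc
        assert out.brain_median_hu == ref.brain_median_hu
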