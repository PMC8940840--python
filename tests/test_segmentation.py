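import numpy as np
import pytest

from psmatlp import (
    LabelMask,
    MaskRole,
    SegmentationConfig,
    SuvImage,
    build_threshold_map,
    lesion_stats,
    liver_reference_threshold,
    segment_whole_body,
    voxel_volume_ml,
)
from psmatlp.image_model import AlignmentError

from _oracles import brute_force_segment


def _mask(arr, role, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(voxels=arr.astype(np.int16), role=role, spacing=spacing)


class TestLiverReferenceThreshold:
    def test_uniform_reference(self):
        vox = np.full((4, 4, 4), 4.0)
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        voi = _mask(np.ones((4, 4, 4)), MaskRole.LIVER_REFERENCE_VOI)
        assert liver_reference_threshold(img, voi) == pytest.approx(6.0)

    def test_mean_of_mixed_reference(self):
        vox = np.zeros((1, 1, 2))
        vox[0, 0, 0], vox[0, 0, 1] = 2.0, 4.0
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        voi = _mask(np.ones((1, 1, 2)), MaskRole.LIVER_REFERENCE_VOI)
        assert liver_reference_threshold(img, voi) == pytest.approx(4.5)

    def test_empty_voi_is_an_error_not_a_fallback(self):
        img = SuvImage(voxels=np.ones((3, 3, 3)), spacing=(1, 1, 1))
        voi = _mask(np.zeros((3, 3, 3)), MaskRole.LIVER_REFERENCE_VOI)
        with pytest.raises(ValueError):
            liver_reference_threshold(img, voi)


class TestThresholdMap:
    def test_no_liver_mask_gives_constant_global_threshold(self):
        img = SuvImage(voxels=np.ones((3, 3, 3)), spacing=(1, 1, 1))
        thr = build_threshold_map(img)
        assert np.all(thr == 3.0)

    def test_liver_voxels_carry_liver_threshold(self):
        img = SuvImage(voxels=np.ones((3, 3, 3)), spacing=(1, 1, 1))
        liver = np.zeros((3, 3, 3))
        liver[0] = 1
        thr = build_threshold_map(img, _mask(liver, MaskRole.LIVER), liver_threshold=6.0)
        assert np.all(thr[0] == 6.0) and np.all(thr[1:] == 3.0)

    def test_shape_mismatch_raises(self):
        img = SuvImage(voxels=np.ones((3, 3, 3)), spacing=(1, 1, 1))
        with pytest.raises(AlignmentError):
            build_threshold_map(img, _mask(np.zeros((2, 2, 2)), MaskRole.LIVER), 6.0)


class TestSegmentWholeBody:
    def test_noiseless_sphere_blob(self, sphere_image):
        """A uniform SUV-8 ball of radius 4 voxels holds the 257 lattice
        points of the radius-4 ball; volume = 257 x 0.008 mL."""
        result = segment_whole_body(sphere_image)
        assert len(result) == 1
        lesion = result.lesions[0]
        assert lesion.voxel_count == 257
        assert lesion.volume_ml == pytest.approx(2.056)
        assert lesion.suv_mean == pytest.approx(8.0)
        assert lesion.suv_max == pytest.approx(8.0)

    def test_blob_inside_exclusion_mask_yields_empty_set(self, sphere_image):
        excl = _mask(np.ones(sphere_image.shape), MaskRole.EXCLUSION, spacing=(2, 2, 2))
        result = segment_whole_body(sphere_image, exclusion_mask=excl)
        assert len(result) == 0

    def test_corner_touching_blobs_split_by_connectivity(self):
        vox = np.zeros((6, 6, 6))
        vox[1:3, 1:3, 1:3] = 8.0
        vox[3:5, 3:5, 3:5] = 8.0  # touches the first only at the (3,3,3) corner
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        assert len(segment_whole_body(img, config=SegmentationConfig(connectivity=26))) == 1
        assert len(segment_whole_body(img, config=SegmentationConfig(connectivity=6))) == 2

    def test_min_lesion_volume_filters_small_components(self):
        vox = np.zeros((8, 8, 8))
        vox[1, 1, 1] = 5.0  # single voxel, 0.001 mL
        vox[4:6, 4:6, 4:6] = 5.0  # 8 voxels, 0.008 mL
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        result = segment_whole_body(img, config=SegmentationConfig(min_lesion_volume_ml=0.002))
        assert len(result) == 1 and result.lesions[0].voxel_count == 8

    def test_liver_mask_without_reference_voi_raises(self, sphere_image):
        liver = _mask(np.ones(sphere_image.shape), MaskRole.LIVER, spacing=(2, 2, 2))
        with pytest.raises(ValueError):
            segment_whole_body(sphere_image, liver_mask=liver)

    def test_segmented_voxels_respect_threshold_and_exclusion(self):
        rng = np.random.default_rng(5)
        vox = rng.uniform(0, 6, (12, 12, 12))
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        excl = _mask((rng.random((12, 12, 12)) < 0.2), MaskRole.EXCLUSION)
        result = segment_whole_body(img, exclusion_mask=excl)
        # every candidate voxel (>= threshold, outside exclusion) is claimed
        # by exactly one lesion and nothing else is
        total = sum(l.voxel_count for l in result)
        candidates = (vox >= 3.0) & ~excl.as_bool()
        assert total == int(candidates.sum())
        for lesion in result:
            assert lesion.suv_mean >= 3.0 and lesion.suv_max >= 3.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(6)
        vox = rng.uniform(0, 8, (10, 10, 10))
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        counts = []
        for thr in (2.0, 3.0, 4.0, 5.0):
            res = segment_whole_body(img, config=SegmentationConfig(global_threshold_suv=thr))
            counts.append(sum(l.voxel_count for l in res))
        assert counts == sorted(counts, reverse=True)

    def test_lesion_ids_ordered_by_descending_volume(self):
        vox = np.zeros((10, 10, 10))
        vox[1, 1, 1] = 9.0
        vox[5:8, 5:8, 5:8] = 4.0
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        res = segment_whole_body(img)
        assert [l.lesion_id for l in res] == [1, 2]
        assert res.lesions[0].voxel_count > res.lesions[1].voxel_count


class TestLesionStats:
    def test_mean_and_max(self):
        vox = np.zeros((2, 2, 2))
        vox[0, 0, 0], vox[0, 0, 1] = 3.0, 5.0
        img = SuvImage(voxels=vox, spacing=(1, 1, 1))
        lesion = lesion_stats(img, np.array([[0, 0, 0], [0, 0, 1]]))
        assert lesion.suv_mean == pytest.approx(4.0)
        assert lesion.suv_max == pytest.approx(5.0)

    def test_single_voxel_volume(self):
        img = SuvImage(voxels=np.full((2, 2, 2), 7.0), spacing=(1, 1, 1))
        lesion = lesion_stats(img, np.array([[0, 0, 0]]))
        assert lesion.volume_ml == pytest.approx(0.001)
        assert lesion.voxel_count == 1

    def test_empty_set_raises(self):
        img = SuvImage(voxels=np.ones((2, 2, 2)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            lesion_stats(img, np.empty((0, 3)))


@pytest.mark.parametrize("seed", range(8))
def test_matches_brute_force_oracle_on_random_grids(seed):
    """Voxel-exact equivalence with an exhaustive scan + BFS flood fill on
    random grids with random thresholds, exclusion and liver masks."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(5, 15, size=3))
    vox = rng.uniform(0, 8, shape)
    spacing = tuple(rng.uniform(0.5, 4.0, size=3))
    img = SuvImage(voxels=vox, spacing=spacing)
    connectivity = int(rng.choice([6, 18, 26]))
    threshold = float(rng.uniform(1.0, 6.0))
    config = SegmentationConfig(global_threshold_suv=threshold, connectivity=connectivity)

    excl = _mask((rng.random(shape) < 0.15), MaskRole.EXCLUSION, spacing=spacing)
    liver = (rng.random(shape) < 0.2)
    voi = liver & (rng.random(shape) < 0.5)
    kwargs = {"exclusion_mask": excl}
    thr_map = np.full(shape, threshold)
    if voi.any():
        liver_mask = _mask(liver, MaskRole.LIVER, spacing=spacing)
        voi_mask = _mask(voi, MaskRole.LIVER_REFERENCE_VOI, spacing=spacing)
        kwargs |= {"liver_mask": liver_mask, "liver_ref_voi": voi_mask}
        thr_map[liver] = config.liver_factor * vox[voi].mean()

    result = segment_whole_body(img, config=config, **kwargs)
    expected = brute_force_segment(
        vox, thr_map, excl.as_bool(), connectivity, voxel_volume_ml(img)
    )

    assert len(result) == len(expected)
    for got, want in zip(result.lesions, expected):
        assert got.voxel_count == want["voxel_count"]
        assert got.volume_ml == pytest.approx(want["volume_ml"])
        assert got.suv_mean == pytest.approx(want["suv_mean"])
        assert got.suv_max == pytest.approx(want["suv_max"])
        assert got.centroid == pytest.approx(want["centroid"])
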