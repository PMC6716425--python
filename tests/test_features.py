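"""Feature extraction: subdivision, statistics, SOR, the 90-feature schema."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdstriatum.core import OCCIPITAL, SAR_LABELS, ImageVolume, LabelMap
from pdstriatum.features import (
    extract_features,
    feature_names,
    features_to_frame,
    region_statistics,
    region_volume,
    sor,
    subdivide_region,
)
from pdstriatum.phantom import PhantomConfig, generate_subject
from pdstriatum.registration import propagate_labels

RNG = np.random.default_rng(5)


def make_labels(data, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(data, dtype=np.int32), spacing, (0.0, 0.0, 0.0))


def make_image(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing, (0.0, 0.0, 0.0), "PET")


class TestFeatureNames:
    def test_exactly_90_unique_names(self):
        names = feature_names()
        assert len(names) == 90
        assert len(set(names)) == 90

    def test_schema_decomposition(self):
        names = feature_names()
        sor_feats = [n for n in names if n.endswith("_sor")]
        vol_feats = [n for n in names if n.endswith("_volume")]
        assert len(sor_feats) == 84 and len(vol_feats) == 6
        # 14 regions x 6 statistics
        regions = {n.rsplit("_", 2)[0] for n in sor_feats}
        assert len(regions) == 14


class TestSubdivideRegion:
    def test_three_separated_blobs_recovered_exactly(self):
        """Three compact blobs far apart: k-means must return exactly the
        blob partition (verified against blob membership)."""
        data = np.zeros((30, 10, 10), dtype=np.int32)
        blobs = [(2, 5), (14, 17), (26, 29)]
        for lo, hi in blobs:
            data[lo:hi, 4:7, 4:7] = 1
        part = subdivide_region(make_labels(data), region_id=1, k=3, seed=0)
        for lo, hi in blobs:
            blob_vox = np.argwhere((np.arange(30)[:, None, None] >= lo)
                                   & (np.arange(30)[:, None, None] < hi) & (data == 1))
            assigned = set()
            vox_set = {tuple(v) for v in blob_vox}
            for sub in (1, 2, 3):
                sub_vox = {tuple(v) for v in part.voxels_of(sub)}
                if vox_set & sub_vox:
                    assigned.add(sub)
                    assert vox_set <= sub_vox or sub_vox <= vox_set
            assert len(assigned) == 1

    def test_partition_covers_region(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data[2:8, 2:8, 2:8] = 1
        part = subdivide_region(make_labels(data), 1, k=3, seed=1)
        union = np.vstack([part.voxels_of(s) for s in (1, 2, 3)])
        assert len(union) == (data == 1).sum()
        assert len({tuple(v) for v in union}) == len(union)

    def test_deterministic_for_fixed_seed(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data[1:9, 1:9, 1:9] = 1
        a = subdivide_region(make_labels(data), 1, seed=4)
        b = subdivide_region(make_labels(data), 1, seed=4)
        assert np.array_equal(a.assignment, b.assignment)

    def test_anterior_first_centroid_order(self):
        data = np.zeros((6, 30, 6), dtype=np.int32)
        data[2:5, 2:28, 2:5] = 1
        part = subdivide_region(make_labels(data), 1, k=3, seed=0)
        ys = part.centroids[:, 1]
        assert ys[0] > ys[1] > ys[2]   # index 1 (row 0) most anterior (+y)

    def test_too_few_voxels_rejected(self):
        data = np.zeros((5, 5, 5), dtype=np.int32)
        data[0, 0, :2] = 1
        with pytest.raises(ValueError, match="voxels"):
            subdivide_region(make_labels(data), 1, k=3)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subdivide_region(make_labels(np.zeros((4, 4, 4))), 1)


class TestRegionStatistics:
    def test_hand_computed_example(self):
        img = make_image(np.arange(64, dtype=float).reshape(4, 4, 4))
        img.data[0, 0, :4] = [1, 2, 3, 4]
        vox = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3]])
        s = region_statistics(img, vox)
        assert s == {"max": 4, "min": 1, "median": 2.5,
                     "q1": 1.75, "q3": 3.25, "mean": 2.5}

    def test_constant_region_all_stats_equal(self):
        img = make_image(np.full((4, 4, 4), 7.5))
        vox = np.argwhere(np.ones((4, 4, 4), dtype=bool))
        assert set(region_statistics(img, vox).values()) == {7.5}

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_quantile_ordering(self, values):
        img = make_image(np.zeros((1, 1, len(values))))
        img.data[0, 0, :] = values
        vox = np.array([[0, 0, i] for i in range(len(values))])
        s = region_statistics(img, vox)
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            region_statistics(make_image(np.zeros((2, 2, 2))), np.empty((0, 3), dtype=int))


class TestSor:
    def test_direct_substitution(self):
        assert sor(2.0, 1.0) == pytest.approx(1.0)

    def test_equal_uptake_is_zero(self):
        assert sor(3.3, 3.3) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.01, 50))
    def test_global_scaling_invariance(self, region, occ, lam):
        assert sor(lam * region, lam * occ) == pytest.approx(sor(region, occ), rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            sor(1.0, 0.0)


class TestRegionVolume:
    def test_count_times_voxel_volume(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data.flat[:100] = 1
        assert region_volume(make_labels(data), 1) == pytest.approx(100.0)

    def test_anisotropic_spacing(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 1
        assert region_volume(make_labels(data, spacing=(1.0, 2.0, 3.0)), 1) == 6.0

    def test_absent_region_warns_zero(self):
        with pytest.warns(UserWarning, match="absent"):
            v = region_volume(make_labels(np.zeros((3, 3, 3))), 5)
        assert v == 0.0


@pytest.fixture(scope="module")
def extraction_inputs():
    cfg = PhantomConfig(noise_sd=0.0, geometry_jitter_sd=0.0)
    subj = generate_subject(cfg, "NL", "features")
    pet_labels = propagate_labels(subj.labels_mr_space, subj.true_transform, subj.pet)
    return subj, pet_labels, cfg


class TestExtractFeatures:
    def test_vector_length_is_90(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        fv = extract_features(subj.pet, pet_labels, subj.labels_mr_space, seed=0)
        assert len(fv.values) == 90
        assert fv.names == feature_names()

    def test_constant_pet_gives_zero_sor(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        flat = ImageVolume(np.full(subj.pet.shape, 2.0), subj.pet.spacing,
                           subj.pet.origin, "PET")
        fv = extract_features(flat, pet_labels, subj.labels_mr_space, seed=0)
        sor_vals = fv.values[:84]
        np.testing.assert_allclose(sor_vals, 0.0, atol=1e-12)

    def test_scaling_invariance_of_sor_and_volumes(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        fv = extract_features(subj.pet, pet_labels, subj.labels_mr_space, seed=0)
        scaled = ImageVolume(subj.pet.data * 3.7, subj.pet.spacing,
                             subj.pet.origin, "PET")
        fv2 = extract_features(scaled, pet_labels, subj.labels_mr_space, seed=0)
        np.testing.assert_allclose(fv2.values, fv.values, rtol=1e-9)

    def test_noise_free_whole_putamen_mean_sor_exact(self, extraction_inputs):
        """Configured uptake 3.0 vs occipital 1.0 -> mean-SOR = 2 exactly;
        check through the whole pipeline path (subregions partition the
        putamen, so their mean-SORs are all exactly 2 as well)."""
        subj, pet_labels, cfg = extraction_inputs
        fv = extract_features(subj.pet, pet_labels, subj.labels_mr_space, seed=0)
        vals = fv.as_series()
        for region in ("r_putamen", "l_putamen"):
            for sub in (1, 2, 3):
                assert vals[f"{region}_sub{sub}_mean_sor"] == pytest.approx(2.0, abs=1e-12)

    def test_subregion_correspondence_across_subjects(self):
        cfg = PhantomConfig(noise_sd=0.0, geometry_jitter_sd=0.0)
        parts = []
        for sid in ("a", "b"):
            subj = generate_subject(cfg, "NL", sid)
            pet_labels = propagate_labels(subj.labels_mr_space, subj.true_transform,
                                          subj.pet)
            parts.append(subdivide_region(pet_labels, SAR_LABELS["r_putamen"], seed=0))
        for part in parts:
            assert part.centroids[2, 1] == min(part.centroids[:, 1])  # sub3 most posterior

    def test_missing_occipital_rejected(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        stripped = LabelMap(np.where(pet_labels.data == OCCIPITAL, 0, pet_labels.data),
                            pet_labels.spacing, pet_labels.origin)
        with pytest.raises(ValueError, match="occipital"):
            extract_features(subj.pet, stripped, subj.labels_mr_space, seed=0)

    def test_empty_sar_lists_regions(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        stripped = LabelMap(
            np.where(pet_labels.data == SAR_LABELS["l_pallidum"], 0, pet_labels.data),
            pet_labels.spacing, pet_labels.origin)
        with pytest.raises(ValueError, match="l_pallidum"):
            extract_features(subj.pet, stripped, subj.labels_mr_space, seed=0)

    def test_frame_round_trip(self, extraction_inputs):
        subj, pet_labels, _ = extraction_inputs
        fv = extract_features(subj.pet, pet_labels, subj.labels_mr_space, seed=0)
        fv.subject_id, fv.group = "s1", "NL"
        frame = features_to_frame([fv])
        assert frame.shape == (1, 92)
        assert list(frame.columns[:2]) == ["id", "group"]
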