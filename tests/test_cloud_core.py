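"""Point-cloud model, PLY round trips, ROI filtering, augmentation, labels."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from phenopoint.cloud_core import (AugmentationScheme, LabelScheme,
                                   PLYParseError, PointCloud, ROIFilterConfig,
                                   augment, collapse_labels,
                                   coordinate_inversion, read_ply, roi_filter,
                                   train_test_split_plants, write_ply)


class TestPointCloud:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PointCloud(np.zeros((3, 3)), np.zeros((2, 3)))

    def test_color_range_enforced(self):
        with pytest.raises(ValueError):
            PointCloud(np.zeros((1, 3)), [[0, 300, 0]])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError):
            PointCloud([[0, 0, np.nan]], [[0, 0, 0]])


class TestPlyIO:
    def test_ascii_three_points(self, tmp_path):
        p = tmp_path / "tiny.ply"
        p.write_text(
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "end_header\n"
            "1.5 2.5 3.5 10 20 30\n0 0 0 0 0 0\n-1 -2 -3 255 255 255\n")
        cloud = read_ply(p)
        assert len(cloud) == 3
        np.testing.assert_array_equal(
            cloud.coords, [[1.5, 2.5, 3.5], [0, 0, 0], [-1, -2, -3]])
        np.testing.assert_array_equal(cloud.colors[0], [10, 20, 30])
        assert not cloud.has_labels

    @pytest.mark.parametrize("fmt", ["ascii", "binary_le"])
    def test_round_trip(self, fmt, labeled_cloud, tmp_path):
        path = tmp_path / f"rt_{fmt}.ply"
        write_ply(labeled_cloud, path, format=fmt)
        back = read_ply(path)
        if fmt == "binary_le":
            np.testing.assert_array_equal(back.coords, labeled_cloud.coords)
        else:
            np.testing.assert_allclose(back.coords, labeled_cloud.coords,
                                       atol=1e-6)
        np.testing.assert_array_equal(back.colors, labeled_cloud.colors)
        np.testing.assert_array_equal(back.labels, labeled_cloud.labels)

    def test_large_binary_round_trip_bit_exact(self, rng, tmp_path):
        cloud = PointCloud(rng.normal(0, 500, (100_000, 3)),
                           rng.integers(0, 256, (100_000, 3)))
        path = tmp_path / "big.ply"
        write_ply(cloud, path)
        back = read_ply(path)
        np.testing.assert_array_equal(back.coords, cloud.coords)

    def test_empty_cloud_round_trip(self, tmp_path):
        cloud = PointCloud(np.empty((0, 3)), np.empty((0, 3)))
        path = tmp_path / "empty.ply"
        write_ply(cloud, path, format="ascii")
        assert len(read_ply(path)) == 0

    def test_missing_color_property_rejected(self, tmp_path):
        p = tmp_path / "nogreen.ply"
        p.write_text(
            "ply\nformat ascii 1.0\nelement vertex 1\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar blue\n"
            "end_header\n0 0 0 1 2\n")
        with pytest.raises(PLYParseError, match="green"):
            read_ply(p)

    def test_truncated_body_names_position(self, labeled_cloud, tmp_path):
        path = tmp_path / "trunc.ply"
        write_ply(labeled_cloud, path)
        data = path.read_bytes()
        path.write_bytes(data[:-40])
        with pytest.raises(PLYParseError, match="truncated"):
            read_ply(path)

    def test_not_a_ply(self, tmp_path):
        p = tmp_path / "junk.ply"
        p.write_text("OFF\n0 0 0\n")
        with pytest.raises(PLYParseError):
            read_ply(p)


class TestRoiFilter:
    def test_all_inside_is_identity(self, small_cloud):
        cfg = ROIFilterConfig(x=(-1000, 1000), y=(-1000, 1000), z=(-1000, 1000))
        out = roi_filter(small_cloud, cfg)
        np.testing.assert_array_equal(out.coords, small_cloud.coords)

    def test_interval_selection(self):
        cloud = PointCloud([[0, 0, 100], [0, 0, 400], [0, 0, 900]],
                           np.zeros((3, 3)))
        out = roi_filter(cloud, ROIFilterConfig(z=(350, 450)))
        np.testing.assert_array_equal(out.coords, [[0, 0, 400]])

    def test_bounds_are_closed(self):
        cloud = PointCloud([[350, 0, 0], [450, 0, 0], [449.999, 0, 0]],
                           np.zeros((3, 3)))
        out = roi_filter(cloud, ROIFilterConfig(x=(350, 450)))
        assert len(out) == 3

    def test_idempotent(self, small_cloud):
        cfg = ROIFilterConfig(x=(-50, 50), z=(0, 100))
        once = roi_filter(small_cloud, cfg)
        twice = roi_filter(once, cfg)
        np.testing.assert_array_equal(once.coords, twice.coords)

    def test_labels_carried(self, labeled_cloud):
        cfg = ROIFilterConfig(y=(50, 150))
        out = roi_filter(labeled_cloud, cfg)
        mask = ((labeled_cloud.coords[:, 1] >= 50)
                & (labeled_cloud.coords[:, 1] <= 150))
        np.testing.assert_array_equal(out.labels, labeled_cloud.labels[mask])

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            ROIFilterConfig(x=(10, -10))


class TestAugment:
    def test_default_scheme_emits_16(self, small_cloud):
        variants = augment(small_cloud)
        assert len(variants) == 16

    def test_first_variant_is_input(self, small_cloud):
        variants = augment(small_cloud)
        np.testing.assert_allclose(variants[0].coords, small_cloud.coords,
                                   atol=1e-12)

    def test_variants_preserve_metric_structure(self, small_cloud):
        base = pdist(small_cloud.coords)
        for v in augment(small_cloud):
            np.testing.assert_allclose(pdist(v.coords), base, atol=1e-9)

    def test_full_turn_is_identity(self, small_cloud):
        scheme = AugmentationScheme(rotation_angles_deg=(360.0,), mirror=False)
        out = augment(small_cloud, scheme)[0]
        np.testing.assert_allclose(out.coords, small_cloud.coords, atol=1e-9)

    def test_mirror_is_involution(self, small_cloud):
        scheme = AugmentationScheme(rotation_angles_deg=(0.0,), mirror=True)
        mirrored = augment(small_cloud, scheme)[1]
        back = augment(mirrored, scheme)[1]
        np.testing.assert_allclose(back.coords, small_cloud.coords, atol=1e-9)

    def test_labels_and_counts_preserved(self, labeled_cloud):
        for v in augment(labeled_cloud):
            assert len(v) == len(labeled_cloud)
            np.testing.assert_array_equal(v.labels, labeled_cloud.labels)

    def test_empty_angle_list_rejected(self, small_cloud):
        with pytest.raises(ValueError):
            augment(small_cloud, AugmentationScheme(rotation_angles_deg=()))


class TestInversionAndLabels:
    def test_inversion_negates(self):
        cloud = PointCloud([[1, 2, 3]], [[9, 9, 9]])
        out = coordinate_inversion(cloud)
        np.testing.assert_array_equal(out.coords, [[-1, -2, -3]])
        np.testing.assert_array_equal(out.colors, cloud.colors)

    def test_inversion_involution_and_linearity(self, small_cloud):
        twice = coordinate_inversion(coordinate_inversion(small_cloud))
        np.testing.assert_array_equal(twice.coords, small_cloud.coords)
        inv = coordinate_inversion(small_cloud)
        np.testing.assert_allclose(inv.centroid(), -small_cloud.centroid())

    def test_collapse_maps_instances_to_leaf(self):
        cloud = PointCloud(np.zeros((5, 3)), np.zeros((5, 3)),
                           [0, 1, 2, 3, 7])
        out = collapse_labels(cloud)
        np.testing.assert_array_equal(out.labels, [0, 1, 2, 2, 2])

    def test_collapse_idempotent_on_semantic(self):
        cloud = PointCloud(np.zeros((3, 3)), np.zeros((3, 3)), [0, 1, 2])
        out = collapse_labels(collapse_labels(cloud))
        np.testing.assert_array_equal(out.labels, [0, 1, 2])

    def test_unlabeled_points_rejected(self):
        cloud = PointCloud(np.zeros((2, 3)), np.zeros((2, 3)), [-1, -1])
        with pytest.raises(ValueError):
            collapse_labels(cloud)

    def test_label_scheme_rejects_invalid(self):
        with pytest.raises(ValueError):
            LabelScheme().collapse(-3)


class TestSplit:
    @pytest.mark.parametrize("n,expected_train", [(97, 68), (10, 7), (100, 70)])
    def test_seven_three_rounding(self, n, expected_train):
        train, test = train_test_split_plants(n)
        assert len(train) == expected_train
        assert len(train) + len(test) == n

    def test_seeded_shuffle_partitions(self):
        train, test = train_test_split_plants(97, seed=3)
        assert sorted(np.concatenate([train, test])) == list(range(97))


class TestConfigFile:
    def test_defaults_from_empty_file(self, tmp_path):
        from phenopoint.cloud_core import load_config
        p = tmp_path / "cfg.yaml"
        p.write_text("")
        cfg = load_config(p)
        assert cfg["roi"].intervals == (None, None, None)
        assert cfg["augmentation"].n_variants() == 16

    def test_overrides_and_extras(self, tmp_path):
        from phenopoint.cloud_core import load_config
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "roi_z: [350, 450]\nroi_y: [500, 650]\nmirror: false\n"
            "rotation_angles_deg: [0, 90, 180, 270]\nvoxel_size: 1.5\n")
        cfg = load_config(p)
        assert cfg["roi"].z == (350.0, 450.0)
        assert cfg["roi"].y == (500.0, 650.0)
        assert cfg["augmentation"].n_variants() == 4
        assert cfg["extra"] == {"voxel_size": 1.5}


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4),
                          st.floats(-1e4, 1e4)), min_size=1, max_size=40),
       st.tuples(st.floats(-100, 100), st.floats(0, 200)))
def test_roi_filter_idempotent_and_subset(points, interval):
    """Filtering twice equals filtering once, and the result is a subset."""
    lo, span = interval
    cloud = PointCloud(np.array(points), np.zeros((len(points), 3)))
    cfg = ROIFilterConfig(x=(lo, lo + span))
    once = roi_filter(cloud, cfg)
    twice = roi_filter(once, cfg)
    np.testing.assert_array_equal(once.coords, twice.coords)
    assert len(once) <= len(cloud)
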