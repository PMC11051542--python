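import numpy as np
import pytest
from scipy import ndimage

from meglabel.atlas import (
    Atlas,
    lookup,
    nearest_labeled,
    query_all,
    read_atlas_manifest,
    reverse_normalize_atlas,
    skull_outline,
)
from meglabel.formats import LookupTable
from meglabel.geometry import Frame, FrameTransform, Volume, invert
from meglabel.synthetic import affine_from_params


def _atlas(values, space="native", entries=None, voxel=1.0, name="toy"):
    values = np.asarray(values, dtype=np.int32)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    frame = Frame.WORLD if space == "native" else Frame.TEMPLATE
    if entries is None:
        entries = {int(c): f"region_{int(c)}" for c in np.unique(values) if c > 0}
    return Atlas(
        name=name,
        labels=Volume(values, FrameTransform(affine, Frame.VOXEL, frame), role="label"),
        lookup=LookupTable(name, entries),
        space=space,
    )


class TestLookup:
    def test_printed_aal_entry_labels_voxel(self):
        values = np.zeros((4, 4, 4), np.int32)
        values[1, 2, 3] = 85
        atlas = _atlas(values, entries={85: "Temporal_Mid_L"}, name="AAL_MNI_V4")
        res = lookup(atlas, (1, 2, 3))
        assert res.status == "labeled"
        assert res.code == 85
        assert res.label == "Temporal_Mid_L"

    def test_zero_code_is_unlabeled(self):
        atlas = _atlas(np.zeros((4, 4, 4), np.int32), entries={1: "a"})
        res = lookup(atlas, (0, 0, 0))
        assert res.status == "unlabeled" and res.code == 0 and res.label == ""

    def test_negative_index_is_out_of_fov(self):
        atlas = _atlas(np.ones((4, 4, 4), np.int32))
        assert lookup(atlas, (-1, 0, 0)).status == "out_of_fov"
        assert lookup(atlas, (0, 0, 4)).status == "out_of_fov"

    def test_code_without_lookup_entry_is_unlabeled(self):
        values = np.zeros((4, 4, 4), np.int32)
        values[0, 0, 0] = 9
        with pytest.warns(UserWarning, match="no lookup entry"):
            atlas = _atlas(values, entries={1: "a"})
        assert lookup(atlas, (0, 0, 0)).status == "unlabeled"

    def test_pure_function_repeatable(self):
        values = np.zeros((4, 4, 4), np.int32)
        values[2, 2, 2] = 3
        atlas = _atlas(values)
        assert lookup(atlas, (2, 2, 2)) == lookup(atlas, (2, 2, 2))

    def test_requires_native_space(self):
        atlas = _atlas(np.ones((4, 4, 4), np.int32), space="template")
        with pytest.raises(ValueError, match="native"):
            lookup(atlas, (0, 0, 0))


class TestNearestLabeled:
    def test_labeled_voxel_returns_itself_distance_zero(self):
        values = np.zeros((8, 8, 8), np.int32)
        values[4, 4, 4] = 2
        atlas = _atlas(values)
        res = nearest_labeled(atlas, (4, 4, 4), max_radius_mm=5)
        assert res.status == "labeled" and res.distance_mm == 0.0

    def test_single_voxel_three_mm_away(self):
        values = np.zeros((8, 8, 8), np.int32)
        values[4, 4, 7] = 5
        atlas = _atlas(values)  # 1 mm grid
        res = nearest_labeled(atlas, (4, 4, 4), max_radius_mm=5)
        assert res.status == "labeled"
        assert res.label == "region_5"
        assert res.distance_mm == pytest.approx(3.0)

    def test_outside_radius_not_found(self):
        values = np.zeros((8, 8, 8), np.int32)
        values[4, 4, 7] = 5
        atlas = _atlas(values)
        assert nearest_labeled(atlas, (4, 4, 4), max_radius_mm=2).status == "not_found"

    def test_radius_zero_equals_lookup_semantics(self):
        values = np.zeros((6, 6, 6), np.int32)
        values[1, 1, 1] = 4
        atlas = _atlas(values)
        assert nearest_labeled(atlas, (1, 1, 1), 0.0).status == "labeled"
        assert nearest_labeled(atlas, (2, 2, 2), 0.0).status == "not_found"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        values = np.zeros((12, 12, 12), np.int32)
        spots = rng.choice(12**3, size=30, replace=False)
        values.ravel()[spots] = rng.integers(1, 5, size=30)
        atlas = _atlas(values, voxel=1.5)
        labeled = np.argwhere(values > 0)
        world = atlas.labels.voxel_to_world.apply(labeled.astype(float))
        for _ in range(50):
            q = rng.integers(0, 12, size=3)
            res = nearest_labeled(atlas, q, max_radius_mm=8.0)
            qw = atlas.labels.voxel_to_world.apply(q.astype(float))
            dists = np.linalg.norm(world - qw, axis=1)
            if values[tuple(q)] > 0:
                assert res.distance_mm == 0.0
                continue
            in_radius = dists <= 8.0
            if not in_radius.any():
                assert res.status == "not_found"
            else:
                assert res.status == "labeled"
                assert res.distance_mm == pytest.approx(dists[in_radius].min())

    def test_tie_broken_by_smaller_code(self):
        values = np.zeros((7, 7, 7), np.int32)
        values[3, 3, 1] = 9  # both 2 mm away on a symmetric 1 mm grid
        values[3, 3, 5] = 2
        atlas = _atlas(values)
        res = nearest_labeled(atlas, (3, 3, 3), max_radius_mm=4)
        assert res.code == 2


class TestReverseNormalize:
    def test_identity_matching_grids_unchanged(self):
        rng = np.random.default_rng(5)
        values = rng.integers(0, 4, size=(10, 10, 10))
        atlas = _atlas(values, space="template")
        native = Volume(
            np.zeros((10, 10, 10)),
            FrameTransform(np.eye(4), Frame.VOXEL, Frame.WORLD),
        )
        norm = FrameTransform(np.eye(4), Frame.WORLD, Frame.TEMPLATE)
        out = reverse_normalize_atlas(atlas, native, norm)
        assert out.space == "native"
        np.testing.assert_array_equal(out.labels.values, values)
        assert out.lookup.entries == atlas.lookup.entries

    def test_code_conservation_under_any_normalization(self):
        rng = np.random.default_rng(6)
        atlas = _atlas(rng.integers(0, 5, size=(12, 12, 12)), space="template")
        native = Volume(
            np.zeros((12, 12, 12)),
            FrameTransform(np.eye(4), Frame.VOXEL, Frame.WORLD),
        )
        norm = FrameTransform(
            affine_from_params((3.0, -2.0, 1.0), (5.0, -4.0, 8.0), (1.05, 0.95, 1.0)),
            Frame.WORLD, Frame.TEMPLATE,
        )
        out = reverse_normalize_atlas(atlas, native, norm)
        assert set(np.unique(out.labels.values)) <= set(np.unique(atlas.labels.values)) | {0}

    def test_already_native_rejected(self):
        atlas = _atlas(np.ones((4, 4, 4), np.int32), space="native")
        native = Volume(np.zeros((4, 4, 4)), FrameTransform(np.eye(4), Frame.VOXEL, Frame.WORLD))
        with pytest.raises(ValueError, match="already in native"):
            reverse_normalize_atlas(atlas, native, FrameTransform(np.eye(4), Frame.WORLD, Frame.TEMPLATE))

    def test_region_centroids_map_through_known_affine(self):
        # 3 compact regions; centroids must land within one voxel of the
        # analytically transformed centroids
        values = np.zeros((20, 20, 20), np.int32)
        values[3:6, 3:6, 3:6] = 1
        values[12:15, 4:7, 5:8] = 2
        values[8:11, 13:16, 12:15] = 3
        affine_t = np.eye(4)
        affine_t[:3, 3] = -10.0
        atlas = Atlas(
            "toy3",
            Volume(values, FrameTransform(affine_t, Frame.VOXEL, Frame.TEMPLATE), role="label"),
            LookupTable("toy3", {1: "a", 2: "b", 3: "c"}),
            space="template",
        )
        norm = FrameTransform(
            affine_from_params((2.0, -1.0, 1.5), (0, 0, 6.0)), Frame.WORLD, Frame.TEMPLATE
        )
        affine_n = np.eye(4)
        affine_n[:3, 3] = -10.0
        native = Volume(np.zeros((20, 20, 20)), FrameTransform(affine_n, Frame.VOXEL, Frame.WORLD))
        out = reverse_normalize_atlas(atlas, native, norm)
        inv_norm = invert(norm)
        for code in (1, 2, 3):
            src_centroid_world = atlas.labels.voxel_to_world.apply(
                np.argwhere(values == code).mean(axis=0)
            )
            expected_world = inv_norm.apply(src_centroid_world)
            got_vox = np.argwhere(out.labels.values == code).mean(axis=0)
            got_world = out.labels.voxel_to_world.apply(got_vox)
            assert np.linalg.norm(got_world - expected_world) < 1.0  # 1 voxel = 1 mm


class TestSkullOutline:
    def _ball(self, radius=10, shape=(32, 32, 32)):
        affine = np.eye(4)
        affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
        idx = np.indices(shape, dtype=float)
        pts = np.moveaxis(idx, 0, -1) + affine[:3, 3]
        mask = (np.linalg.norm(pts, axis=-1) <= radius).astype(np.uint8)
        return Volume(mask, FrameTransform(affine, Frame.VOXEL, Frame.TEMPLATE), role="mask")

    def _native(self, shape=(32, 32, 32)):
        affine = np.eye(4)
        affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0
        return Volume(np.zeros(shape), FrameTransform(affine, Frame.VOXEL, Frame.WORLD))

    def test_ball_becomes_hollow_shell(self):
        mask = self._ball()
        norm = FrameTransform(np.eye(4), Frame.WORLD, Frame.TEMPLATE)
        outline = skull_outline(mask, self._native(), norm)
        # erosion oracle: outline == mask minus its 6-connected erosion
        m = mask.values.astype(bool)
        eroded = ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
        np.testing.assert_array_equal(outline.values.astype(bool), m & ~eroded)
        assert not outline.values[eroded].any()  # interior all zero

    def test_outline_subset_and_covers_boundary(self):
        mask = self._ball(radius=8)
        norm = FrameTransform(np.eye(4), Frame.WORLD, Frame.TEMPLATE)
        outline = skull_outline(mask, self._native(), norm).values.astype(bool)
        m = mask.values.astype(bool)
        assert np.all(~outline | m)  # outline subset of mask
        # every mask voxel 6-adjacent to background is on the outline
        bg_adjacent = m & ~ndimage.binary_erosion(m, ndimage.generate_binary_structure(3, 1))
        assert np.array_equal(outline, bg_adjacent)

    def test_empty_reverse_normalized_mask_is_error(self):
        mask = self._ball(radius=5)
        # a 200 mm shift pushes the mask entirely out of the native FOV
        norm = FrameTransform(
            affine_from_params((200.0, 0, 0), (0, 0, 0)), Frame.WORLD, Frame.TEMPLATE
        )
        with pytest.raises(ValueError, match="empty"):
            skull_outline(mask, self._native(), norm)


class TestQueryAll:
    def test_order_preserved_and_statuses(self):
        v1 = np.zeros((4, 4, 4), np.int32)  # unlabeled at the probe voxel
        v2 = np.zeros((4, 4, 4), np.int32)
        v2[1, 1, 1] = 3
        a1 = _atlas(v1, entries={1: "x"}, name="first")
        a2 = _atlas(v2, name="second")
        results = query_all([a1, a2], (1, 1, 1))
        assert [r.atlas_name for r in results] == ["first", "second"]
        assert [r.status for r in results] == ["unlabeled", "labeled"]

    def test_both_labeled_in_configured_order(self):
        v = np.ones((4, 4, 4), np.int32)
        res = query_all([_atlas(v, name="b"), _atlas(v, name="a")], (0, 0, 0))
        assert [r.atlas_name for r in res] == ["b", "a"]
        assert all(r.status == "labeled" for r in res)

    def test_empty_atlas_list(self):
        assert query_all([], (0, 0, 0)) == []


class TestManifest:
    def test_bundle_round_trip(self, subject):
        atlases = read_atlas_manifest(subject.manifest_path)
        assert len(atlases) == 1
        assert atlases[0].name == "toy"
        assert atlases[0].space == "template"
        np.testing.assert_array_equal(
            atlases[0].labels.values, subject.atlas_template.labels.values
        )
        assert atlases[0].lookup.entries == subject.atlas_template.lookup.entries
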