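"""Colour / motion / shape / size-change feature extraction."""

import numpy as np
import pytest
from skimage.color import rgb2hsv

from handuse.data_model import BoundingBox, HandMask, Role, Side
from handuse.region_features import (
    HOG_RAW_LENGTH,
    FeatureConfig,
    assemble_features,
    bhattacharyya_distance,
    colour_features,
    dense_flow,
    extract_instances,
    feature_schema,
    fit_shape_projection,
    hog_shape,
    motion_features,
    partition_regions,
    size_change_feature,
)
from handuse.synthetic_scenes import SceneConfig, generate_task


def brute_force_partition_counts(frame_size, box, expanded, mask):
    """Per-pixel membership oracle for the three-region split."""
    fw, fh = frame_size
    hand = surround = background = 0
    for y in range(fh):
        for x in range(fw):
            in_box = box.x <= x < box.x2 and box.y <= y < box.y2
            in_exp = expanded.x <= x < expanded.x2 and expanded.y <= y < expanded.y2
            if mask[y, x] and in_box:
                hand += 1
            elif in_exp:
                surround += 1
            else:
                background += 1
    return hand, surround, background


class TestPartitionRegions:
    def test_counts_match_pixel_membership_oracle(self, rng):
        for _ in range(25):
            fw, fh = int(rng.integers(20, 40)), int(rng.integers(20, 40))
            x = int(rng.integers(0, fw - 5))
            y = int(rng.integers(0, fh - 5))
            box = BoundingBox(x, y, int(rng.integers(3, fw - x)), int(rng.integers(3, fh - y)))
            mask = rng.random((fh, fw)) < 0.3
            expansion = float(rng.uniform(1.0, 2.0))
            part = partition_regions((fw, fh), box, HandMask(mask), expansion)
            expanded = box.clipped((fw, fh)).expanded(expansion, (fw, fh))
            assert part.counts() == brute_force_partition_counts(
                (fw, fh), box.clipped((fw, fh)), expanded, mask
            )

    def test_partition_covers_frame_exactly(self, rng):
        for _ in range(10):
            box = BoundingBox(int(rng.integers(0, 60)), int(rng.integers(0, 60)), 20, 20)
            mask = rng.random((100, 100)) < 0.5
            part = partition_regions((100, 100), box, HandMask(mask), 1.5)
            assert sum(part.counts()) == 10_000
            union = part.hand | part.surround | part.background
            assert union.all()
            assert not (part.hand & part.surround).any()
            assert not (part.surround & part.background).any()

    def test_known_geometry_pixel_counts(self):
        # box interior fully masked, no expansion: hand 400, surround 0
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 40:60] = True
        box = BoundingBox(40, 40, 20, 20)
        part = partition_regions((100, 100), box, HandMask(mask), 1.0)
        assert part.counts() == (400, 0, 9600)

    def test_box_covering_frame_leaves_no_background(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        part = partition_regions((50, 50), BoundingBox(0, 0, 50, 50), HandMask(mask), 1.5)
        assert part.counts()[2] == 0
        assert part.counts()[1] == 2500 - 100

    def test_empty_hand_is_flagged_not_fatal(self):
        mask = np.zeros((50, 50), dtype=bool)
        part = partition_regions((50, 50), BoundingBox(5, 5, 10, 10), HandMask(mask), 1.5)
        assert part.hand_empty


class TestBhattacharyya:
    def test_identity_disjoint_and_direct_formula(self):
        assert bhattacharyya_distance([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert bhattacharyya_distance([1.0, 0.0], [0.0, 1.0]) == 1.0
        got = bhattacharyya_distance([0.5, 0.5], [1.0, 0.0])
        assert got == pytest.approx(np.sqrt(1 - np.sqrt(0.5)), abs=1e-12)

    def test_agrees_with_formula_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            h1 = rng.random(n)
            h2 = rng.random(n)
            h1 /= h1.sum()
            h2 /= h2.sum()
            expected = np.sqrt(max(0.0, 1.0 - np.sum(np.sqrt(h1 * h2))))
            got = bhattacharyya_distance(h1, h2)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got == pytest.approx(bhattacharyya_distance(h2, h1), abs=1e-12)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            bhattacharyya_distance([2.0, 1.0], [0.5, 0.5])


class TestColourFeatures:
    def test_uniform_frame_gives_zero_distances(self):
        frame = np.full((40, 60, 3), 128, dtype=np.uint8)
        mask = np.zeros((40, 60), dtype=bool)
        mask[10:20, 20:30] = True
        part = partition_regions((60, 40), BoundingBox(18, 8, 14, 14), HandMask(mask), 1.5)
        out = colour_features(rgb2hsv(frame), part)
        assert out.shape == (6,)
        assert np.allclose(out, 0.0)

    def test_position_permutation_within_regions_is_invariant(self, rng):
        frame = rng.integers(0, 255, size=(40, 60, 3), dtype=np.uint8)
        mask = np.zeros((40, 60), dtype=bool)
        mask[10:20, 20:30] = True
        box = BoundingBox(18, 8, 14, 14)
        part = partition_regions((60, 40), box, HandMask(mask), 1.5)
        hsv = rgb2hsv(frame)
        before = colour_features(hsv, part)
        # shuffle pixel positions inside each region
        shuffled = hsv.copy()
        for region in (part.hand, part.surround, part.background):
            vals = shuffled[region]
            shuffled[region] = vals[rng.permutation(len(vals))]
        after = colour_features(shuffled, part)
        assert np.allclose(before, after)

    def test_object_patch_raises_hand_vs_surround_hue_distance(self, small_scene):
        # during an interaction the surround contains the object's hue;
        # the hand/surround contrast should beat surround/background
        seq = small_scene
        obs = seq.get(25, Side.MORE_AFFECTED)  # inside the planted segment
        assert obs.interacting
        fw, fh = seq.frame_size
        part = partition_regions((fw, fh), obs.box, obs.mask, 1.5)
        out = colour_features(rgb2hsv(seq.frames[25]), part)
        hue_hand_surround, hue_surround_background = out[0], out[3]
        assert hue_hand_surround > hue_surround_background


class TestDenseFlow:
    def test_identical_frames_give_near_zero_flow(self, rng):
        frame = rng.integers(0, 255, size=(60, 80, 3), dtype=np.uint8)
        flow = dense_flow(frame, frame)
        assert flow.shape == (60, 80, 2)
        assert np.abs(flow).max() < 0.25

    def test_planted_horizontal_shift_recovered(self, rng):
        texture = rng.random((60, 80)).astype(float)
        prev = np.stack([texture] * 3, axis=-1)
        curr = np.roll(prev, 3, axis=1)  # content moves +3 px rightward
        flow = dense_flow(prev, curr)
        inner = flow[10:-10, 10:-10]
        assert 2.0 <= np.median(inner[..., 0]) <= 4.0
        assert abs(np.median(inner[..., 1])) < 1.0

    def test_reversed_pair_has_opposite_direction(self, rng):
        texture = rng.random((60, 80)).astype(float)
        prev = np.stack([texture] * 3, axis=-1)
        curr = np.roll(prev, 4, axis=1)
        fwd = np.median(dense_flow(prev, curr)[10:-10, 10:-10, 0])
        bwd = np.median(dense_flow(curr, prev)[10:-10, 10:-10, 0])
        assert fwd > 1.0 and bwd < -1.0


class TestMotionFeatures:
    @staticmethod
    def _partition():
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:35, 30:45] = True
        return partition_regions((80, 60), BoundingBox(28, 18, 20, 20), HandMask(mask), 1.5)

    def test_static_pair_gives_all_zero_differences(self):
        flow = np.zeros((60, 80, 2))
        out = motion_features(flow, self._partition())
        assert out.shape == (60,)
        assert np.allclose(out, 0.0)

    def test_output_length_matches_bin_config(self, rng):
        flow = rng.standard_normal((60, 80, 2))
        assert motion_features(flow, self._partition(), n_bins=15).shape == (60,)
        assert motion_features(flow, self._partition(), n_bins=8).shape == (32,)

    def test_coherent_hand_object_motion_has_small_hand_surround_contrast(self):
        # hand and rigidly attached object move together against a static
        # background: hand-vs-surround histogram differences should be
        # smaller than surround-vs-background differences
        part = self._partition()
        flow = np.zeros((60, 80, 2))
        moving = part.hand | part.surround
        flow[moving] = (3.0, 1.0)
        out = motion_features(flow, part)
        hand_surround = np.abs(out[:30]).sum()
        surround_background = np.abs(out[30:]).sum()
        assert hand_surround < surround_background


class TestHogShape:
    def test_raw_length_from_cell_block_geometry(self, rng):
        frame = rng.integers(0, 255, size=(90, 120, 3), dtype=np.uint8)
        vec = hog_shape(frame, BoundingBox(10, 10, 30, 50))
        assert vec.shape == (HOG_RAW_LENGTH,)
        assert HOG_RAW_LENGTH == 108  # 1×3 blocks × 4 cells × 9 orientations

    def test_uniform_crop_gives_zero_vector(self):
        frame = np.full((90, 120, 3), 77, dtype=np.uint8)
        vec = hog_shape(frame, BoundingBox(10, 10, 30, 50))
        assert np.allclose(vec, 0.0)

    def test_unsigned_gradients_invariant_under_intensity_inversion(self, rng):
        # inverting intensities negates every gradient; with unsigned
        # orientation bins the descriptor is exactly unchanged
        frame = rng.integers(0, 255, size=(90, 120, 3), dtype=np.uint8)
        box = BoundingBox(10, 10, 30, 50)
        assert np.array_equal(hog_shape(frame, box), hog_shape(255 - frame, box))

    def test_180_degree_rotation_permutes_cells_on_whole_cell_grid(self, rng):
        # on an exact multiple of the cell grid, a 180° rotation permutes
        # cells and blocks but maps each unsigned orientation bin onto
        # itself, so the sorted energies coincide
        from skimage.feature import hog as skimage_hog

        img = rng.random((64, 32))
        kwargs = dict(
            orientations=9, pixels_per_cell=(16, 16), cells_per_block=(2, 2),
            block_norm="L2-Hys",
        )
        h1 = skimage_hog(img, **kwargs)
        h2 = skimage_hog(np.rot90(img, 2), **kwargs)
        assert np.allclose(np.sort(h1), np.sort(h2), atol=1e-6)

    def test_degenerate_box_rejected(self, rng):
        frame = rng.integers(0, 255, size=(50, 50, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            hog_shape(frame, BoundingBox(5, 5, 1, 1))


class TestShapeProjection:
    def test_planted_low_rank_data_concentrates_variance(self, rng):
        basis = rng.standard_normal((5, HOG_RAW_LENGTH))
        coeffs = rng.standard_normal((200, 5))
        data = coeffs @ basis
        proj = fit_shape_projection(data, n_components=60)
        projected = proj.apply(data)
        variances = projected.var(axis=0)
        assert variances[5:].sum() <= 1e-8 * variances.sum()

    def test_components_orthonormal_and_count_fixed(self, rng):
        data = rng.standard_normal((150, HOG_RAW_LENGTH))
        proj = fit_shape_projection(data, n_components=60)
        gram = proj.components @ proj.components.T
        assert np.allclose(gram, np.eye(60), atol=1e-6)
        assert proj.apply(data).shape == (150, 60)

    def test_reconstruction_error_monotone_in_component_count(self, rng):
        data = rng.standard_normal((150, HOG_RAW_LENGTH))
        proj = fit_shape_projection(data, n_components=60)
        centred = data - proj.mean
        errors = []
        for k in (5, 20, 40, 60):
            comp = proj.components[:k]
            recon = (centred @ comp.T) @ comp
            errors.append(np.sum((centred - recon) ** 2))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_too_few_samples_is_a_hard_error(self, rng):
        with pytest.raises(ValueError, match="smaller component count"):
            fit_shape_projection(rng.standard_normal((60, HOG_RAW_LENGTH)), n_components=60)


class TestSizeChange:
    def test_constant_area_gives_zero_vector(self):
        assert np.allclose(size_change_feature(np.full(30, 200.0), 5), 0.0)

    def test_direct_formula_evaluation(self):
        areas = np.array([100.0, 110.0] + [110.0] * 20)
        out = size_change_feature(areas, 0)
        assert np.allclose(out, [0.1] + [0.0] * 9)

    def test_length_ten_even_near_sequence_end(self):
        areas = np.linspace(100, 200, 12)
        out = size_change_feature(areas, 10)
        assert out.shape == (10,)
        assert np.count_nonzero(out) == 1  # only one in-range forward difference

    def test_zero_area_frame_rejected(self):
        areas = np.array([100.0, 0.0, 100.0])
        with pytest.raises(ValueError, match="no hand pixels"):
            size_change_feature(areas, 1)


class TestAssembleFeatures:
    def test_stage_row_lengths(self, small_scene):
        raw = extract_instances(small_scene, Side.MORE_AFFECTED)
        projection = fit_shape_projection(
            np.vstack([raw.hog_raw, raw.hog_raw + 1e-3]), n_components=60
        )
        X_int, idx_int, y_int = (
            assemble_features(small_scene, Side.MORE_AFFECTED, "interaction", projection)
        )
        assert X_int.shape == (small_scene.n_frames, 6 + 60 + 60)
        assert idx_int.shape == y_int.shape
        X_role, idx_role, y_role = (
            assemble_features(small_scene, Side.MORE_AFFECTED, "role", projection)
        )
        assert X_role.shape[1] == 60 + 60 + 10
        # role rows exist only on role-labeled (interacting) frames
        assert X_role.shape[0] == int(np.sum(y_int == 1))
        assert set(y_role.tolist()) <= {0, 1}

    def test_instances_without_masks_are_excluded(self, small_scene):
        import copy

        seq = copy.copy(small_scene)
        seq.observations = dict(small_scene.observations)
        for t in (3, 7, 9):
            obs = copy.copy(seq.observations[(t, Side.MORE_AFFECTED)])
            obs.mask = None
            seq.observations[(t, Side.MORE_AFFECTED)] = obs
        raw = extract_instances(seq, Side.MORE_AFFECTED)
        assert raw.n_instances == seq.n_frames - 3
        assert not {3, 7, 9} & set(raw.frame_indices.tolist())

    def test_schema_slices_sum_to_full_row_length(self):
        interaction = feature_schema("interaction")
        assert [(n, l) for n, l in interaction] == [("colour", 6), ("motion", 60), ("shape", 60)]
        assert sum(l for _, l in interaction) == 126
        role = feature_schema("role")
        assert sum(l for _, l in role) == 130
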