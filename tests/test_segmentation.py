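from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcrack3d import (
    compute_envelope,
    hysteresis_segment,
    label_porosities,
    planarity_field,
    planarity_guided_filter,
    segment_bone,
    segment_porosities,
)
from microcrack3d.segmentation import ConfigError, ThresholdingError
from _geom import digitized_ellipsoid


# ---------------------------------------------------------------------------
# Hysteresis oracle: explicit flood fill from seeds over candidates
# ---------------------------------------------------------------------------


def hysteresis_oracle(field, low, high):
    cand = field >= low
    seeds = np.argwhere(cand & (field >= high))
    out = np.zeros(field.shape, bool)
    q = deque(map(tuple, seeds))
    for s in q:
        out[s] = True
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offsets:
            p = (z + dz, y + dy, x + dx)
            if all(0 <= p[i] < field.shape[i] for i in range(3)):
                if cand[p] and not out[p]:
                    out[p] = True
                    q.append(p)
    return out


class TestHysteresis:
    def test_textbook_1d_profile(self):
        # profile [0,3,9,4,0,4,0]: the isolated 4 has no seed to connect to
        field = np.array([0, 3, 9, 4, 0, 4, 0], float)[None, None, :]
        mask = hysteresis_segment(field, low=2, high=8)
        assert list(np.nonzero(mask.ravel())[0]) == [1, 2, 3]

    def test_low_equals_high_is_simple_threshold(self, rng):
        field = rng.random((8, 8, 8))
        mask = hysteresis_segment(field, 0.5, 0.5)
        np.testing.assert_array_equal(mask, field >= 0.5)

    def test_low_above_high_rejected(self):
        with pytest.raises(ConfigError):
            hysteresis_segment(np.zeros((2, 2, 2)), 0.9, 0.1)

    def test_matches_flood_fill_oracle_on_random_fields(self, rng):
        for _ in range(100):
            field = rng.random((10, 10, 10)).astype(np.float32)
            low, high = sorted(rng.uniform(0.2, 0.95, 2))
            got = hysteresis_segment(field, low, high)
            want = hysteresis_oracle(field, low, high)
            np.testing.assert_array_equal(got, want)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        low=st.floats(0.05, 0.5),
        spread=st.floats(0.0, 0.45),
    )
    def test_flood_fill_equivalence_property(self, seed, low, spread):
        field = np.random.default_rng(seed).random((7, 7, 7))
        high = low + spread
        np.testing.assert_array_equal(
            hysteresis_segment(field, low, high), hysteresis_oracle(field, low, high)
        )


class TestLabeling:
    def test_diagonal_connectivity_semantics(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        _, n26 = label_porosities(mask, connectivity=26)
        _, n6 = label_porosities(mask, connectivity=6)
        assert (n26, n6) == (1, 2)

    def test_empty_mask_has_zero_labels(self):
        labels, n = label_porosities(np.zeros((4, 4, 4), bool))
        assert n == 0 and labels.max() == 0

    def test_labels_contiguous_and_deterministic(self, rng):
        mask = rng.random((12, 12, 12)) < 0.2
        labels, n = label_porosities(mask)
        assert set(np.unique(labels)) == set(range(n + 1))
        labels2, _ = label_porosities(mask)
        np.testing.assert_array_equal(labels, labels2)

    def test_invalid_connectivity(self):
        with pytest.raises(ConfigError):
            label_porosities(np.zeros((2, 2, 2), bool), connectivity=4)


# ---------------------------------------------------------------------------
# Bone threshold and envelope
# ---------------------------------------------------------------------------


class TestBoneSegmentation:
    def test_two_valued_volume_is_separated_exactly(self, rng):
        truth = rng.random((24, 24, 24)) < 0.3
        data = np.where(truth, 200.0, 50.0)
        mask, thr = segment_bone(data, "auto")
        np.testing.assert_array_equal(mask, truth)
        assert 50 < thr <= 200

    def test_threshold_zero_selects_everything(self, rng):
        data = rng.uniform(10, 100, (8, 8, 8))
        mask, _ = segment_bone(data, 0.0)
        assert mask.all()

    def test_unimodal_histogram_rejected(self, rng):
        data = rng.normal(100, 5, (20, 20, 20))
        with pytest.raises(ThresholdingError):
            segment_bone(data, "auto")

    def test_noisy_phantom_threshold_close_to_truth(self, rng):
        truth = np.zeros((32, 32, 32), bool)
        truth[10:22] = True
        data = np.where(truth, 200.0, 60.0) + rng.normal(0, 10, truth.shape)
        mask, _ = segment_bone(data, "auto")
        assert (mask != truth).mean() < 0.01


class TestEnvelope:
    def test_thin_slot_is_closed(self):
        cube = np.ones((30, 30, 30), bool)
        cube[14:17, 5:25, 5:25] = False  # 3-voxel internal slot
        env = compute_envelope(cube, voxel_size_um=1.4, closing_radius_um=14.0)
        assert env.all()

    def test_solid_bone_is_unchanged(self):
        bone = np.zeros((24, 24, 24), bool)
        bone[6:18] = True  # slab, no porosity
        env = compute_envelope(bone, 1.4)
        np.testing.assert_array_equal(env, bone)

    def test_carved_lacuna_is_restored(self):
        bone = np.zeros((40, 40, 40), bool)
        bone[8:32] = True
        lacuna = np.zeros_like(bone)
        lacuna[16:24, 16:24, 16:24] = digitized_ellipsoid((3.5, 3.5, 3.5), pad=0)[
            :8, :8, :8
        ]
        carved = bone & ~lacuna
        env = compute_envelope(carved, 1.4)
        diff = env & ~carved
        # envelope restores exactly the carved ellipsoid voxels
        np.testing.assert_array_equal(diff, lacuna & bone)

    def test_envelope_contains_bone(self, small_phantom):
        _, vol, truth = small_phantom
        mask, _ = segment_bone(vol.data)
        env = compute_envelope(mask, vol.voxel_size_um)
        assert (mask & ~env).sum() == 0


# ---------------------------------------------------------------------------
# Planarity filter
# ---------------------------------------------------------------------------


class TestPlanarity:
    def test_constant_volume_scores_zero(self):
        field = planarity_field(np.full((16, 16, 16), 50.0), 1.4, 2.1)
        assert field.score.max() == 0.0

    def test_dark_sheet_beats_background_and_normal_recovered(self):
        data = np.full((32, 32, 32), 200.0, np.float32)
        data[15:17] = 60.0  # 2-voxel dark sheet, normal along z
        field = planarity_field(data, 1.4, 2.1)
        on = field.score[15:17].mean()
        off = np.concatenate([field.score[:12], field.score[20:]]).mean()
        assert on > 5 * max(off, 1e-9)
        # recovered normal within 5 degrees of the z axis
        sup = np.stack(field.support, 1)
        sel = (sup[:, 0] >= 15) & (sup[:, 0] <= 16)
        normals = field.normal[sel]
        cosang = np.abs(normals[:, 0])
        assert np.median(np.degrees(np.arccos(np.clip(cosang, -1, 1)))) < 5

    def test_blob_scores_below_sheet_at_equal_contrast(self):
        sheet = np.full((32, 32, 32), 200.0, np.float32)
        sheet[15:17] = 60.0
        blob = np.full((32, 32, 32), 200.0, np.float32)
        zz, yy, xx = np.mgrid[0:32, 0:32, 0:32]
        blob[(zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 16] = 60.0
        fs = planarity_field(sheet, 1.4, 2.1)
        fb = planarity_field(blob, 1.4, 2.1)
        # compare raw (pre-normalisation) responses via a common scale:
        # score each volume against the sheet's max by recomputing jointly
        joint = np.concatenate([sheet, blob], axis=0)
        fj = planarity_field(joint, 1.4, 2.1)
        sheet_score = fj.score[15:17].mean()
        blob_vox = fj.score[32:][(zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 16]
        assert blob_vox.mean() <= 0.5 * sheet_score

    def test_sigma_below_voxel_rejected(self):
        with pytest.raises(ConfigError):
            planarity_field(np.zeros((8, 8, 8)), 1.4, 0.7)

    def test_normals_are_unit_length(self, small_phantom):
        _, vol, _ = small_phantom
        field = planarity_field(vol.data[:48, :48, :48], vol.voxel_size_um, 2.1)
        norms = np.linalg.norm(field.normal, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_scores_in_unit_interval(self, small_phantom):
        _, vol, _ = small_phantom
        field = planarity_field(vol.data[:48, :48, :48], vol.voxel_size_um, 2.1)
        assert field.score.min() >= 0.0
        assert field.score.max() <= 1.0


class TestGuidedFilter:
    def test_constant_volume_preserved_exactly(self):
        data = np.full((12, 12, 12), 80.0, np.float32)
        out = planarity_guided_filter(data, np.zeros_like(data), 1.4)
        np.testing.assert_allclose(out, data, atol=1e-5)

    def test_infinite_bandwidths_reduce_to_spatial_smoothing(self, rng):
        data = rng.uniform(0, 100, (16, 16, 16)).astype(np.float32)
        score = rng.random((16, 16, 16)).astype(np.float32)
        out = planarity_guided_filter(
            data, score, 1.0, spatial_radius_um=2.0,
            planarity_bandwidth=1e9, intensity_bandwidth=1e9,
        )
        # oracle: normalised convolution with the same truncated kernel
        r = 2
        kern = np.zeros((2 * r + 1,) * 3)
        for dz in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    d2 = dz * dz + dy * dy + dx * dx
                    if d2 <= r * r:
                        kern[dz + r, dy + r, dx + r] = np.exp(-d2 / (2 * (r / 2) ** 2))
        from scipy import ndimage

        pad = np.pad(data, r, mode="edge")
        num = ndimage.convolve(pad, kern)[r:-r, r:-r, r:-r]
        den = kern.sum()
        np.testing.assert_allclose(out, num / den, rtol=1e-4, atol=1e-3)

    def test_crack_cnr_improves_under_noise(self, small_phantom):
        cfg, vol, truth = small_phantom
        rng = np.random.default_rng(5)
        noisy = vol.data + rng.normal(0, 14, vol.data.shape).astype(np.float32)
        field = planarity_field(noisy, vol.voxel_size_um, 2.1)
        out = planarity_guided_filter(noisy, field.score, vol.voxel_size_um)
        crack_idx = tuple(
            np.concatenate([o.indices[i] for o in truth.cracks()]) for i in range(3)
        )
        bone = truth.bone_mask & (truth.label_map == 0)

        def cnr(img):
            sig = bone_mean(img, bone) - img[crack_idx].mean()
            return sig / img[bone].std()

        def bone_mean(img, b):
            return img[b].mean()

        assert cnr(out) >= 1.5 * cnr(noisy)


# ---------------------------------------------------------------------------
# Full chain invariants
# ---------------------------------------------------------------------------


class TestChain:
    def test_determinism_and_mask_containment(self, small_phantom):
        _, vol, truth = small_phantom
        seg1 = segment_porosities(vol.data, vol.voxel_size_um)
        seg2 = segment_porosities(vol.data, vol.voxel_size_um)
        np.testing.assert_array_equal(seg1["labels"], seg2["labels"])
        # porosity inside the envelope and disjoint from the final bone phase
        assert not (seg1["porosity_mask"] & ~seg1["envelope"]).any()
        assert not (seg1["porosity_mask"] & seg1["bone"]).any()

    def test_zero_noise_components_cover_truth(self, small_phantom):
        _, vol, truth = small_phantom
        seg = segment_porosities(vol.data, vol.voxel_size_um)
        # every truth object is hit by some predicted component
        for o in truth.objects:
            hit = seg["labels"][o.indices]
            assert (hit > 0).mean() > 0.5
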