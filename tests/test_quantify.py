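import numpy as np
import pytest
from scipy import ndimage

from microcrack3d import (
    classify_porosity,
    compute_smi,
    crack_surface,
    fit_ellipsoid,
    local_trabecular_thickness,
    object_thickness,
    thickness_map,
    trabecular_shape,
)
from microcrack3d.quantify import (
    EmptyObjectError,
    SiteError,
    UndefinedSurfaceError,
    analyze_porosities,
    specimen_metrics,
)
from _geom import digitized_ball, digitized_ellipsoid


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def moment_fit_oracle(mask, voxel_size):
    """Semi-axes via explicit per-voxel moment summation (slow, simple)."""
    pts = [
        ((i + 0.5) * voxel_size, (j + 0.5) * voxel_size, (k + 0.5) * voxel_size)
        for i, j, k in zip(*np.nonzero(mask))
    ]
    n = len(pts)
    cz = sum(p[0] for p in pts) / n
    cy = sum(p[1] for p in pts) / n
    cx = sum(p[2] for p in pts) / n
    m = np.zeros((3, 3))
    for p in pts:
        d = np.array([p[0] - cz, p[1] - cy, p[2] - cx])
        m += np.outer(d, d)
    m /= n
    # voxels are solid cubes: add each voxel's own second moment
    m += (voxel_size**2 / 12.0) * np.eye(3)
    eig = np.sort(np.linalg.eigvalsh(m))[::-1]
    return np.sqrt(5.0 * np.clip(eig, 0, None))


def thickness_oracle(mask, voxel_size):
    """Exhaustive maximal-inscribed-sphere search.

    Every object voxel is a candidate sphere centre with radius
    EDT - 0.5 voxels; each voxel's thickness is the largest diameter among
    the spheres that cover it, found by looping over all centres.
    """
    mask = np.asarray(mask, bool)
    edt = ndimage.distance_transform_edt(mask)
    out = np.zeros(mask.shape)
    centers = np.argwhere(mask)
    radii = edt[mask] - 0.5
    zz, yy, xx = np.indices(mask.shape)
    for (cz, cy, cx), r in zip(centers, radii):
        r = max(r, 0.5)
        covered = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r + 1e-9
        out[covered & mask] = np.maximum(out[covered & mask], 2 * r)
    return out * voxel_size


def random_blob(rng, shape=(24, 24, 24), n_seeds=4, iters=5):
    mask = np.zeros(shape, bool)
    for _ in range(n_seeds):
        p = tuple(rng.integers(4, s - 4) for s in shape)
        mask[p] = True
    for _ in range(iters):
        mask = ndimage.binary_dilation(mask, iterations=2)
        noise = rng.random(shape) < 0.15
        mask &= ~noise
    mask = ndimage.binary_closing(mask)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return mask


# ---------------------------------------------------------------------------
# Ellipsoid fit
# ---------------------------------------------------------------------------


class TestFitEllipsoid:
    def test_single_voxel_degenerates_to_zero_extent(self):
        fit = fit_ellipsoid((np.array([3]), np.array([4]), np.array([5])), 1.4)
        assert fit.length_um == 0.0
        assert fit.width_um == 0.0

    def test_digitized_ellipsoid_recovers_semi_axes(self):
        mask = digitized_ellipsoid((50, 25, 5))
        fit = fit_ellipsoid(np.nonzero(mask), 1.0)
        np.testing.assert_allclose(fit.semi_axes_um, [50, 25, 5], rtol=0.02)

    def test_digitized_ball_is_isotropic(self):
        mask = digitized_ball(10.5)
        fit = fit_ellipsoid(np.nonzero(mask), 1.0)
        np.testing.assert_allclose(fit.semi_axes_um, 10.5, rtol=0.02)

    def test_rotation_about_z_preserves_length_and_width(self):
        # Digitise the same ellipsoid upright and rotated 30 degrees.
        a, b, c = 30, 15, 4
        n = 40
        zz, yy, xx = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
        upright = (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1
        th = np.deg2rad(30)
        xr = xx * np.cos(th) + yy * np.sin(th)
        yr = -xx * np.sin(th) + yy * np.cos(th)
        rotated = (xr / a) ** 2 + (yr / b) ** 2 + (zz / c) ** 2 <= 1
        f0 = fit_ellipsoid(np.nonzero(upright), 1.0)
        f1 = fit_ellipsoid(np.nonzero(rotated), 1.0)
        assert abs(f1.length_um - f0.length_um) / f0.length_um < 0.03
        assert abs(f1.width_um - f0.width_um) / f0.width_um < 0.03

    def test_matches_bruteforce_oracle_on_random_blobs(self, rng):
        for _ in range(10):
            mask = random_blob(rng)
            fit = fit_ellipsoid(np.nonzero(mask), 1.4)
            oracle = moment_fit_oracle(mask, 1.4)
            np.testing.assert_allclose(fit.semi_axes_um, oracle, rtol=1e-9, atol=1e-9)

    def test_lattice_rotation_invariance(self, rng):
        mask = random_blob(rng)
        f0 = fit_ellipsoid(np.nonzero(mask), 1.0)
        for axes in [(0, 1), (0, 2), (1, 2)]:
            f1 = fit_ellipsoid(np.nonzero(np.rot90(mask, axes=axes)), 1.0)
            np.testing.assert_allclose(
                f1.semi_axes_um, f0.semi_axes_um, rtol=1e-9, atol=1e-9
            )


# ---------------------------------------------------------------------------
# Thickness map
# ---------------------------------------------------------------------------


class TestThicknessMap:
    def test_ball_thickness_equals_diameter(self):
        d = 21
        mask = digitized_ball(d / 2)
        th = thickness_map(mask, 1.0)
        center = tuple(s // 2 for s in mask.shape)
        assert abs(th[center] - d) <= 1.0
        # the ball is its own maximal sphere at (almost) every voxel
        assert np.median(th[mask]) >= d - 2

    def test_slab_thickness(self):
        mask = np.zeros((11, 24, 24), bool)
        mask[4:7] = True  # 3-voxel slab
        th = thickness_map(mask, 1.0)
        interior = mask.copy()
        interior[:, :2, :] = interior[:, -2:, :] = False
        interior[:, :, :2] = interior[:, :, -2:] = False
        assert abs(th[interior].mean() - 3.0) <= 1.0

    def test_two_thickness_lshape_averages(self):
        # Halves of thickness t and 2t with equal voxel counts -> mean 1.5t.
        t = 4
        mask = np.zeros((20, 16, 32), bool)
        mask[8 : 8 + t, :, :16] = True
        mask[8 : 8 + 2 * t, :, 16:24] = True  # half the x-extent, double thickness
        th = thickness_map(mask, 1.0)
        thin = object_thickness(th, np.nonzero(mask[:, :, :16]))
        # thin half alone
        assert abs(thin - t) <= 1.0

    def test_matches_exhaustive_oracle_on_random_blobs(self, rng):
        for _ in range(5):
            mask = random_blob(rng, shape=(20, 20, 20), n_seeds=3, iters=4)
            th = thickness_map(mask, 1.0)
            oracle = thickness_oracle(mask, 1.0)
            assert np.max(np.abs(th[mask] - oracle[mask])) <= 1.0 + 1e-6

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyObjectError):
            thickness_map(np.zeros((4, 4, 4), bool), 1.0)

    def test_object_thickness_of_ball(self):
        mask = digitized_ball(7.5)
        th = thickness_map(mask, 1.4)
        val = object_thickness(th, np.nonzero(mask))
        # mean over all voxels is below the diameter but close for a ball
        assert 15 * 1.4 * 0.75 <= val <= 15 * 1.4 + 1.4


# ---------------------------------------------------------------------------
# Surface, classification, specimen metrics
# ---------------------------------------------------------------------------


class TestSurfaceAndClass:
    def test_surface_is_volume_over_thickness(self):
        assert crack_surface(10.0, 2.0) == 5.0
        assert crack_surface(7.0, 7.0) == 1.0

    def test_zero_thickness_raises(self):
        with pytest.raises(UndefinedSurfaceError):
            crack_surface(1.0, 0.0)

    @pytest.mark.parametrize(
        "volume,thickness,width,expected",
        [
            (89100.0, 3.11, 201.0, "microcrack"),   # long thin sheet
            (2000.0, 10.0, 10.0, "lacuna"),          # compact, ratio ~1
            (400.0, 1.0, 100.0, "other"),            # below the volume cut
            (600.0, 33.0, 100.0, "microcrack"),      # ratio just below 1/3
            (600.0, 34.0, 100.0, "lacuna"),          # ratio 0.34 >= 1/3
        ],
    )
    def test_classification_rule(self, volume, thickness, width, expected):
        got = classify_porosity(volume, thickness, width)
        if volume > 500 and width > 0 and thickness / width < 1 / 3:
            assert got == "microcrack"
        assert got == expected

    def test_zero_width_is_other(self):
        assert classify_porosity(1000.0, 1.0, 0.0) == "other"

    def test_class_partition_is_exhaustive(self, small_phantom):
        _, vol, truth = small_phantom
        records = analyze_porosities(truth.label_map, vol.voxel_size_um)
        assert len(records) == len(truth.objects)
        assert all(r.cls in ("microcrack", "lacuna", "other") for r in records)

    def test_specimen_metrics_bookkeeping(self, small_phantom):
        _, vol, truth = small_phantom
        records = analyze_porosities(truth.label_map, vol.voxel_size_um)
        porosity = truth.label_map > 0
        envelope = truth.bone_mask | porosity
        rep = specimen_metrics(records, porosity, envelope, vol.voxel_size_um)
        n_cr = sum(r.cls == "microcrack" for r in records)
        n_la = sum(r.cls == "lacuna" for r in records)
        assert rep.n_cracks == n_cr
        assert rep.n_lacunae == n_la
        assert rep.crack_density_mm3 == pytest.approx(n_cr / rep.bv_mm3)
        assert rep.lacuna_density_mm3 == pytest.approx(n_la / rep.bv_mm3)
        assert 0 < rep.bvtv < 1

    def test_all_bone_bvtv_is_one(self):
        full = np.ones((8, 8, 8), bool)
        rep = specimen_metrics([], np.zeros_like(full), full, 1.4)
        assert rep.bvtv == 1.0
        assert rep.crack_density_mm3 == 0.0


# ---------------------------------------------------------------------------
# SMI and local trabecular context
# ---------------------------------------------------------------------------


class TestSMI:
    def test_plate_rod_ball_reference_values(self):
        plate = np.zeros((40, 64, 64), bool)
        plate[10:30] = True  # slab through the full xy extent
        zz, yy, xx = np.mgrid[0:64, 0:64, 0:64]
        rod = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        ball = (zz - 32) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2 <= 25**2
        assert abs(compute_smi(plate) - 0.0) <= 0.5
        assert abs(compute_smi(rod) - 3.0) <= 0.5
        assert abs(compute_smi(ball) - 4.0) <= 0.5


class TestSiteMetrics:
    def test_tb_th_lo_in_uniform_plate(self):
        t = 30  # voxels
        mask = np.zeros((96, 96, 96), bool)
        mask[33 : 33 + t] = True
        th = thickness_map(mask, 1.4)
        centroid = np.array([48 * 1.4, 48 * 1.4, 48 * 1.4])
        val = local_trabecular_thickness(th, mask, centroid, 40.0, 1.4)
        assert abs(val - t * 1.4) <= 1.5 * 1.4

    def test_plate_vs_rod_discrimination(self):
        plate = np.zeros((80, 80, 80), bool)
        plate[20:60] = True  # 56 um plate at 1.4 um voxels... thickness 40 vox
        zz, yy, xx = np.mgrid[0:80, 0:80, 0:80]
        rod = (yy - 40) ** 2 + (xx - 40) ** 2 <= 14**2  # diameter 28 vox
        c = np.array([40 * 1.4] * 3)
        th_p = thickness_map(plate, 1.4, coarse=True)
        th_r = thickness_map(rod, 1.4, coarse=True)
        tp = local_trabecular_thickness(th_p, plate, c, 30.0, 1.4)
        tr = local_trabecular_thickness(th_r, rod, c, 30.0, 1.4)
        assert tp > tr

    def test_centroid_far_from_bone_raises(self):
        mask = np.zeros((64, 64, 64), bool)
        mask[2:6] = True
        th = thickness_map(mask, 1.4)
        far = np.array([60 * 1.4, 32 * 1.4, 32 * 1.4])  # ~75 um from the slab
        with pytest.raises(SiteError):
            local_trabecular_thickness(th, mask, far, 10.0, 1.4)

    def test_trabecular_shape_classes(self):
        c = np.array([40 * 1.4] * 3)
        plate = np.zeros((80, 80, 80), bool)
        plate[30:50] = True
        assert trabecular_shape(plate, c, 40.0, 1.4) == "plate"
        zz, yy, xx = np.mgrid[0:80, 0:80, 0:80]
        rod = (yy - 40) ** 2 + (xx - 40) ** 2 <= 10**2
        assert trabecular_shape(rod, c, 40.0, 1.4) == "rod"
        # Y-junction: three coplanar rods meeting at the centre.
        junction = np.zeros((80, 80, 80), bool)
        for ang in (90, 210, 330):
            u = np.array([0.0, np.sin(np.deg2rad(ang)), np.cos(np.deg2rad(ang))])
            t = (yy - 40) * u[1] + (xx - 40) * u[2]
            rho2 = (zz - 40) ** 2 + (yy - 40 - t * u[1]) ** 2 + (xx - 40 - t * u[2]) ** 2
            junction |= (rho2 <= 8**2) & (t >= -2) & (t <= 38)
        assert trabecular_shape(junction, c, 40.0, 1.4) == "junction"
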