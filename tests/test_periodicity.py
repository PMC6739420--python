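"""Honeycomb-module segmentation and lattice-spacing statistics."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import cKDTree

from collic.periodicity import (
    CentroidSet,
    DensityVolume,
    detect_off_centroids,
    dog_filter,
    honeycomb_spacing,
    project_volume,
    spacing_statistics,
)
from collic.synthetic import generate_honeycomb_volume

VOX = 10.0


def pit_image(centers_um, extent_um=1280.0, pixel_um=VOX, sigma_um=13.0,
              wall=100.0, depth=90.0):
    """Flat field with Gaussian density pits at given (y, x) centers."""
    n = int(extent_um / pixel_um)
    yy = (np.arange(n) + 0.5) * pixel_um
    gy, gx = np.meshgrid(yy, yy, indexing="ij")
    img = np.full((n, n), wall)
    for cy, cx in centers_um:
        img -= depth * np.exp(-((gy - cy) ** 2 + (gx - cx) ** 2) / (2 * sigma_um**2))
    return np.clip(img, 0, None)


class TestProjectVolume:
    def test_uniform_volume_projects_uniform(self):
        vol = DensityVolume(np.full((4, 8, 8), 3.0), (VOX, VOX, VOX))
        img, px = project_volume(vol, "dv")
        assert np.all(img == 3.0)
        assert px == (VOX, VOX)

    def test_single_bright_voxel(self):
        data = np.zeros((4, 8, 8))
        data[2, 5, 3] = 9.0
        vol = DensityVolume(data, (VOX, VOX, VOX))
        img, _ = project_volume(vol, "dv")
        assert img[5, 3] == 9.0
        assert img.sum() == 9.0

    def test_synthetic_barrel_walls_at_known_positions(self):
        vol, truth = generate_honeycomb_volume(130.0, 0.0, VOX, (4, 96, 96), seed=0)
        img, px = project_volume(DensityVolume(vol, (VOX, VOX, VOX)), "dv")
        # density at each generated center is at a local low
        for cy, cx in truth.centers_um:
            r, c = int(cy / VOX), int(cx / VOX)
            assert img[r, c] < img.mean()

    def test_bad_axis_rejected(self):
        vol = DensityVolume(np.zeros((2, 4, 4)), (VOX, VOX, VOX))
        with pytest.raises(ValueError):
            project_volume(vol, "sideways")


class TestDogFilter:
    def test_constant_image_zero_response(self):
        out = dog_filter(np.full((32, 32), 5.0), 20.0, 60.0, (VOX, VOX))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_blob_of_intermediate_scale_peaks_at_center(self):
        img = pit_image([(640.0, 640.0)], sigma_um=35.0)
        out = dog_filter(img, 26.0, 78.0, (VOX, VOX))
        r, c = np.unravel_index(np.argmin(out), out.shape)
        assert abs((r + 0.5) * VOX - 640.0) <= VOX
        assert abs((c + 0.5) * VOX - 640.0) <= VOX

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        fa = dog_filter(a, 20.0, 60.0, (VOX, VOX))
        fb = dog_filter(b, 20.0, 60.0, (VOX, VOX))
        fc = dog_filter(2 * a + 3 * b, 20.0, 60.0, (VOX, VOX))
        assert np.allclose(fc, 2 * fa + 3 * fb, atol=1e-9)

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((8, 8)), 60.0, 20.0, (VOX, VOX))


class TestDetectOffCentroids:
    def test_two_pits_130_apart(self):
        centers = [(640.0, 575.0), (640.0, 705.0)]
        img = pit_image(centers, sigma_um=30.0)
        filt = dog_filter(img, 26.0, 78.0, (VOX, VOX))
        cents = detect_off_centroids(filt, (VOX, VOX))
        assert cents.n == 2
        assert cents.nn_dist_um[0] == pytest.approx(130.0, abs=3.0)

    def test_single_pit_rejected(self):
        img = pit_image([(640.0, 640.0)], sigma_um=30.0)
        filt = dog_filter(img, 26.0, 78.0, (VOX, VOX))
        with pytest.raises(ValueError, match="insufficient centroids"):
            detect_off_centroids(filt, (VOX, VOX))

    def test_perfect_lattice_nn_distances_equal_constant(self):
        vol, truth = generate_honeycomb_volume(130.0, 0.0, VOX, (4, 160, 160), seed=0)
        stats_, cents = honeycomb_spacing(DensityVolume(vol, (VOX,) * 3))
        inner = cents.nn_dist_um[
            (cents.coords_um.min(axis=1) > 200) & (cents.coords_um.max(axis=1) < 1400)
        ]
        assert np.allclose(inner, 130.0, atol=5.0)

    def test_translation_equivariance(self):
        vol, truth = generate_honeycomb_volume(130.0, 0.0, VOX, (4, 128, 128), seed=0)
        img = vol[0]
        shift = 3  # pixels
        shifted = np.roll(img, shift, axis=1)
        f1 = dog_filter(img, 26.0, 78.0, (VOX, VOX))
        f2 = dog_filter(shifted, 26.0, 78.0, (VOX, VOX))
        c1 = detect_off_centroids(f1, (VOX, VOX))
        c2 = detect_off_centroids(f2, (VOX, VOX))
        # interior centroids move by exactly the applied shift
        t1 = cKDTree(c1.coords_um + [0.0, shift * VOX])
        d, _ = t1.query(c2.coords_um, k=1)
        interior = (c2.coords_um[:, 1] > 200) & (c2.coords_um[:, 1] < 1080)
        assert np.median(d[interior]) < 2.0

    def test_rotation_preserves_nn_multiset(self):
        vol, _ = generate_honeycomb_volume(130.0, 4.0, VOX, (4, 128, 128), seed=1)
        img = vol[0]
        f1 = dog_filter(img, 26.0, 78.0, (VOX, VOX))
        f2 = dog_filter(np.rot90(img), 26.0, 78.0, (VOX, VOX))
        c1 = detect_off_centroids(f1, (VOX, VOX))
        c2 = detect_off_centroids(f2, (VOX, VOX))
        assert c1.n == c2.n
        assert np.allclose(np.sort(c1.nn_dist_um), np.sort(c2.nn_dist_um), atol=1e-6)


class TestSpacingStatistics:
    def test_equal_distances(self):
        cents = CentroidSet(np.zeros((12, 2)), np.full(12, 130.0))
        s = spacing_statistics(cents)
        assert s.mean_um == 130.0
        assert s.sem_um == 0.0

    def test_jittered_lattice_recovery(self):
        vol, truth = generate_honeycomb_volume(130.0, 7.0, VOX, (4, 192, 192), seed=2)
        s, cents = honeycomb_spacing(DensityVolume(vol, (VOX,) * 3))
        d, _ = cKDTree(truth.centers_um).query(truth.centers_um, k=2)
        true_mean = d[:, 1].mean()
        assert s.mean_um == pytest.approx(true_mean, abs=7.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, size=(30, 2))
        d, _ = cKDTree(pts).query(pts, k=2)
        a = spacing_statistics(CentroidSet(pts, d[:, 1]))
        d2, _ = cKDTree(2 * pts).query(2 * pts, k=2)
        b = spacing_statistics(CentroidSet(2 * pts, d2[:, 1]))
        assert b.mean_um == pytest.approx(2 * a.mean_um, rel=1e-12)

    def test_poisson_points_show_no_spurious_lattice(self):
        """On homogeneous Poisson pit images the detected NN distances
        follow the 2D Poisson nearest-neighbor law (no imposed spacing).

        NN distances are taken for interior centroids only, so the
        infinite-domain law F(d) = 1 - exp(-lambda pi d^2) applies without
        window-edge censoring; distances are pooled over several point
        realizations, and per-realization the detected distribution is also
        compared against the generated points' own NN distribution.
        """
        extent, n_pts = 2560.0, 90
        lam = n_pts / (extent - 80.0) ** 2
        pooled = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            centers = rng.uniform(40.0, extent - 40.0, size=(n_pts, 2))
            img = pit_image(centers, extent_um=extent, sigma_um=10.0)
            filt = dog_filter(img, 10.0, 30.0, (VOX, VOX))
            cents = detect_off_centroids(filt, (VOX, VOX), threshold_percentile=3.0)
            core = np.all(
                (cents.coords_um > 300) & (cents.coords_um < extent - 300), axis=1
            )
            pooled.append(1.0 - np.exp(-lam * np.pi * cents.nn_dist_um[core] ** 2))
            d, _ = cKDTree(centers).query(centers, k=2)
            tcore = np.all((centers > 300) & (centers < extent - 300), axis=1)
            two = stats.ks_2samp(cents.nn_dist_um[core], d[tcore, 1])
            assert two.pvalue > 0.01
        assert stats.kstest(np.concatenate(pooled), "uniform").pvalue > 0.01
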