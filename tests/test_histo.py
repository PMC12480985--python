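"""Concentric-ring binning, normalization, centroid detection and densities."""

import numpy as np
import pytest

from imequant.histo import (
    BACKGROUND_BIN,
    ImplantImage,
    N_BINS,
    bin_intensity,
    density_profile,
    detect_centroids,
    detect_hole,
    normalize_profile,
    ring_labels,
)
from imequant.synth.ihc import IhcImageConfig, gen_ihc_image, ramp_profile

MPP = 2.0  # coarse test-scale pixels: 2 um/px keeps fixtures small


def disk_mask(size, radius_px, center=None):
    c = (size - 1) / 2.0 if center is None else center
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - c, xx - c) <= radius_px


@pytest.fixture(scope="module")
def small_labels():
    # hole radius 100 um (50 px), image 800 px (1600 um) across
    hole = disk_mask(800, 50)
    return hole, ring_labels(hole, MPP)


class TestRingLabels:
    def test_geometry_of_bins(self, small_labels):
        hole, labels = small_labels
        c = (800 - 1) / 2.0
        # pixel ~75 um from the hole edge lies in bin 1
        px = int(c + (100 + 75) / MPP)
        assert labels[int(c), px] == 1
        # inside the hole: unlabeled
        assert labels[int(c), int(c)] == -1
        # well beyond 650 um: unlabeled
        px_far = int(c) + int((100 + 660) / MPP)
        assert labels[int(c), px_far] == -1
        assert labels.max() == N_BINS - 1

    def test_outer_boundary_is_half_open(self):
        # single-pixel hole with 50 um pixels: distances are exact multiples
        hole = np.zeros((31, 31), dtype=bool)
        hole[15, 15] = True
        labels = ring_labels(hole, 50.0)
        assert labels[15, 15 + 12] == 12  # 600 um -> last bin
        assert labels[15, 15 + 13] == -1  # exactly 650 um -> excluded

    def test_area_partition(self, small_labels):
        hole, labels = small_labels
        n_hole = hole.sum()
        n_binned = (labels >= 0).sum()
        n_beyond = ((labels == -1) & ~hole).sum()
        assert n_hole + n_binned + n_beyond == labels.size

    def test_hole_near_border_rejected(self):
        hole = disk_mask(200, 20, center=30)
        with pytest.raises(ValueError):
            ring_labels(hole, MPP)

    def test_empty_hole_rejected(self):
        with pytest.raises(ValueError):
            ring_labels(np.zeros((100, 100), dtype=bool), MPP)


class TestBinIntensity:
    def test_flat_image_every_bin_equal(self, small_labels):
        hole, labels = small_labels
        img = ImplantImage(np.full(hole.shape, 7.0), hole, MPP, "GFAP")
        prof = bin_intensity(img, labels)
        assert np.allclose(prof.mean_raw, 7.0)

    def test_artifact_pixels_excluded(self, small_labels):
        hole, labels = small_labels
        intensity = np.full(hole.shape, 5.0)
        artifact = np.zeros(hole.shape, dtype=bool)
        sel = labels == 0
        rows, cols = np.nonzero(sel)
        half = len(rows) // 2
        artifact[rows[:half], cols[:half]] = True
        intensity[artifact] = 1e6
        img = ImplantImage(intensity, hole, MPP, "CD68", artifact_mask=artifact)
        prof = bin_intensity(img, labels)
        assert prof.mean_raw[0] == pytest.approx(5.0)
        assert prof.n_pixels[0] == sel.sum() - half

    def test_matches_bruteforce_pixel_loop(self):
        rng = np.random.default_rng(0)
        hole = disk_mask(64, 3)
        labels = ring_labels(hole, 12.0, max_dist_um=300.0)
        intensity = rng.uniform(0, 100, size=(64, 64))
        artifact = rng.random((64, 64)) < 0.1
        img = ImplantImage(intensity, hole, 12.0, "IgG", artifact_mask=artifact)
        prof = bin_intensity(img, labels)
        for b in range(N_BINS):
            vals = [intensity[r, c]
                    for r in range(64) for c in range(64)
                    if labels[r, c] == b and not artifact[r, c]]
            if vals:
                assert prof.mean_raw[b] == pytest.approx(np.mean(vals))
                assert prof.n_pixels[b] == len(vals)
            else:
                assert np.isnan(prof.mean_raw[b])


class TestNormalization:
    def test_marker_factor_maps_background(self, small_labels):
        hole, labels = small_labels
        img = ImplantImage(np.full(hole.shape, 3.0), hole, MPP, "GFAP")
        prof = normalize_profile(bin_intensity(img, labels))
        assert np.allclose(prof.normalized, 1.0)  # constitutive marker
        img = ImplantImage(np.full(hole.shape, 3.0), hole, MPP, "CD68")
        prof = normalize_profile(bin_intensity(img, labels))
        assert np.allclose(prof.normalized, 0.0)  # absent-in-health marker

    def test_double_background_with_zero_factor_is_one(self, small_labels):
        hole, labels = small_labels
        intensity = np.full(hole.shape, 4.0)
        intensity[labels == BACKGROUND_BIN] = 2.0
        img = ImplantImage(intensity, hole, MPP, "IgG")
        prof = normalize_profile(bin_intensity(img, labels))
        assert prof.normalized[0] == pytest.approx(1.0)

    def test_scale_invariance(self, small_labels):
        hole, labels = small_labels
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, size=hole.shape)
        p1 = normalize_profile(bin_intensity(ImplantImage(base, hole, MPP, "GFAP"), labels))
        p2 = normalize_profile(
            bin_intensity(ImplantImage(base * 37.0, hole, MPP, "GFAP"), labels)
        )
        assert np.allclose(p1.normalized, p2.normalized)

    def test_nonpositive_background_rejected(self, small_labels):
        hole, labels = small_labels
        img = ImplantImage(np.zeros(hole.shape), hole, MPP, "GFAP")
        with pytest.raises(ValueError):
            normalize_profile(bin_intensity(img, labels))


class TestCentroidsAndDensity:
    def test_blank_image_yields_no_centroids(self):
        hole = disk_mask(800, 50)
        img = ImplantImage(np.zeros(hole.shape, dtype=np.uint16), hole, MPP, "NeuN")
        assert len(detect_centroids(img)) == 0

    def test_rendered_somata_are_recovered(self):
        cfg = IhcImageConfig(
            marker="NeuN", image_size=800, microns_per_pixel=2.0, hole_radius_um=60.0,
            profile=np.ones(N_BINS), background_density_mm2=30.0, noise_sigma=20.0, seed=5,
        )
        image, truth = gen_ihc_image(cfg)
        detected = detect_centroids(image, soma_diameter_um=cfg.soma_diameter_um)
        assert len(detected) == pytest.approx(len(truth.centroids), abs=2)

    def test_uniform_process_count_within_poisson_band(self):
        cfg = IhcImageConfig(
            marker="NeuN", image_size=800, microns_per_pixel=2.0, hole_radius_um=60.0,
            profile=np.ones(N_BINS), background_density_mm2=100.0, seed=8,
        )
        _, truth = gen_ihc_image(cfg)
        hole_area = np.pi * 0.06**2
        usable = np.pi * (0.06 + 0.65) ** 2 - hole_area  # mm^2 out to 650 um
        expected = 100.0 * usable
        assert abs(len(truth.centroids) - expected) <= 3 * np.sqrt(expected)

    def test_uniform_density_normalizes_to_one(self):
        cfg = IhcImageConfig(
            marker="NeuN", image_size=900, microns_per_pixel=2.0, hole_radius_um=100.0,
            profile=np.ones(N_BINS), background_density_mm2=2000.0, seed=3,
        )
        image, truth = gen_ihc_image(cfg)
        labels = ring_labels(image.hole_mask, 2.0)
        prof = density_profile(truth.centroids, labels, 2.0)
        assert np.nanmax(np.abs(prof.normalized - 1.0)) < 0.4  # ~3 sigma Poisson band
        assert prof.normalized[BACKGROUND_BIN] == 1.0

    def test_centroid_inside_artifact_not_counted(self):
        hole = disk_mask(800, 50)
        labels = ring_labels(hole, MPP)
        artifact = np.zeros(hole.shape, dtype=bool)
        artifact[400:421, 500:521] = True  # patch inside the labeled rings
        pts = np.array([[410.0, 510.0],  # inside the artifact patch
                        [400.0, 740.0],  # bin 11
                        [400.0, 750.0]])  # background bin
        prof = density_profile(pts, labels, MPP, artifact)
        assert prof.counts.sum() == 2

    def test_pixel_size_invariance_of_density(self):
        # same physical scene sampled at two pixel sizes
        rng = np.random.default_rng(6)
        phys_pts_um = np.column_stack(
            [rng.uniform(-600, 600, 300), rng.uniform(-600, 600, 300)]
        )
        out = {}
        for mpp, size in [(2.0, 800), (4.0, 400)]:
            hole = disk_mask(size, 50 * 2.0 / mpp)
            labels = ring_labels(hole, mpp)
            c = (size - 1) / 2.0
            pts = phys_pts_um / mpp + c
            ok = (pts >= 0).all(axis=1) & (pts < size).all(axis=1)
            try:
                prof = density_profile(pts[ok], labels, mpp)
                out[mpp] = prof.density
            except ValueError:
                pytest.skip("background bin empty in this draw")
        ratio = out[2.0] / out[4.0]
        assert np.nanmedian(np.abs(ratio - 1.0)) < 0.25  # discretization-limited

    def test_empty_background_rejected(self, small_labels):
        hole, labels = small_labels
        pts = np.array([[399.0, 460.0]])  # a single centroid near the hole
        with pytest.raises(ValueError):
            density_profile(pts, labels, MPP)


class TestHoleDetection:
    def test_synthetic_disk_recovered(self):
        truth = disk_mask(400, 60)
        img = np.where(truth, 50.0, 2000.0) + np.random.default_rng(2).normal(0, 20, truth.shape)
        mask = detect_hole(img, quantile=0.12)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_user_mask_wins(self):
        user = disk_mask(100, 10)
        assert detect_hole(np.zeros((100, 100)), hole_mask=user) is user

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError):
            detect_hole(np.full((100, 100), 5.0))
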