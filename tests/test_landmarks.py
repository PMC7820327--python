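"""Landmark detection: thresholds, candidates, ellipse fit, macula search."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwfdr import landmarks as lmk
from uwfdr import synthetic as syn
from uwfdr.errors import DegenerateMaskError, FormatError, ValidationError


def rgb(h, w, value=(0, 0, 0)):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = value
    return img


class TestGaussianWeightGreen:
    def test_center_weight_is_one(self):
        img = rgb(101, 101, (0, 200, 0))
        out = lmk.gaussian_weight_green(img, sigma_frac=0.25)
        assert out[50, 50] == pytest.approx(200.0)

    def test_distance_s_gives_exp_half(self):
        img = rgb(101, 101, (0, 100, 0))
        s = 0.25 * 101
        out = lmk.gaussian_weight_green(img, sigma_frac=0.25)
        # sample a pixel at distance ~s right of center
        col = int(round(50 + s))
        val = out[50, col]
        d = col - 50
        assert val == pytest.approx(100 * np.exp(-d ** 2 / (2 * s ** 2)), rel=1e-9)

    def test_corner_suppressed_below_disc_range(self):
        # bright border pixels cannot reach a disc-level threshold after weighting
        img = rgb(400, 400, (0, 255, 0))
        out = lmk.gaussian_weight_green(img, sigma_frac=0.25)
        s = 0.25 * 400
        corner_d2 = 2 * (199.5 ** 2)
        expected = 255 * np.exp(-corner_d2 / (2 * s ** 2))
        assert out[0, 0] == pytest.approx(expected, rel=1e-9)
        assert out[0, 0] < 50  # far below any plausible disc tau

    def test_rejects_non_rgb(self):
        with pytest.raises(FormatError):
            lmk.gaussian_weight_green(np.zeros((10, 10), dtype=np.uint8))


class TestEstimateThreshold:
    def test_zero_variance(self):
        stats = lmk.estimate_threshold([np.array([100, 100, 100])])
        assert (stats.mu, stats.sigma, stats.tau) == (100.0, 0.0, 100.0)

    def test_population_sd_convention(self):
        stats = lmk.estimate_threshold([np.array([90.0, 110.0])])
        assert stats.mu == pytest.approx(100.0)
        assert stats.sigma == pytest.approx(10.0)  # population SD, not sample
        assert stats.tau == pytest.approx(90.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            lmk.estimate_threshold([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.lists(st.integers(0, 255), min_size=1, max_size=30),
                    min_size=1, max_size=5))
    def test_tau_identity(self, patches):
        stats = lmk.estimate_threshold([np.array(p, dtype=float) for p in patches])
        assert stats.tau == stats.mu - stats.sigma

    def test_tau_below_disc_centers_on_synthetic(self, ref_pairs, ref_stats):
        centers = []
        for img, mask in ref_pairs:
            weighted = lmk.gaussian_weight_green(img, 0.35)
            centers.append(weighted[mask > 0].max())
        assert ref_stats.tau < min(centers)


def blob_image(centers, radius=20, value=(180, 230, 40), shape=(400, 500)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for (r, c) in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = value
    return img


class TestFindCandidates:
    def test_nearby_blobs_merge(self):
        img = blob_image([(200, 200), (200, 300)])
        stats = lmk.ThresholdStats(mu=150.0, sigma=20.0)
        cands = lmk.find_candidates(img, stats, min_area=10, max_area=1e5, merge_dist=150)
        assert len(cands) == 1

    def test_distant_blobs_stay_separate(self):
        # low tau: both blobs survive the center-weighting attenuation
        img = blob_image([(100, 100), (300, 400)])
        stats = lmk.ThresholdStats(mu=60.0, sigma=20.0)
        cands = lmk.find_candidates(img, stats, min_area=10, max_area=1e5, merge_dist=150)
        assert len(cands) == 2

    def test_fusion_is_convex_combination(self):
        img = blob_image([(200, 250)], radius=25)
        stats = lmk.ThresholdStats(mu=150.0, sigma=20.0)
        (cand,) = lmk.find_candidates(img, stats, min_area=10, max_area=1e5,
                                      merge_dist=150)
        expected = 0.75 * np.asarray(cand.green_center) + 0.25 * np.asarray(cand.red_center)
        assert cand.fused_center == pytest.approx(tuple(expected))

    def test_fused_center_worked_example(self):
        cand = lmk.CandidateRegion(pixel_coords=np.array([[100, 100]]),
                                   green_center=(100.0, 100.0),
                                   red_center=(120.0, 100.0))
        assert cand.fused_center == (105.0, 100.0)

    def test_no_survivors_is_empty_list(self):
        img = rgb(200, 200)
        stats = lmk.ThresholdStats(mu=150.0, sigma=20.0)
        assert lmk.find_candidates(img, stats, min_area=10, max_area=1e5,
                                   merge_dist=150) == []

    def test_single_disc_candidate_near_truth(self, clean_set, ref_stats):
        img, truth, _ = clean_set[0]
        cands = lmk.find_candidates(img, ref_stats)
        assert len(cands) == 1
        err = np.hypot(cands[0].fused_center[0] - truth.disc_center[0],
                       cands[0].fused_center[1] - truth.disc_center[1])
        assert err <= 5

    def test_merge_is_order_independent(self):
        rng = np.random.default_rng(0)
        centroids = rng.uniform(0, 500, size=(8, 2))
        base = lmk._merge_components(centroids, 120.0)
        base_sets = sorted(tuple(g) for g in base)
        for _ in range(5):
            perm = rng.permutation(8)
            merged = lmk._merge_components(centroids[perm], 120.0)
            relabeled = sorted(tuple(sorted(perm[i] for i in g)) for g in merged)
            assert relabeled == base_sets


class TestCropCandidate:
    def test_uniform_inside_circle_zero_corners(self):
        img = rgb(800, 800, (90, 90, 90))
        patch = lmk.crop_candidate(img, (400, 400), 200, 128)
        assert patch[64, 64].tolist() == [90, 90, 90]
        assert patch[0, 0].tolist() == [0, 0, 0]

    def test_edge_center_zero_padded(self):
        img = rgb(400, 400, (90, 90, 90))
        patch = lmk.crop_candidate(img, (200, 10), 200, 200)
        assert patch[:, :40].max() == 0  # left half is out-of-bounds padding

    def test_output_size_contract(self):
        img = rgb(700, 700, (50, 50, 50))
        patch = lmk.crop_candidate(img, (350, 350), 614, 512)
        assert patch.shape == (512, 512, 3)

    def test_center_outside_rejected(self):
        with pytest.raises(ValidationError):
            lmk.crop_candidate(rgb(100, 100), (200, 50), 50, 32)


def brute_force_moments(mask):
    """Independent oracle: explicit sums over foreground pixels."""
    ys, xs = np.nonzero(mask)
    n = len(ys)
    cy, cx = ys.sum() / n, xs.sum() / n
    dy, dx = ys - cy, xs - cx
    mu20 = (dy * dy).sum() / n
    mu02 = (dx * dx).sum() / n
    mu11 = (dy * dx).sum() / n
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11 ** 2)
    l1 = (mu20 + mu02 + common) / 2
    l2 = (mu20 + mu02 - common) / 2
    return (cy, cx), (2 * np.sqrt(l1), 2 * np.sqrt(l2))


class TestFitEllipse:
    def test_disk_recovery(self):
        mask = syn.ellipse_mask((200, 200), (100, 100), (40, 40), 0)
        (center, axes, _angle) = lmk.fit_ellipse(mask)
        assert center == pytest.approx((100, 100), abs=0.5)
        assert axes[0] == pytest.approx(40, abs=1)
        assert axes[1] == pytest.approx(40, abs=1)

    def test_axis_aligned_ellipse(self):
        mask = syn.ellipse_mask((300, 300), (150, 150), (50, 25), 0)
        center, axes, angle = lmk.fit_ellipse(mask)
        assert min(angle, 180 - angle) < 2  # ~0 mod 180
        assert axes[0] == pytest.approx(50, rel=0.02)
        assert axes[1] == pytest.approx(25, rel=0.02)

    @pytest.mark.parametrize("params", [
        ((120, 140), (45, 30), 30.0),
        ((100, 100), (60, 20), 120.0),
        ((90, 160), (35, 33), 75.0),
    ])
    def test_matches_brute_force_oracle(self, params):
        center, axes, angle = params
        mask = syn.ellipse_mask((260, 300), center, axes, angle)
        got_c, got_axes, got_angle = lmk.fit_ellipse(mask)
        ref_c, ref_axes = brute_force_moments(mask)
        assert got_c == pytest.approx(ref_c, abs=1e-9)
        assert got_axes == pytest.approx(ref_axes, rel=1e-9)
        assert got_axes[0] == pytest.approx(axes[0], rel=0.03)
        diff = abs(got_angle - angle) % 180
        assert min(diff, 180 - diff) < 3

    def test_tiny_mask_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2] = mask[2, 3] = mask[3, 2] = mask[3, 3] = True
        with pytest.raises(DegenerateMaskError):
            lmk.fit_ellipse(mask)


class TestDetectMacula:
    def test_unique_black_pixel_wins(self):
        img = rgb(200, 600, (120, 120, 120))
        img[102, 150] = (0, 0, 0)
        got = lmk.detect_macula(img, (100, 400), h_range=300, v_range=10,
                                exclusion_radius=30)
        assert got == (102.0, 150.0)

    def test_window_clipped_at_border(self):
        img = rgb(100, 200, (120, 120, 120))
        img[52, 5] = (0, 0, 0)
        got = lmk.detect_macula(img, (50, 20), h_range=500, v_range=10,
                                exclusion_radius=5)
        assert got == (52.0, 5.0)

    def test_window_outside_image_rejected(self):
        img = rgb(100, 100)
        with pytest.raises(ValidationError):
            lmk.detect_macula(img, (200, 50), h_range=10, v_range=10)

    def test_recovery_on_synthetic(self, clean_set, ref_stats):
        errors = []
        for img, truth, _ in clean_set:
            det = lmk.detect_landmarks(img, ref_stats)
            errors.append(np.hypot(det.macula_center[0] - truth.macula_center[0],
                                   det.macula_center[1] - truth.macula_center[1]))
        assert np.median(errors) <= 10


def test_landmark_recovery_on_clean_images(clean_set, ref_stats):
    """Disc <= 5 px and macula <= 10 px on clean synthetic images."""
    ok = 0
    for img, truth, _ in clean_set:
        det = lmk.detect_landmarks(img, ref_stats)
        derr = np.hypot(det.disc_center[0] - truth.disc_center[0],
                        det.disc_center[1] - truth.disc_center[1])
        merr = np.hypot(det.macula_center[0] - truth.macula_center[0],
                        det.macula_center[1] - truth.macula_center[1])
        ok += (derr <= 5) and (merr <= 10)
    assert ok >= 0.95 * len(clean_set)
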