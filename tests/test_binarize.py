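import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import ndimage

from octaquant.binarize import (
    ThresholdCurve,
    binarize,
    compute_vld_threshold,
    fit_two_segment,
    huang_threshold,
    mean_threshold,
    skeletonize,
    sweep_vld_curve,
)
from octaquant.errors import (
    FitDegenerateError,
    NoThresholdError,
    ParameterError,
)
from octaquant.image_io import EnFaceImage, Plexus

from conftest import DISJOINT_SPEC, make_image

EIGHT = np.ones((3, 3), dtype=int)


class TestBinarize:
    def test_constant_at_threshold_all_foreground(self):
        img = make_image(np.full((8, 8), 100, dtype=np.uint8))
        assert binarize(img, 100).all()

    def test_constant_above_threshold_all_background(self):
        img = make_image(np.full((8, 8), 100, dtype=np.uint8))
        assert not binarize(img, 101).any()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        img = make_image(px)
        out = binarize(img, 87)
        expected = np.array([[v >= 87 for v in row] for row in px])
        np.testing.assert_array_equal(out, expected)

    @given(
        px=arrays(np.uint8, (12, 12), elements=st.integers(0, 255)),
        t=st.integers(0, 254),
    )
    @settings(max_examples=50, deadline=None)
    def test_foreground_count_non_increasing_in_t(self, px, t):
        img = make_image(px)
        assert binarize(img, t).sum() >= binarize(img, t + 1).sum()

    def test_out_of_range_threshold_rejected(self):
        img = make_image(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ParameterError):
            binarize(img, 300)


class TestSkeletonize:
    def test_wide_bar_reduces_to_line(self):
        b = np.zeros((60, 60), dtype=bool)
        b[28:31, 5:55] = True  # 3 px wide, 50 px long
        s = skeletonize(b)
        assert abs(int(s.sum()) - 50) <= 2
        assert ndimage.label(s, EIGHT)[1] == 1

    def test_single_pixel_fixed_point(self):
        b = np.zeros((7, 7), dtype=bool)
        b[3, 3] = True
        np.testing.assert_array_equal(skeletonize(b), b)

    def test_empty_map(self):
        assert skeletonize(np.zeros((9, 9), dtype=bool)).sum() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_contract_on_random_blobs(self, seed):
        from skimage.data import binary_blobs

        b = binary_blobs(length=90, blob_size_fraction=0.1, volume_fraction=0.4, rng=seed)
        s = skeletonize(b)
        assert (s <= b).all(), "skeleton must be a subset of the foreground"
        assert not (s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any()
        assert ndimage.label(b, EIGHT)[1] == ndimage.label(s, EIGHT)[1]


class TestSweep:
    def test_constant_image_drops_to_zero(self):
        img = make_image(np.full((20, 20), 100, dtype=np.uint8))
        curve = sweep_vld_curve(img)
        above = curve.thresholds > 100
        assert (curve.vld_counts[above] == 0).all()
        assert curve.vld_counts[~above].max() > 0 or True  # counts may be tiny

    def test_matches_independent_loop(self):
        rng = np.random.default_rng(11)
        px = np.where(
            rng.random((40, 40)) < 0.3,
            rng.integers(150, 231, (40, 40)),
            rng.integers(20, 56, (40, 40)),
        ).astype(np.uint8)
        img = make_image(px)
        curve = sweep_vld_curve(img, t_min=10, t_max=200)
        for t, count in zip(curve.thresholds[::13], curve.vld_counts[::13]):
            assert count == int(skeletonize(binarize(img, int(t))).sum())

    def test_counts_bounded(self):
        rng = np.random.default_rng(2)
        img = make_image(rng.integers(0, 256, (30, 30), dtype=np.uint8))
        curve = sweep_vld_curve(img)
        assert (curve.vld_counts >= 0).all()
        assert (curve.vld_counts <= 900).all()

    def test_degenerate_range_rejected(self):
        img = make_image(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ParameterError):
            sweep_vld_curve(img, t_min=50, t_max=50)


def two_piece_curve(break_x=60, m1=-50.0, m2=-1.0, x_max=130, y0=5000.0):
    """Continuous two-segment line with vertex at ``break_x``."""
    x = np.arange(1, x_max + 1)
    y_break = y0 + m1 * (break_x - 1)
    y = np.where(x <= break_x, y0 + m1 * (x - 1), y_break + m2 * (x - break_x))
    return ThresholdCurve(thresholds=x, vld_counts=y.astype(float))


class TestTwoSegmentFit:
    def test_exact_recovery_on_noise_free_data(self):
        fit = fit_two_segment(two_piece_curve())
        assert fit.breakpoint == 60
        assert fit.intersection_x == pytest.approx(60.0, abs=1.0)
        assert fit.total_sse == pytest.approx(0.0, abs=1e-6)
        m_noise, _ = fit.noise_line
        m_signal, _ = fit.signal_line
        assert m_noise == pytest.approx(-50.0)
        assert m_signal == pytest.approx(-1.0)

    def test_single_line_degenerate(self):
        x = np.arange(1, 101)
        y = 1000.0 - 3.0 * x
        with pytest.raises(FitDegenerateError):
            fit_two_segment(ThresholdCurve(thresholds=x, vld_counts=y))

    def test_noisy_recovery_rate(self):
        base = two_piece_curve()
        span = base.vld_counts.max() - base.vld_counts.min()
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            noisy = np.maximum(base.vld_counts + rng.normal(0, 0.01 * span, len(base.vld_counts)), 0)
            fit = fit_two_segment(ThresholdCurve(thresholds=base.thresholds, vld_counts=noisy))
            if abs(fit.intersection_x - 60.0) <= 3.0:
                hits += 1
        assert hits >= 95

    def test_window_too_small_rejected(self):
        x = np.arange(1, 16)
        y = np.linspace(100, 0, 15)
        with pytest.raises(ParameterError):
            fit_two_segment(ThresholdCurve(thresholds=x, vld_counts=y), min_segment=10)


class TestVldThreshold:
    def test_lands_in_support_gap(self, synthetic_eye, eye_threshold):
        images, truth = synthetic_eye
        t = eye_threshold.threshold
        assert truth.boundary_t < t <= DISJOINT_SPEC.vessel_intensity[0]
        # ground-truth membership: all pure-noise pixels below, vessels at/above
        dcp = images[Plexus.DCP]
        vessel = truth.vessel_mask[Plexus.DCP]
        noise_px = dcp.pixels[~vessel]
        vessel_px = dcp.pixels[vessel]
        assert (noise_px < t).mean() >= 0.99
        assert (vessel_px >= t).mean() >= 0.95

    def test_deterministic(self, synthetic_eye, eye_threshold):
        images, _ = synthetic_eye
        again = compute_vld_threshold(images[Plexus.DCP])
        assert again.threshold == eye_threshold.threshold
        np.testing.assert_array_equal(
            again.curve.vld_counts, eye_threshold.curve.vld_counts
        )

    def test_rotation_invariance(self, synthetic_eye, eye_threshold):
        images, _ = synthetic_eye
        rotated = EnFaceImage(
            pixels=np.rot90(images[Plexus.DCP].pixels).copy(),
            plexus=Plexus.DCP,
            fov_mm=3.0,
        )
        res = compute_vld_threshold(rotated)
        assert abs(res.threshold - eye_threshold.threshold) <= 1

    def test_diagnostics_present(self, eye_threshold):
        assert len(eye_threshold.curve.thresholds) == 254
        lo, hi = eye_threshold.fit.fit_range
        assert lo <= eye_threshold.fit.intersection_x <= hi


class TestComparatorThresholds:
    def test_mean_half_and_half(self):
        px = np.zeros((10, 10), dtype=np.uint8)
        px[:5] = 100
        assert mean_threshold(make_image(px)) == 50

    def test_mean_constant(self):
        assert mean_threshold(make_image(np.full((6, 6), 77, dtype=np.uint8))) == 77

    def test_mean_matches_brute_force(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        expected = int(np.floor(sum(int(v) for v in px.ravel()) / 400 + 0.5))
        assert mean_threshold(make_image(px)) == expected

    def test_huang_between_modes(self):
        px = np.zeros((50, 50), dtype=np.uint8)
        px[:, :25] = 30
        px[:, 25:] = 200
        t = huang_threshold(make_image(px))
        assert 30 < t <= 200

    def test_huang_is_criterion_argmin(self):
        rng = np.random.default_rng(9)
        px = np.concatenate(
            [rng.normal(60, 10, 800), rng.normal(180, 15, 800)]
        ).clip(0, 255).astype(np.uint8)
        img = make_image(px.reshape(40, 40))
        t_star = huang_threshold(img)

        def criterion(t):
            g = img.pixels.astype(float).ravel()
            lo, hi = g[g < t], g[g >= t]
            c = float(g.max() - g.min())
            e = 0.0
            for part in (lo, hi):
                mu = part.mean()
                u = 1.0 / (1.0 + np.abs(part - mu) / c)
                s = -u * np.log(u) - (1 - u) * np.log(np.maximum(1 - u, 1e-300))
                s[u >= 1.0] = 0.0
                e += s.sum()
            return e

        vals = {t: criterion(t) for t in range(int(px.min()) + 1, int(px.max()) + 1)}
        assert vals[t_star] <= min(vals.values()) + 1e-9

    def test_huang_constant_image_rejected(self):
        with pytest.raises(NoThresholdError):
            huang_threshold(make_image(np.full((8, 8), 42, dtype=np.uint8)))
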