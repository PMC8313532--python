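"""Tests for FFT reconstruction, demultiplexing, alignment, fusion and CS."""

import numpy as np
import pytest

from cyclospi import (
    AcquisitionConfig,
    CyclicCode,
    GaussianNoise,
    acquire,
    analytic_inverse_apply,
    cs_reconstruct,
    demux,
    fft_reconstruct,
    fold_crt,
    fuse,
    image_metrics,
    project,
    qr_code,
    resolution_target,
    subpixel_align,
)
from cyclospi.recon import remux, tv_value


class TestFftReconstruct:
    def test_hand_computed_order3(self, code3):
        assert np.allclose(fft_reconstruct(code3, np.array([3.0, 4.0, 5.0])), [1, 2, 3])

    def test_matches_analytic_inverse(self, small_codes, rng):
        for code in small_codes:
            y = rng.normal(size=code.order)
            a = analytic_inverse_apply(code, y)
            f = fft_reconstruct(code, y)
            assert np.allclose(f, a, rtol=1e-8, atol=1e-8)

    def test_matches_dense_solve(self, tp15, rng):
        y = rng.normal(size=15)
        dense = np.linalg.solve(tp15.matrix().astype(float), y)
        assert np.allclose(fft_reconstruct(tp15, y), dense, atol=1e-10)

    def test_round_trip_experimental_scale(self, tp10403, rng):
        x = rng.uniform(0, 1, 10403)
        y = project(tp10403, x)
        assert np.abs(fft_reconstruct(tp10403, y) - x).max() < 1e-6

    def test_constant_signal_forward_check(self, qr19):
        y = np.ones(19)
        x = fft_reconstruct(qr19, y)
        assert np.allclose(project(qr19, x), y, atol=1e-10)

    def test_singular_code_rejected(self):
        code = CyclicCode(order=7, bits=np.ones(7, dtype=np.uint8), method="custom")
        with pytest.raises(ValueError, match="singular"):
            fft_reconstruct(code, np.ones(7))

    def test_length_mismatch(self, qr19):
        with pytest.raises(ValueError):
            fft_reconstruct(qr19, np.zeros(18))


class TestDemux:
    def test_m1_identity(self, tp15, rng):
        x = rng.uniform(0, 1, 15)
        tr = acquire(tp15, x, AcquisitionConfig(oversampling=1))
        ds = demux(tr)
        assert ds.shape == (1, 15)
        assert np.array_equal(ds[0], tr.samples)

    def test_dataset0_is_projection(self, tp15, rng):
        x = rng.uniform(0, 1, 15)
        tr = acquire(tp15, x, AcquisitionConfig(oversampling=5))
        assert np.allclose(demux(tr)[0], project(tp15, x))

    def test_remux_round_trip(self, tp15, rng):
        x = rng.uniform(0, 1, 15)
        tr = acquire(tp15, x, AcquisitionConfig(oversampling=4))
        assert np.array_equal(remux(demux(tr)), tr.samples)


class TestSubpixelAlign:
    def test_identity(self, rng):
        v = rng.normal(size=19)
        assert np.array_equal(subpixel_align(v, 0.0), v)

    def test_inverse_shifts(self, rng):
        v = rng.normal(size=31)
        w = subpixel_align(subpixel_align(v, 0.37), -0.37)
        assert np.allclose(w, v, atol=1e-9)

    def test_integer_limit_on_smooth_vector(self):
        # a single low-frequency sinusoid is band-limited: the delta -> 1
        # limit of the fractional shift equals the exact unit roll
        n = 19
        t = np.arange(n)
        v = np.cos(2 * np.pi * t / n)
        rolled = np.roll(v, -1)  # shift of -1 index unit
        for delta, tol in ((0.9, 0.7), (0.99, 0.07), (0.9999, 7e-4)):
            err = np.abs(subpixel_align(v, delta) - rolled).max()
            # error shrinks linearly with (1 - delta)
            assert err < tol
        assert np.allclose(subpixel_align(v, 1.0), rolled, atol=1e-12)


class TestFuse:
    def test_m1_noiseless_exact(self, tp10403, layout10403):
        ph = resolution_target(101, 103, [2, 3, 5])
        x = layout10403.unfold(ph.image)
        tr = acquire(tp10403, x, AcquisitionConfig(oversampling=1))
        est = fuse(tr, tp10403, layout10403)
        assert np.abs(est.image - ph.image).max() < 1e-6
        assert est.n_datasets_used == 1

    def test_blend_identity_small_and_large(self, qr19, tp10403, rng):
        # circulants commute: recon of dataset m is exactly
        # (1 - m/M) x + (m/M) roll(x, 1)
        for code in (qr19, tp10403):
            x = rng.uniform(0, 1, code.order)
            tr = acquire(code, x, AcquisitionConfig(oversampling=5))
            ds = demux(tr)
            for m in range(5):
                d = m / 5
                xm = fft_reconstruct(code, ds[m])
                assert np.allclose(xm, (1 - d) * x + d * np.roll(x, 1), atol=1e-8)

    def test_fused_image_is_fold_of_code_vector(self, tp15, layout15, rng):
        x = rng.uniform(0, 1, 15)
        tr = acquire(tp15, x, AcquisitionConfig(oversampling=3))
        est = fuse(tr, tp15, layout15)
        assert np.array_equal(est.image, layout15.fold(est.x_code_domain))

    def test_deblend_restores_detail(self, tp10403, layout10403):
        ph = resolution_target(101, 103, [2, 3, 5])
        x = layout10403.unfold(ph.image)
        tr = acquire(tp10403, x, AcquisitionConfig(oversampling=5))
        plain = fuse(tr, tp10403, layout10403)
        sharp = fuse(tr, tp10403, layout10403, deblend=True)
        rmse_plain = image_metrics(plain, ph).rmse
        rmse_sharp = image_metrics(sharp, ph).rmse
        assert rmse_sharp < rmse_plain / 10
        assert rmse_sharp < 0.01

    def test_fusion_noise_gain(self, tp10403, layout10403):
        """Fused M=5 reduces RMSE vs M=1 by roughly sqrt(5) under Gaussian
        noise (small Monte Carlo here; the full 100-rep version is in the
        acceptance suite)."""
        ph = resolution_target(101, 103, [3, 5])
        x = layout10403.unfold(ph.image)
        sigma = 20.0
        r1, r5 = [], []
        for rep in range(10):
            t1 = acquire(tp10403, x, AcquisitionConfig(1, GaussianNoise(sigma), seed=rep))
            t5 = acquire(tp10403, x, AcquisitionConfig(5, GaussianNoise(sigma), seed=500 + rep))
            r1.append(image_metrics(fuse(t1, tp10403, layout10403), ph).rmse)
            r5.append(image_metrics(fuse(t5, tp10403, layout10403), ph).rmse)
        ratio = np.mean(r1) / np.mean(r5)
        assert 0.6 * np.sqrt(5) < ratio < 1.2 * np.sqrt(5)

    def test_inconsistent_order_rejected(self, tp15, layout10403, rng):
        tr = acquire(tp15, rng.uniform(0, 1, 15), AcquisitionConfig(oversampling=2))
        with pytest.raises(ValueError):
            fuse(tr, tp15, layout10403)

    def test_parameter_recovery_bias(self, tp10403, layout10403):
        """Grayscale values recovered with bias < 1% of range under the
        default-level Gaussian noise, 100 reps."""
        rng = np.random.default_rng(0)
        smooth = rng.uniform(0.2, 0.8, (101, 103))
        from scipy.ndimage import gaussian_filter

        smooth = gaussian_filter(smooth, 3)
        from cyclospi import Phantom

        ph = Phantom(image=np.clip(smooth, 0, 1), kind="grayscale")
        x = layout10403.unfold(ph.image)
        acc = np.zeros(10403)
        reps = 100
        for rep in range(reps):
            tr = acquire(tp10403, x, AcquisitionConfig(1, GaussianNoise(2.0), seed=rep))
            acc += fuse(tr, tp10403, layout10403).x_code_domain
        bias = acc / reps - x
        assert np.sqrt(np.mean(bias**2)) < 0.01


class TestCsReconstruct:
    def test_unregularized_limit(self, tp15, layout15, rng):
        x = rng.uniform(0, 1, 15)
        y = project(tp15, x)
        est = cs_reconstruct(tp15, y, np.arange(15), 0.0, layout15, max_iter=3000, tol=1e-10)
        ref = fft_reconstruct(tp15, y)
        assert np.linalg.norm(est.x_code_domain - ref) / np.linalg.norm(ref) < 1e-3

    def test_half_measurements_piecewise_constant(self, tp15, layout15):
        img = np.zeros((3, 5))
        img[:, 1:3] = 1.0
        x_true = layout15.unfold(img)
        y = project(tp15, x_true)
        rng = np.random.default_rng(4)
        idx = np.sort(rng.choice(15, size=8, replace=False))
        est = cs_reconstruct(tp15, y[idx], idx, 0.05, layout15, max_iter=2000)
        # exact support recovery after thresholding
        assert np.array_equal((est.x_code_domain > 0.5).astype(int), x_true.astype(int))
        # oracle comparison: the solver's objective must beat both the truth
        # and the dense min-norm least-squares solution
        s_sub = tp15.matrix().astype(float)[idx]

        def objective(v):
            r = s_sub @ v - y[idx]
            return 0.5 * r @ r + 0.05 * tv_value(layout15.fold(v))

        pinv_sol = np.linalg.pinv(s_sub) @ y[idx]
        assert objective(est.x_code_domain) <= objective(x_true) + 1e-6
        assert objective(est.x_code_domain) <= objective(pinv_sol) + 1e-6

    def test_empty_indices_rejected(self, tp15):
        with pytest.raises(ValueError, match="empty"):
            cs_reconstruct(tp15, np.zeros(0), np.zeros(0, dtype=int), 0.0)

    def test_weight_without_layout_rejected(self, tp15):
        with pytest.raises(ValueError, match="layout"):
            cs_reconstruct(tp15, np.zeros(15), np.arange(15), 0.1, None)


class TestImageMetrics:
    def test_perfect_estimate(self, layout15):
        ph = resolution_target(30, 40, [2])
        m = image_metrics(ph.image, ph)
        assert m.rmse == 0.0
        assert m.psnr == np.inf
        assert m.bar_contrast == pytest.approx(1.0)

    def test_constant_offset(self):
        ph = resolution_target(30, 40, [2])
        m = image_metrics(ph.image + 0.25, ph)
        assert m.rmse == pytest.approx(0.25)
        assert m.psnr == pytest.approx(20 * np.log10(1 / 0.25))

    def test_zero_estimate_guarded(self):
        ph = resolution_target(30, 40, [2])
        m = image_metrics(np.zeros((30, 40)), ph)
        assert m.bar_contrast == 0.0  # 0/0 guarded

    def test_shape_mismatch(self):
        ph = resolution_target(30, 40, [2])
        with pytest.raises(ValueError):
            image_metrics(np.zeros((40, 30)), ph)


class TestOracleEquivalence:
    """Dual-route checks binding the FFT path to independent oracles."""

    def test_three_routes_agree(self, rng):
        for p in (3, 7, 19, 31):
            code = qr_code(p)
            y = rng.normal(size=p)
            fft_x = fft_reconstruct(code, y)
            analytic_x = analytic_inverse_apply(code, y)
            dense_x = np.linalg.solve(code.matrix().astype(float), y)
            assert np.allclose(fft_x, analytic_x, atol=1e-8)
            assert np.allclose(fft_x, dense_x, atol=1e-8)

    def test_end_to_end_any_m(self, tp15, layout15, rng):
        ph_img = rng.uniform(0, 1, (3, 5))
        x = layout15.unfold(ph_img)
        for m in (1, 2, 5, 8):
            tr = acquire(tp15, x, AcquisitionConfig(oversampling=m))
            est = fuse(tr, tp15, layout15, deblend=True, deblend_eps=1e-9)
            assert np.abs(est.x_code_domain - x).max() < 1e-4
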