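"""Susceptibility distortion: forward model against a discrete k-space
simulation oracle, warp recovery, and the echo-spacing scaling."""

import numpy as np
import pytest

import epigrad as eg
from epigrad.distortion import displacement_map


@pytest.fixture(scope="module")
def timing_pair():
    prot = eg.EPIProtocol.from_resolution(0.6, 192.0, grappa_r=3, partial_fourier=0.75)
    imp = eg.min_te(prot, eg.load_coil_preset("impulse"))
    body = eg.min_te(prot, eg.load_coil_preset("xr_body"))
    return imp, body


def _gaussian_fmap(shape, amp_hz, sigma=20.0):
    idx = np.meshgrid(*[np.arange(n) - n / 2 for n in shape], indexing="ij")
    r2 = sum(i ** 2 for i in idx)
    return amp_hz * np.exp(-r2 / (2 * sigma ** 2))


class TestForwardModel:
    def test_zero_field_identity(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        out = eg.epi_distort(smooth_test_image, np.zeros_like(smooth_test_image), t)
        assert np.allclose(out, smooth_test_image)

    def test_linear_in_echo_spacing(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        fmap = _gaussian_fmap(smooth_test_image.shape, 30.0)
        n = smooth_test_image.shape[-1]
        d1 = displacement_map(fmap, t, n)
        half = eg.EPITiming(
            es_ms=t.es_ms / 2, es_eff_ms=t.es_eff_ms / 2,
            bw_per_pixel_hz=2 * t.bw_per_pixel_hz, n_echoes=t.n_echoes,
            echoes_before_center=t.echoes_before_center,
            train_ms=t.n_echoes * t.es_ms / 2, te_min_ms=t.te_min_ms,
        )
        assert np.allclose(displacement_map(fmap, half, n), d1 / 2)

    def test_signal_conservation(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        fmap = _gaussian_fmap(smooth_test_image.shape, 60.0)
        out = eg.epi_distort(smooth_test_image, fmap, t)
        assert out.sum() == pytest.approx(smooth_test_image.sum(), rel=1e-9)

    def test_matches_kspace_phase_accrual_oracle(self, timing_pair):
        """Full discrete EPI simulation: per-line off-resonance phase
        accrual then inverse DFT.  Point sources at several positions are
        displaced by the same amount in the oracle reconstruction and in
        the forward model, agreeing to < 0.1 pixel."""
        t, _ = timing_pair
        n = 32
        y = np.arange(n)
        img = np.zeros((n, n))
        blobs = [(6, 10), (14, 20), (22, 8), (28, 16)]
        for x0, y0 in blobs:
            img[x0] = np.exp(-(y - y0) ** 2 / (2 * 1.2 ** 2))
        fmap = _gaussian_fmap((n, n), 120.0, sigma=10.0)

        # oracle: line k (acquired k*es_eff after the centre echo) carries
        # the accrued off-resonance phase; then per-column inverse DFT
        k = np.arange(n) - n // 2
        tk = k * t.es_eff_ms * 1e-3
        phase = np.exp(-2j * np.pi * fmap[..., None] * tk[None, None, :])
        F = np.exp(-2j * np.pi * np.outer(k, y) / n)
        ksp = np.einsum("ky,xy,xyk->xk", F, img + 0j, phase)
        recon = np.abs(np.einsum("ky,xk->xy", F.conj(), ksp)) / n

        model = eg.epi_distort(img, fmap, t, pe_direction=+1, pe_axis=1)
        for x0, y0 in blobs:
            w_o = recon[x0] ** 2
            w_m = model[x0] ** 2
            c_o = (w_o @ y) / w_o.sum()
            c_m = (w_m @ y) / w_m.sum()
            assert abs(c_o - c_m) < 0.1

    def test_round_trip_smooth_field(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        fmap = _gaussian_fmap(smooth_test_image.shape, 40.0, sigma=40.0)
        ap = eg.epi_distort(smooth_test_image, fmap, t, +1)
        back = eg.epi_distort(ap, fmap, t, -1)
        interior = (slice(4, -4), slice(4, -4))
        err = np.sqrt(((back - smooth_test_image)[interior] ** 2).mean())
        assert err / smooth_test_image.std() < 0.01

    def test_excessive_displacement_rejected(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        with pytest.raises(ValueError, match="FOV"):
            eg.epi_distort(smooth_test_image,
                           np.full_like(smooth_test_image, 1e5), t)


class TestWarpEstimation:
    def test_identical_images_zero_field(self, smooth_test_image):
        res = eg.estimate_warp(smooth_test_image, smooth_test_image, voxel_mm=0.6)
        assert np.abs(res.warp_mm).max() < 0.05

    def test_recovery_of_known_field(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        img = smooth_test_image + 0.05 * (smooth_test_image > 0)
        fmap = 250.0 * _gaussian_fmap(img.shape, 1.0, sigma=20.0)
        true = displacement_map(fmap, t, img.shape[-1])
        ap = eg.epi_distort(img, fmap, t, +1)
        pa = eg.epi_distort(img, fmap, t, -1)
        res = eg.estimate_warp(ap, pa, voxel_mm=0.6, pe_axis=1)
        rmse_mm = np.sqrt(((res.warp_pix - true) ** 2).mean()) * 0.6
        assert rmse_mm < 0.3

    def test_antisymmetric_under_swap(self, smooth_test_image, timing_pair):
        t, _ = timing_pair
        fmap = 150.0 * _gaussian_fmap(smooth_test_image.shape, 1.0, sigma=25.0)
        ap = eg.epi_distort(smooth_test_image, fmap, t, +1)
        pa = eg.epi_distort(smooth_test_image, fmap, t, -1)
        fwd = eg.estimate_warp(ap, pa, voxel_mm=0.6)
        rev = eg.estimate_warp(pa, ap, voxel_mm=0.6)
        assert np.allclose(fwd.warp_mm, -rev.warp_mm, atol=1e-12)

    def test_warp_scales_with_echo_spacing(self, smooth_test_image, timing_pair):
        t_imp, t_body = timing_pair
        img = smooth_test_image + 0.05 * (smooth_test_image > 0)
        fmap = 120.0 * _gaussian_fmap(img.shape, 1.0, sigma=20.0)
        warps = {}
        for key, t in (("imp", t_imp), ("body", t_body)):
            ap = eg.epi_distort(img, fmap, t, +1)
            pa = eg.epi_distort(img, fmap, t, -1)
            warps[key] = eg.estimate_warp(ap, pa, voxel_mm=0.6).warp_pix
        true_body = displacement_map(fmap, t_body, img.shape[-1])
        m = np.abs(true_body) > 1.0
        ratio = np.median(warps["imp"][m] / warps["body"][m])
        es_ratio = t_imp.es_ms / t_body.es_ms
        assert ratio == pytest.approx(es_ratio, rel=0.10)
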