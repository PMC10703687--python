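"""Receive-array synthesis, optimal-combination SNR and SENSE g-factor."""

import numpy as np
import pytest

import epigrad as eg
from epigrad.arrays import NoiseCovariance, SensitivitySet, _loop_field


class TestGeometry:
    def test_96_channel_row_structure(self):
        g = eg.build_helmet_array(96)
        assert g.row_counts[:3] == (12, 18, 24)
        assert sum(g.row_counts[3:]) == 42
        assert g.n_channels == 96

    def test_determinism(self):
        a = eg.build_helmet_array(64, seed=11)
        b = eg.build_helmet_array(64, seed=11)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.radii, b.radii)

    def test_centers_on_helmet_surface(self):
        g = eg.build_helmet_array(32)
        a, b, c = g.helmet_semiaxes
        # implicit-function residual small -> distance to surface << 1 mm
        f = (g.centers[:, 0] / a) ** 2 + (g.centers[:, 1] / b) ** 2 \
            + (g.centers[:, 2] / c) ** 2
        assert np.abs(f - 1).max() < 2e-2

    def test_loops_shrink_with_channel_count(self):
        means = [eg.build_helmet_array(n).radii.mean() for n in (32, 64, 96)]
        assert means[0] > means[1] > means[2]

    def test_unsupported_count(self):
        with pytest.raises(ValueError):
            eg.build_helmet_array(48)


class TestSensitivities:
    def test_decay_along_loop_axis(self):
        center = np.array([0.0, 0.0, 100.0])
        normal = np.array([0.0, 0.0, -1.0])
        pts = np.array([[0.0, 0.0, 100.0 - d] for d in (20, 40, 60, 80)])
        B = _loop_field(center, normal, 20.0, pts)
        mags = np.linalg.norm(B, axis=1)
        assert np.all(np.diff(mags) < 0)

    def test_conductor_intersection_raises_with_mask(self):
        g = eg.build_helmet_array(8)
        # a grid point dropped exactly onto the first loop's conductor
        on_ring = g.centers[0] + g.radii[0] * _perp(g.normals[0])
        with pytest.raises(ValueError, match="conductor"):
            _loop_field(g.centers[0], g.normals[0], g.radii[0],
                        on_ring[None, :], strict=True)

    def test_noise_cov_identity_at_zero_coupling(self):
        g = eg.build_helmet_array(8)
        psi = eg.noise_cov(g, coupling_scale=0.0, sigma=2.0)
        assert np.allclose(psi.psi, 4.0 * np.eye(8))

    def test_noise_cov_positive_definite_random_geometries(self):
        for seed in range(25):
            g = eg.build_helmet_array(32, seed=seed)
            psi = eg.noise_cov(g, coupling_scale=0.4)
            assert np.linalg.eigvalsh(psi.psi).min() > 0

    def test_covariance_validation(self):
        with pytest.raises(ValueError):
            NoiseCovariance(np.array([[1.0, 2.0], [0.0, 1.0]]))  # not Hermitian
        with pytest.raises(ValueError):
            NoiseCovariance(np.array([[1.0, 2.0], [2.0, 1.0]]))  # indefinite


def _perp(n):
    v = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        v = np.array([0.0, 1.0, 0.0])
    p = np.cross(n, v)
    return p / np.linalg.norm(p)


class TestSNRMap:
    def test_single_channel_reduces_to_scalar(self):
        s = SensitivitySet(values=np.full((1, 2, 2, 1), 3.0 + 4.0j))
        psi = NoiseCovariance(np.array([[4.0]]))
        assert np.allclose(eg.snr_map(s, psi), 5.0 / 2.0)

    def test_two_identical_channels_sqrt2_gain(self):
        v = np.full((1, 2, 2, 1), 1.0 + 1.0j)
        s1 = SensitivitySet(values=v)
        s2 = SensitivitySet(values=np.concatenate([v, v]))
        psi1 = NoiseCovariance(np.eye(1))
        psi2 = NoiseCovariance(np.eye(2))
        assert np.allclose(eg.snr_map(s2, psi2),
                           np.sqrt(2) * eg.snr_map(s1, psi1))

    def test_adding_channel_never_decreases_snr(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal((5, 4, 4, 2)) + 1j * rng.standard_normal((5, 4, 4, 2))
        m_less = eg.snr_map(SensitivitySet(v[:4]), NoiseCovariance(np.eye(4)))
        m_more = eg.snr_map(SensitivitySet(v), NoiseCovariance(np.eye(5)))
        assert np.all(m_more >= m_less - 1e-12)


class TestRetainedSNR:
    def test_unaccelerated_is_unity(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, 4, 8, 2)) + 1j * rng.standard_normal((4, 4, 8, 2))
        s = SensitivitySet(v)
        psi = NoiseCovariance(np.eye(4))
        assert np.all(eg.retained_snr_map(s, psi, eg.SamplingPattern()) == 1.0)

    def test_g_at_least_one(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((6, 4, 8, 4)) + 1j * rng.standard_normal((6, 4, 8, 4))
        s = SensitivitySet(v)
        psi = NoiseCovariance(np.eye(6))
        inv_g = eg.retained_snr_map(s, psi, eg.SamplingPattern(r_pe=2, sms=2, caipi_shift=1))
        assert np.all(inv_g <= 1.0 + 1e-12)
        assert np.all(inv_g > 0)

    def test_two_voxel_toy_matches_monte_carlo(self):
        """Analytic SENSE g equals brute-force noise propagation through
        the unfolding matrix on a 2-voxel, 2-channel toy system."""
        rng = np.random.default_rng(5)
        S = rng.standard_normal((2, 1, 2, 1)) + 1j * rng.standard_normal((2, 1, 2, 1))
        psi_m = np.array([[1.0, 0.3 + 0.1j], [0.3 - 0.1j, 0.8]])
        psi = NoiseCovariance(psi_m)
        inv_g = eg.retained_snr_map(SensitivitySet(S), psi,
                                    eg.SamplingPattern(r_pe=2))
        # Monte-Carlo: unfold folded noisy data, compare noise std with the
        # unaccelerated optimal-combination noise
        SA = S[:, 0, :, 0]  # channels x 2 aliased voxels
        psi_inv = np.linalg.inv(psi_m)
        M = SA.conj().T @ psi_inv @ SA
        U = np.linalg.inv(M) @ SA.conj().T @ psi_inv
        n_draws = 100_000
        L = np.linalg.cholesky(psi_m)
        noise = L @ ((rng.standard_normal((2, n_draws))
                      + 1j * rng.standard_normal((2, n_draws))) / np.sqrt(2))
        rec = U @ noise
        sd_acc = rec.std(axis=1)
        sd_full = 1.0 / np.sqrt(np.real(np.diag(M)))
        g_mc = sd_acc / sd_full
        assert np.allclose(1.0 / g_mc, inv_g[0, :, 0], rtol=0.02)

    def test_rank_deficient_flagged_as_zero(self):
        # identical sensitivities everywhere -> aliases indistinguishable
        v = np.ones((2, 1, 4, 1), dtype=complex)
        s = SensitivitySet(v)
        psi = NoiseCovariance(np.eye(2))
        inv_g = eg.retained_snr_map(s, psi, eg.SamplingPattern(r_pe=2))
        assert np.all(inv_g == 0.0)

    def test_grid_divisibility_enforced(self):
        v = np.ones((2, 3, 5, 2), dtype=complex)
        with pytest.raises(ValueError):
            eg.retained_snr_map(SensitivitySet(v), NoiseCovariance(np.eye(2)),
                                eg.SamplingPattern(r_pe=2))
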