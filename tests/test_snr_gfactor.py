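"""SNR maps, combination optimality, summaries, g-factors and transmit
loss against closed forms and brute-force oracles."""

import warnings

import numpy as np
import pytest

from csiqa import noisecal, phantom, snr
from csiqa.datamodel import (
    AcquisitionSpec,
    NoiseModel,
    SensitivityMap,
    SignalMap,
    SNRMap,
    TxMap,
    ValidationError,
)


def _sig(arr):
    return SignalMap(s=np.asarray(arr, complex), inphase_time_ms=0.0,
                     inphase_index=0)


def _unit_noise(n, scaled=True):
    return NoiseModel(psi=np.eye(n, dtype=complex), scaled=scaled)


class TestSingleChannel:
    def test_forced_arithmetic(self):
        sig = _sig(np.full((2, 2, 1), 10.0))
        model = NoiseModel(psi=np.array([[2.0]], complex), scaled=True)
        m = snr.snr_map_single(sig, model)
        np.testing.assert_allclose(m.snr, 10.0)

    def test_zero_signal_gives_zero(self):
        m = snr.snr_map_single(_sig(np.zeros((2, 2, 1))), _unit_noise(1))
        assert not np.any(m.snr)

    def test_multichannel_input_redirected(self):
        with pytest.raises(ValidationError, match="snr_map_array"):
            snr.snr_map_single(_sig(np.zeros((2, 2, 3))), _unit_noise(3))

    def test_unscaled_noise_rejected(self):
        with pytest.raises(ValidationError, match="scaled"):
            snr.snr_map_single(_sig(np.zeros((2, 2, 1))),
                               _unit_noise(1, scaled=False))

    def test_background_follows_rician_moments(self):
        """Noise-only single-channel SNR is Rayleigh(1): mean sqrt(pi/2)."""
        psi = np.array([[2.0]], complex)
        s = phantom.complex_gaussian(psi, (100, 100),
                                     np.random.default_rng(0))
        m = snr.snr_map_single(_sig(s), NoiseModel(psi=psi, scaled=True))
        vals = m.snr.ravel()
        assert vals.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=0.02)
        assert vals.std() == pytest.approx(np.sqrt(2 - np.pi / 2), rel=0.03)


class TestArrayCombination:
    def test_hand_computed_two_channel_example(self):
        b = np.zeros((1, 1, 2), complex)
        b[0, 0] = (0.8, 0.6j)
        s = np.zeros((1, 1, 2), complex)
        s[0, 0] = (5 * 0.8, 5 * 0.6j)
        smap = SensitivityMap(b=b, mask=np.ones((1, 1), bool))
        m = snr.snr_map_array(_sig(s), smap, _unit_noise(2))
        assert m.snr[0, 0] == pytest.approx(np.sqrt(2) * 5, abs=1e-6)

    def test_single_channel_reduces_to_eq2(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal((6, 6, 1)) + 1j * rng.standard_normal((6, 6, 1))
        b = np.ones((6, 6, 1), complex)
        smap = SensitivityMap(b=b, mask=np.ones((6, 6), bool))
        model = NoiseModel(psi=np.array([[3.0]], complex), scaled=True)
        m_arr = snr.snr_map_array(_sig(s), smap, model)
        m_one = snr.snr_map_single(_sig(s), model)
        np.testing.assert_allclose(m_arr.snr, m_one.snr, rtol=1e-12)

    def test_matched_filter_beats_any_tested_combination(self):
        """Optimal combination >= sum-of-squares, uniform weights and
        random weights at every voxel (brute-force weight oracle)."""
        rng = np.random.default_rng(2)
        n = 6
        psi = phantom.uniform_covariance(n, rho=0.3) + np.diag(
            rng.uniform(0, 0.5, n))
        b = rng.standard_normal((8, 8, n)) + 1j * rng.standard_normal((8, 8, n))
        a = rng.uniform(1, 3, (8, 8))
        s = a[:, :, None] * b
        smap = SensitivityMap(b=b, mask=np.ones((8, 8), bool))
        model = NoiseModel(psi=psi, scaled=True)
        opt = snr.snr_map_array(_sig(s), smap, model).snr
        for _ in range(20):
            w = rng.standard_normal(n) + 1j * rng.standard_normal(n)
            other = snr.combined_snr(s, w, psi)
            assert np.all(opt >= other - 1e-6)
        uniform = snr.combined_snr(s, np.ones(n), psi)
        assert np.all(opt >= uniform - 1e-6)
        # sum-of-squares behaves as the unwhitened matched direction w = b
        sos_like = snr.combined_snr(s, b, psi)
        assert np.all(opt >= sos_like - 1e-6)

    def test_sos_equals_optimal_for_iid_channels(self):
        rng = np.random.default_rng(7)
        n = 4
        b = rng.standard_normal((5, 5, n)) + 1j * rng.standard_normal((5, 5, n))
        s = 2.0 * b
        model = _unit_noise(n)
        smap = SensitivityMap(b=b, mask=np.ones((5, 5), bool))
        opt = snr.snr_map_array(_sig(s), smap, model).snr
        sos = snr.sum_of_squares_snr(_sig(s), model).snr
        np.testing.assert_allclose(opt, sos, rtol=1e-10)

    def test_equality_for_iid_channels_uniform_profiles(self):
        n = 4
        s = np.full((3, 3, n), 2.0 + 0j)
        b = np.ones((3, 3, n), complex)
        smap = SensitivityMap(b=b, mask=np.ones((3, 3), bool))
        opt = snr.snr_map_array(_sig(s), smap, _unit_noise(n)).snr
        uni = snr.combined_snr(s, np.ones(n), np.eye(n))
        np.testing.assert_allclose(opt, uni, rtol=1e-12)

    def test_invariant_to_per_voxel_b_rescaling(self):
        rng = np.random.default_rng(3)
        n = 5
        b = rng.standard_normal((4, 4, n)) + 1j * rng.standard_normal((4, 4, n))
        s = rng.standard_normal((4, 4, n)) + 1j * rng.standard_normal((4, 4, n))
        scale = rng.uniform(0.1, 10.0, (4, 4))
        mask = np.ones((4, 4), bool)
        m1 = snr.snr_map_array(_sig(s), SensitivityMap(b=b, mask=mask),
                               _unit_noise(n)).snr
        m2 = snr.snr_map_array(
            _sig(s), SensitivityMap(b=scale[:, :, None] * b, mask=mask),
            _unit_noise(n)).snr
        np.testing.assert_allclose(m1, m2, rtol=1e-10)

    def test_invariant_to_unitary_channel_gains(self):
        rng = np.random.default_rng(4)
        n = 4
        b = rng.standard_normal((4, 4, n)) + 1j * rng.standard_normal((4, 4, n))
        s = rng.standard_normal((4, 4, n)) + 1j * rng.standard_normal((4, 4, n))
        psi = phantom.uniform_covariance(n, rho=0.2)
        u = np.diag(np.exp(1j * rng.uniform(0, 2 * np.pi, n)))
        mask = np.ones((4, 4), bool)
        m1 = snr.snr_map_array(_sig(s), SensitivityMap(b=b, mask=mask),
                               NoiseModel(psi=psi, scaled=True)).snr
        m2 = snr.snr_map_array(
            _sig(s @ u.T), SensitivityMap(b=b @ u.T, mask=mask),
            NoiseModel(psi=u @ psi @ u.conj().T, scaled=True)).snr
        np.testing.assert_allclose(m1, m2, rtol=1e-10)

    def test_correlated_noise_gain_from_full_psi(self, acq, cylinder):
        """With strong correlation in the top channel block, using the
        full covariance recovers materially more SNR there than the
        diagonal approximation, and never less anywhere."""
        coils = phantom.make_layout("array14")
        psi = phantom.uniform_covariance(14, rho=0.7, block=slice(0, 7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw, nr, gt = phantom.simulate_csi(
                phantom.PhantomSpec(signal_amplitude=600.0), coils, acq, psi,
                seed=21)
        from csiqa import recon, sensitivity
        img = recon.recon_csi(raw)
        filt = recon.spectral_filter(img, 10.0, acq)
        idx, t = recon.first_inphase_sample(142.0, acq.te_ms, acq)
        sig = recon.extract_signal(filt, idx, acq, t)
        model = noisecal.scale_covariance(
            noisecal.estimate_noise_covariance(nr), 1.0)
        mask = sensitivity.derive_mask(sig, model)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bhat = sensitivity.estimate_sensitivities(sig, model, mask)
        # both combinations are judged against the same measured covariance
        nch = 14
        w_full = np.linalg.solve(model.psi,
                                 bhat.b.reshape(-1, nch).T).T.reshape(bhat.b.shape)
        w_diag = bhat.b / np.real(np.diagonal(model.psi))
        full = snr.combined_snr(sig.s, w_full, model.psi)
        diag = snr.combined_snr(sig.s, w_diag, model.psi)
        m = bhat.mask
        ratio = full[m] / diag[m]
        # the matched filter is optimal for s exactly proportional to b;
        # residual noise in s allows only marginal local violations
        assert ratio.min() >= 0.97
        assert ratio.mean() > 1.0
        assert ratio.max() > 1.2  # material gain where correlation is high


class TestSummary:
    def _map(self, snr_arr, mask=None):
        mask = np.ones(snr_arr.shape, bool) if mask is None else mask
        return SNRMap(snr=np.where(mask, snr_arr, 0.0), mask=mask,
                      n_channels=1)

    def test_constant_map(self):
        m = self._map(np.full((24, 24), 7.0))
        s = snr.snr_summary(m)
        assert s.center == 7.0 and s.surface == 7.0
        np.testing.assert_allclose(s.profile_ap, 7.0)

    def test_center_block_is_central_3x3(self):
        arr = np.zeros((24, 24))
        arr[11:14, 11:14] = 9.0
        s = snr.snr_summary(self._map(arr))
        assert s.center == 9.0

    def test_edge_hotspot_sets_surface_only(self):
        arr = np.ones((24, 24))
        arr[0, 5] = 100.0
        s = snr.snr_summary(self._map(arr))
        assert s.surface == 100.0 and s.center == 1.0

    def test_center_outside_mask_warns_nan(self):
        mask = np.zeros((24, 24), bool)
        mask[0:4, 0:4] = True
        m = self._map(np.ones((24, 24)), mask)
        with pytest.warns(UserWarning):
            s = snr.snr_summary(m)
        assert np.isnan(s.center)

    def test_array_surface_to_center_ratio_exceeds_volume_coil(
            self, array14_pipeline):
        """Close-fitting arrays show surface/center SNR ratios well above
        volume-coil behavior (ratio > 3, as for benchmarked helmet arrays)."""
        sig, model, bhat, gt = array14_pipeline
        m = snr.snr_map_array(sig, bhat, model)
        s = snr.snr_summary(m)
        assert s.surface / s.center > 3.0


class TestGFactor:
    def test_r1_is_unity(self):
        rng = np.random.default_rng(5)
        b = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        smap = SensitivityMap(b=b, mask=np.ones((8, 8), bool))
        gm = snr.sense_gfactor(smap, _unit_noise(4), 1, "row")
        np.testing.assert_allclose(gm.g, 1.0, atol=1e-9)

    def test_orthogonal_sensitivities_give_unity(self):
        b = np.zeros((2, 1, 2), complex)
        b[0, 0] = (1, 0)
        b[1, 0] = (0, 1)
        smap = SensitivityMap(b=b, mask=np.ones((2, 1), bool))
        gm = snr.sense_gfactor(smap, _unit_noise(2), 2, "row")
        np.testing.assert_allclose(gm.g, 1.0, atol=1e-9)

    def test_two_voxel_closed_form(self):
        theta = np.deg2rad(60.0)
        b = np.zeros((2, 1, 2), complex)
        b[0, 0] = (1, 0)
        b[1, 0] = (np.cos(theta), np.sin(theta))
        smap = SensitivityMap(b=b, mask=np.ones((2, 1), bool))
        gm = snr.sense_gfactor(smap, _unit_noise(2), 2, "row")
        np.testing.assert_allclose(gm.g, 1 / np.sin(theta), atol=1e-6)

    def test_r_exceeding_channels_rejected(self):
        b = np.ones((8, 8, 2), complex)
        smap = SensitivityMap(b=b, mask=np.ones((8, 8), bool))
        with pytest.raises(ValidationError):
            snr.sense_gfactor(smap, _unit_noise(2), 4, "row")

    def test_non_divisible_r_rejected(self):
        b = np.ones((9, 9, 4), complex)
        smap = SensitivityMap(b=b, mask=np.ones((9, 9), bool))
        with pytest.raises(ValidationError):
            snr.sense_gfactor(smap, _unit_noise(4), 2, "row")

    def test_array_fixture_ordering(self, array14_pipeline):
        """g >= 1 where defined and R = 4 never beats R = 2 per voxel."""
        sig, model, bhat, gt = array14_pipeline
        g2 = snr.sense_gfactor(bhat, model, 2, "col")
        g4 = snr.sense_gfactor(bhat, model, 4, "col")
        both = g2.defined & g4.defined
        assert both.any()
        assert np.all(g2.g[g2.defined] >= 1 - 1e-9)
        assert np.all(g4.g[both] >= g2.g[both] - 1e-9)


class TestTransmit:
    def test_plane_is_fixed_point_of_smoother(self, acq):
        yy, xx = np.mgrid[0:24, 0:24]
        plane = 1.0 + 0.01 * yy - 0.005 * xx
        tx = TxMap(beta=plane)
        out = snr.smooth_txmap(tx, 75.0, acq)
        np.testing.assert_allclose(out.beta, plane, atol=1e-9)
        assert out.smoothed

    def test_constant_map_unchanged(self, acq):
        out = snr.smooth_txmap(TxMap(beta=np.ones((24, 24))), 75.0, acq)
        np.testing.assert_allclose(out.beta, 1.0, atol=1e-12)

    def test_noise_reduction_on_noisy_plane(self, acq):
        rng = np.random.default_rng(6)
        yy, xx = np.mgrid[0:24, 0:24]
        plane = 1.0 + 0.002 * yy
        noisy = plane + rng.normal(0, 0.1, plane.shape)
        out = snr.smooth_txmap(TxMap(beta=np.maximum(noisy, 0)), 75.0, acq)
        resid_in = (noisy - plane)[6:18, 6:18].std()
        resid_out = (out.beta - plane)[6:18, 6:18].std()
        assert resid_in / resid_out >= 3.0

    def test_loss_closed_form(self):
        loss = snr.tx_snr_loss(np.array([[0.7]]), t1_ms=700.0, tr_ms=1000.0,
                               nominal_flip_deg=70.0)
        assert loss[0, 0] == pytest.approx(0.125, abs=0.002)

    def test_nominal_flip_gives_zero_loss(self):
        loss = snr.tx_snr_loss(np.ones((3, 3)), 700.0, 1000.0, 70.0)
        np.testing.assert_allclose(loss, 0.0, atol=1e-12)

    def test_loss_monotone_below_nominal(self):
        betas = np.linspace(1.0, 0.3, 15)
        loss = snr.tx_snr_loss(betas[None, :], 700.0, 1000.0, 70.0)[0]
        assert np.all(np.diff(loss) > 0)
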