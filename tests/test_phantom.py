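"""Simulator checks against closed forms and known limits."""

import warnings

import numpy as np
import pytest

from csiqa import phantom, recon
from csiqa.datamodel import (
    AcquisitionSpec,
    LoopSpec,
    PhantomSpec,
    ValidationError,
)
from csiqa.filters import BrickwallFilter


class TestPhantomMask:
    def test_cylinder_area_matches_analytic(self, acq, cylinder):
        m = phantom.phantom_mask(cylinder, acq)
        vox_area = np.prod(acq.voxel_size_mm)
        assert m.sum() * vox_area == pytest.approx(np.pi * 125.0 ** 2,
                                                   rel=0.01)

    def test_mirror_symmetry_for_centered_cylinder(self, acq, cylinder):
        m = phantom.phantom_mask(cylinder, acq)
        # voxel coords mirror about the DC column (index N/2), which pairs
        # column j with column N - j for j >= 1
        np.testing.assert_allclose(m[:, 1:], m[:, :0:-1], atol=1e-12)

    def test_zero_diameter_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(diameter_mm=0.0)

    def test_phantom_must_fit_fov(self, acq):
        with pytest.raises(ValidationError):
            phantom.phantom_mask(PhantomSpec(diameter_mm=400.0), acq)


class TestLoopSensitivity:
    def test_on_axis_field_ratio(self, acq):
        # closed form: B(d) / B(0) = a^3 / (a^2 + d^2)^{3/2}; at d = a the
        # ratio is 1/2^{3/2}
        loop = LoopSpec(center_mm=(0, 0, 0), radius_mm=40.0, normal=(0, 0, 1))
        b0 = phantom.loop_sensitivity(loop, acq, slice_z_mm=0.0)
        ba = phantom.loop_sensitivity(loop, acq, slice_z_mm=40.0)
        i0 = acq.matrix[0] // 2
        ratio = abs(ba[i0, i0]) / abs(b0[i0, i0])
        assert ratio == pytest.approx(2.0 ** -1.5, rel=1e-3)

    def test_far_field_decay(self, acq):
        loop = LoopSpec(center_mm=(0, 0, 0), radius_mm=15.0, normal=(0, 0, 1))
        b = phantom.loop_sensitivity(loop, acq, slice_z_mm=0.0)
        i0 = acq.matrix[0] // 2
        far = abs(b[i0, 0])  # 180 mm off-center = 12 radii
        assert far < 0.01 * abs(b[i0, i0])

    def test_mirror_symmetric_magnitudes(self, acq):
        loop = LoopSpec(center_mm=(0, 0, 0), radius_mm=40.0, normal=(0, 0, 1))
        b = np.abs(phantom.loop_sensitivity(loop, acq, slice_z_mm=20.0))
        # grid is symmetric about the DC voxel except for the first row/col
        core = b[1:, 1:]
        np.testing.assert_allclose(core, core[:, ::-1], rtol=1e-9)


class TestTripletFid:
    def test_inphase_and_null_conditions(self, cylinder):
        j = cylinder.j_hz
        t_in = 1000.0 / j   # t + TE = 1/J with TE = 0
        t_null = 500.0 / j
        s = phantom.ethylene_glycol_fid(np.array([t_in, t_null]), cylinder,
                                        te_ms=0.0)
        env = np.exp(-t_in / cylinder.t2star_ms)
        assert abs(s[0]) == pytest.approx(env, rel=1e-9)
        assert abs(s[1]) == pytest.approx(0.0, abs=1e-12)

    def test_singlet_has_pure_exponential_envelope(self):
        spec = PhantomSpec(line_amplitudes=(0, 1, 0), t2star_ms=80.0)
        t = np.linspace(0, 200, 101)
        s = phantom.ethylene_glycol_fid(t, spec, te_ms=2.0)
        np.testing.assert_allclose(np.abs(s), np.exp(-(t + 2.0) / 80.0),
                                   rtol=1e-12)

    def test_negative_time_rejected(self, cylinder):
        with pytest.raises(ValidationError):
            phantom.ethylene_glycol_fid(np.array([-1.0]), cylinder, 0.0)


class TestSimulatedNoise:
    def test_sample_covariance_converges_to_psi(self):
        rec = phantom.simulate_noise(np.eye(4), 10 ** 5, seed=42)
        cov = rec.fid @ rec.fid.conj().T / rec.n_samples
        err = np.linalg.norm(cov - np.eye(4)) / np.linalg.norm(np.eye(4))
        assert err < 0.02

    def test_convergence_rate_with_n(self):
        errs = []
        for n in (10 ** 3, 10 ** 4, 10 ** 5):
            rec = phantom.simulate_noise(np.eye(6), n, seed=9)
            cov = rec.fid @ rec.fid.conj().T / n
            errs.append(np.linalg.norm(cov - np.eye(6)) / np.sqrt(6))
        assert errs[0] > errs[1] > errs[2]

    def test_duplicated_channels_fully_correlated(self):
        psi = np.array([[1.0, 1.0 - 1e-6], [1.0 - 1e-6, 1.0]], complex)
        rec = phantom.simulate_noise(psi, 20000, seed=3)
        c = np.corrcoef(rec.fid[0].real, rec.fid[1].real)[0, 1]
        assert c > 0.99

    def test_non_positive_definite_psi_rejected(self):
        psi = np.array([[1.0, 2.0], [2.0, 1.0]], complex)
        with pytest.raises(ValidationError):
            phantom.simulate_noise(psi, 1000, seed=0)

    def test_coloring_reduces_variance_by_neb(self):
        filt = BrickwallFilter(keep=0.8)
        rec = phantom.simulate_noise(np.eye(2), 2 ** 15, seed=5, coloring=filt)
        var = np.mean(np.abs(rec.fid) ** 2)
        assert var == pytest.approx(0.8, rel=0.03)


class TestSimulateCsi:
    def test_noiseless_roundtrip_recovers_signals(self, acq, cylinder):
        coils = phantom.make_layout("volume")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw, _, gt = phantom.simulate_csi(
                cylinder, coils, acq, np.eye(1, dtype=complex), seed=0,
                noiseless=True)
        img = recon.recon_csi(raw)
        idx, _ = recon.first_inphase_sample(cylinder.j_hz, acq.te_ms, acq)
        s = img[:, :, 0, idx]
        ss = phantom.steady_state_signal(acq.nominal_flip_deg, acq.tr_ms,
                                         cylinder.t1_ms)
        env = phantom.ethylene_glycol_fid(acq.times_ms, cylinder,
                                          acq.te_ms)[idx]
        mask = phantom.phantom_mask(cylinder, acq)
        expected = mask * cylinder.signal_amplitude * ss * env
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_uniform_coil_signal_constant_inside(self, acq, cylinder):
        coils = phantom.make_layout("volume")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw, _, gt = phantom.simulate_csi(
                cylinder, coils, acq, np.eye(1, dtype=complex), seed=0,
                noiseless=True)
        img = recon.recon_csi(raw)
        interior = phantom.phantom_mask(cylinder, acq) == 1.0
        vals = np.abs(img[:, :, 0, 0][interior])
        assert vals.std() / vals.mean() < 0.01

    def test_ground_truth_snr_scalings(self, acq, cylinder):
        """SNR truth scales with amplitude and 1/sqrt(noise variance)."""
        coils = phantom.make_layout("volume")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, gt1 = phantom.simulate_csi(
                cylinder, coils, acq, np.eye(1, dtype=complex), seed=0,
                noiseless=True)
            ph2 = PhantomSpec(signal_amplitude=3.0)
            _, _, gt2 = phantom.simulate_csi(
                ph2, coils, acq, np.eye(1, dtype=complex), seed=0,
                noiseless=True)
            _, _, gt3 = phantom.simulate_csi(
                cylinder, coils, acq, 4.0 * np.eye(1, dtype=complex), seed=0,
                noiseless=True)
        np.testing.assert_allclose(gt2.snr_true, 3.0 * gt1.snr_true,
                                   rtol=1e-9)
        np.testing.assert_allclose(gt3.snr_true, 0.5 * gt1.snr_true,
                                   rtol=1e-9)

    def test_single_channel_pipeline_snr_matches_truth(self, acq):
        """sqrt(2)|s|/sigma recovers the analytic SNR at high amplitude."""
        from csiqa import noisecal, snr
        coils = phantom.make_layout("volume")
        ph = PhantomSpec(signal_amplitude=50.0)
        ratios = []
        for seed in range(10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw, nr, gt = phantom.simulate_csi(
                    ph, coils, acq, np.eye(1, dtype=complex), seed=seed)
            img = recon.recon_csi(raw)
            filt = recon.spectral_filter(img, 10.0, acq)
            idx, t = recon.first_inphase_sample(ph.j_hz, acq.te_ms, acq)
            sig = recon.extract_signal(filt, idx, acq, t)
            model = noisecal.scale_covariance(
                noisecal.estimate_noise_covariance(nr), 1.0)
            m = snr.snr_map_single(sig, model, mask=gt.mask)
            p = recon.band_fraction(10.0, acq)
            exp = gt.expected_pipeline_snr(p)
            i0 = acq.matrix[0] // 2
            ratios.append(m.snr[i0, i0] / exp[i0, i0])
        assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)


def test_layouts_have_expected_channel_counts():
    assert phantom.make_layout("volume").n_channels == 1
    assert phantom.make_layout("array14").n_channels == 14
    assert phantom.make_layout("array8").n_channels == 8
    assert phantom.make_layout("single_loop").n_channels == 1
    with pytest.raises(ValidationError):
        phantom.make_layout("nope")
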