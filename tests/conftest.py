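import warnings

import numpy as np
import pytest

from csiqa.datamodel import AcquisitionSpec, PhantomSpec
from csiqa import noisecal, phantom, recon, sensitivity


@pytest.fixture(scope="session")
def acq():
    """Reference acquisition: 36 cm FOV, 24x24, 5 kHz, 1024 points."""
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def cylinder():
    return PhantomSpec(geometry="cylinder", diameter_mm=250.0)


@pytest.fixture(scope="session")
def array14_sim(acq):
    """One seeded 14-channel cylinder acquisition with ground truth."""
    coils = phantom.make_layout("array14")
    psi = np.eye(coils.n_channels, dtype=complex)
    ph = PhantomSpec(signal_amplitude=600.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw, noise_rec, gt = phantom.simulate_csi(ph, coils, acq, psi, seed=11)
    return raw, noise_rec, gt


@pytest.fixture(scope="session")
def array14_pipeline(acq, array14_sim):
    """Signal map, scaled noise model and estimated sensitivities."""
    raw, noise_rec, gt = array14_sim
    img = recon.recon_csi(raw)
    filt = recon.spectral_filter(img, 10.0, acq)
    idx, t = recon.first_inphase_sample(142.0, acq.te_ms, acq)
    sig = recon.extract_signal(filt, idx, acq, inphase_time_ms=t)
    model = noisecal.scale_covariance(
        noisecal.estimate_noise_covariance(noise_rec), 1.0)
    mask = sensitivity.derive_mask(sig, model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bhat = sensitivity.estimate_sensitivities(sig, model, mask)
    return sig, model, bhat, gt
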