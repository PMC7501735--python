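"""Estimate the channel noise covariance and the bandwidth factor.

The receive filter of a scanner attenuates the band edges, so broadband
noise under-reads the passband noise density; the noise-equivalent
bandwidth (NEB) factor corrects for it.  Here the 'scanner' is emulated
with a raised-cosine receive filter.
"""

import numpy as np

from csiqa import RaisedCosineFilter, simulate_noise, uniform_covariance
from csiqa.noisecal import (
    correlation_matrix,
    estimate_neb_factor,
    estimate_noise_covariance,
    scale_covariance,
)

# 8 channels, correlated within the top 4-channel block
psi_true = uniform_covariance(8, sigma2=1.0, rho=0.4, block=slice(0, 4))
receiver = RaisedCosineFilter(keep=0.8, rolloff=0.2)
noise = simulate_noise(psi_true, n_samples=2 ** 16, seed=3,
                       coloring=receiver)

model = estimate_noise_covariance(noise)
neb = estimate_neb_factor(noise)
print(f"estimated NEB factor: {neb:.3f} "
      f"(analytic for this filter: {receiver.neb_factor():.3f})")

scaled = scale_covariance(model, neb)
print(f"variance scaling: {np.real(scaled.psi[0, 0] / model.psi[0, 0]):.3f}x "
      "(dividing by a factor < 1 raises the variance to the passband level)")

r, r_max, r_mean = correlation_matrix(scaled)
print(f"noise correlation: max {r_max:.2f}, mean {r_mean:.2f} "
      f"(simulated block correlation: 0.40)")
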