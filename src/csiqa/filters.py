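"""Receiver-filter models used to color simulated noise.

Scanner receive chains apply a digital anti-alias filter whose passband is
narrower than the sampled bandwidth, so broadband noise measurements
underestimate the passband noise density.  These filter specs generate that
coloring in simulation and provide the analytic noise-equivalent bandwidth
(NEB) factor that the calibration module must recover.

Frequencies are normalized to the sampling bandwidth: f in [-0.5, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BrickwallFilter", "RaisedCosineFilter", "apply_coloring"]


@dataclass
class BrickwallFilter:
    """Ideal low-pass keeping the central ``keep`` fraction of the band."""

    keep: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.keep <= 1:
            raise ValueError("keep must lie in (0, 1]")

    def response(self, f: np.ndarray) -> np.ndarray:
        return (np.abs(f) <= self.keep / 2).astype(float)

    def neb_factor(self) -> float:
        return self.keep


@dataclass
class RaisedCosineFilter:
    """Flat passband with raised-cosine amplitude roll-off at the edges.

    The response is 1 up to ``keep/2 * (1 - rolloff)``, falls as a
    raised cosine to zero at ``keep/2 * (1 + rolloff)``.
    """

    keep: float = 0.8
    rolloff: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.keep <= 1:
            raise ValueError("keep must lie in (0, 1]")
        if not 0 <= self.rolloff <= 1:
            raise ValueError("rolloff must lie in [0, 1]")
        if self.keep / 2 * (1 + self.rolloff) > 0.5 + 1e-12:
            raise ValueError("roll-off extends beyond the sampled band")

    def response(self, f: np.ndarray) -> np.ndarray:
        f = np.abs(np.asarray(f, dtype=float))
        f1 = self.keep / 2 * (1 - self.rolloff)
        f2 = self.keep / 2 * (1 + self.rolloff)
        h = np.zeros_like(f)
        h[f <= f1] = 1.0
        taper = (f > f1) & (f < f2)
        if f2 > f1:
            h[taper] = 0.5 * (1 + np.cos(np.pi * (f[taper] - f1) / (f2 - f1)))
        return h

    def neb_factor(self) -> float:
        """Mean of |H|^2 over the band relative to the unit plateau."""
        f = np.linspace(-0.5, 0.5, 200001)
        h2 = self.response(f) ** 2
        return float(np.trapezoid(h2, f))


def apply_coloring(fid: np.ndarray, filt) -> np.ndarray:
    """Filter complex time samples along the last axis with ``filt``.

    The filter acts multiplicatively in the frequency domain; no variance
    renormalization is applied, so white input noise comes out with the
    filter's spectral shape and a total variance reduced by the NEB factor
    — exactly what a scanner's receive filter does to thermal noise.
    """
    n = fid.shape[-1]
    f = np.fft.fftfreq(n)
    h = filt.response(f)
    return np.fft.ifft(np.fft.fft(fid, axis=-1) * h, axis=-1)
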