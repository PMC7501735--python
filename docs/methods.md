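# Methods

This note documents the models, conventions and numerical choices behind
`csiqa`, in the spirit of a package reference manual: what is computed,
under which assumptions, and where the design was genuinely open.

## Signal model

The phantom fill is ethylene glycol, whose ¹³C resonance is a 1:2:1
triplet split by J_CH ≈ 142 Hz. The simulated FID envelope is a sum of
three lines at offsets {−J, 0, +J} with weights normalized to unit sum
and a common T2* decay; for the natural 1:2:1 weights this collapses to

    s(t) = A · cos²(πJ(t+TE)) · exp(−(t+TE)/T2*),

with t counted from the start of sampling and TE the excitation-to-
sampling delay. The triplet is fully in phase whenever (t+TE) is an
integer multiple of 1/J; the protocol reads the signal at the first such
sampled time rather than at the spectral peak, because the in-phase
amplitude is insensitive to shim-dependent linewidth. With J = 142 Hz
and echo times of 2.3–3.1 ms the snapped in-phase time is 4.0–4.8 ms
(mean 4.4 ms at the 0.2 ms dwell of the 5 kHz acquisition).

Steady-state weighting sin α(1−E1)/(1−cos α·E1), E1 = exp(−TR/T1), is
applied by default (TR = 1000 ms, T1 = 700 ms, α = 70°); the simulator
can disable it, since the T1-weighting state of a given protocol run is
a scanner-sequence detail.

## Reconstruction scalings

Every transform preserves the noise standard deviation, so that the
separately measured noise variance remains valid at the signal readout:

* spatial DFTs are unitary ("ortho" normalization), centered with the DC
  sample/voxel at index N/2;
* the rectangular ±10 ppm spectral low-pass retains a fraction p of
  spectral points and multiplies the data by 1/√p. Noise keeps its std;
  in-band signal is deliberately scaled by 1/√p — that is the genuine
  SNR gain of discarding out-of-band noise, and it is recorded in the
  provenance block of every pipeline run;
* no zero-filling and no apodization anywhere in the SNR chain.

The simulator produces k-space with the exact inverse of this
convention, so the noiseless round trip is exact to float precision.

## Noise calibration

Ψ is estimated as the sample covariance ⟨n_i n_j*⟩ of the noise-only
FID. Because scanner receive filters attenuate the band edges, the
broadband variance under-reads the passband noise density; the
noise-equivalent bandwidth (NEB) factor corrects it as Ψ_eff = Ψ/f.
Typical measured factors for clinical receivers are ≈ 0.79–0.85, i.e.
the correction *raises* the effective variance.

The NEB estimator is a PSD-plateau ratio: Welch periodograms (Hann
window, 256-sample segments, 50% overlap), channels averaged, factor =
mean PSD over the whole band divided by the median PSD over the central
50% of the band. On white noise it returns 1.0 ± 0.03; for ideal and
raised-cosine filters it matches the analytic ∫|H|²df within 3%. When a
scanner constant is supplied instead, estimates differing from it by
more than ~10% should be treated as a receiver-chain change.

## Coil combination and SNR definition

Single receiver: SNR = √2·|s|/σ, with σ² the scaled complex noise
variance. The √2 expresses SNR relative to the *real* channel noise
component. Arrays use the Roemer matched filter

    SNR = √2 · |bᴴ Ψ⁻¹ s| / √(bᴴ Ψ⁻¹ b),

which is the maximizer of √2|wᴴs|/√(wᴴΨw) over all combination weights
w (verified in tests against brute-force weight search). With the
covariance convention Ψ_ij = E[n_i n_j*] used throughout this package,
the matched filter must be written with the conjugate on b; the
transpose-conjugate variant seen elsewhere corresponds to the opposite
covariance convention and coincides for real-valued Ψ. The expression is
invariant to any positive per-voxel rescaling of b and to simultaneous
per-channel complex gains applied to s, b and Ψ.

The combined background magnitude is Rician (Rayleigh where there is no
signal) for any channel count; sum-of-squares backgrounds follow a
non-central χ law with 2n degrees of freedom. Both facts are enforced by
moment tests at n ∈ {1, 8, 14}; this distribution match is the reason
the optimal combination, not sum-of-squares, underlies cross-coil
comparisons.

## Sensitivity estimation

On a uniform phantom each channel image is itself a noisy estimate of
that channel's complex profile. Profiles are extracted by Perona–Malik
anisotropic diffusion (4-neighbor explicit scheme, conductance
g = exp(−(|∇|/κ)²) computed on the magnitude and applied to real and
imaginary parts jointly, reflecting boundaries, dt ≤ 0.25). Smoothing
real/imag with a shared magnitude-driven conductance preserves phase
structure; smoothing magnitude and phase separately was the open
alternative and is deliberately not used (phase unwrapping at low SNR is
fragile).

The parameter mapping implements a qualitative contract — high edge SNR
⇒ high anisotropy, high overall SNR ⇒ minimal smoothing — as

    κ      = c_κ · σ · max(1, SNR_ref / SNR_edge_max)
    n_iter = clamp(round(c_n / SNR_overall), 2, 200)

with defaults c_κ = 2, SNR_ref = 50, c_n = 400, dt = 0.2, all exposed in
`PMConfig`. The exact constants are this package's choice; the tests pin
only the monotonicity contract and the end-to-end consequence (< 5% SNR
loss versus true profiles at per-channel SNR ≥ 20; in practice the loss
measured on the shipped fixtures is < 0.1%).

Estimated profiles are normalized to unit sum-of-squares per voxel
("sos-unit"); since the SNR expression is invariant to per-voxel
rescaling, this convention cannot bias the result (tested). The support
mask takes voxels whose root-sum-square magnitude exceeds 3× the
root-sum-square noise level, morphologically closed by one voxel; the
threshold is exposed in the pipeline config.

## Summary statistics and g-factors

Center SNR = mean over the 3×3 voxel block centered on the DC voxel
(indices 11–13 of a 24×24 grid, 0-based); surface SNR = in-mask maximum;
line profiles = per-position mean over the three central rows/columns,
anterior–posterior and right–left. Comparison tables normalize each
metric to its per-column maximum (best coil = 100%) and refuse to mix
phantom geometries.

SENSE g-factors use uniform undersampling along one axis; aliasing sets
are index arithmetic i, i+N/R, …; only in-mask set members enter the
sensitivity matrix S, and sets whose normal matrix is numerically
singular (condition > 1e10) are flagged NaN — never clipped. g is
invariant to the overall scale of Ψ, so scaled and unscaled covariances
give identical maps.

Transmit maps (flip-angle scale β relative to nominal) are smoothed by
first-order local polynomial fits over a 7.5 cm square region (uniform
weights, masked voxels, nearest-neighbor fallback below 3 voxels), and
converted to steady-state SNR loss 1 − S(βα)/S(α) with T1 = 700 ms.

## Synthetic data: what it does and does not emulate

The simulator generates: partial-volume support masks (8× supersampling
per axis) for a 250 mm cylinder or a head-shaped ellipse; quasi-static
Biot–Savart receive profiles for circular loops (180-segment line
integration; magnitude |B| per unit current, phase of the circularly
polarized transverse component Bx − iBy); shipped layouts "volume"
(uniform), "array14" (14 × 80 mm loops on a 250 mm ring), "array8" (two
opposed 4-loop paddles) and "single_loop"; and circular complex Gaussian
noise with prescribed channel covariance, optionally colored by a
brick-wall or raised-cosine receiver filter.

Quasi-static fields are justified at the ¹³C Larmor frequency (~32 MHz
at 3 T), where sample loading barely perturbs the field pattern;
coil-noise versus sample-noise regimes are represented only through Ψ.
Not emulated: wavelength effects, coil losses and Q, inter-element
coupling beyond the noise covariance, B0 inhomogeneity beyond a single
global T2*, chemical-shift displacement, and motion. Passing tests
therefore validate the *processing chain* against its own physics model;
they do not certify any specific hardware.

Default study conditions follow the reference protocol (36×36 cm FOV,
24×24, 20 mm slice, 5 kHz, 1024 points, TE 2.7 ms, TR 1000 ms, 70°,
carrier 32.13 MHz; T2* 85 ms, T1 700 ms, J 142 Hz). The fixture signal
amplitude (600 in simulator units with unit noise variance) is set so
the 14-channel array yields center SNR ≈ 30 — the regime reported for
real close-fitting arrays on the 250 mm cylinder — which also places the
per-channel SNR where sensitivity estimation is meaningfully stressed.

## Numerical choices and edge cases

* In-phase snapping: nearest sample; the continuous time is kept in the
  map metadata and the provenance block.
* ppm→Hz conversion uses the container's carrier frequency (default
  32.13 MHz for ¹³C at 3 T).
* Peak positions (J estimation) use 3-point quadratic interpolation on
  the magnitude spectrum; ties break toward lower frequency; fewer than
  three resolvable peaks is an error, not a guess.
* T2* from linewidth: the half-maximum crossings of the center peak are
  located on a trigonometrically interpolated spectrum (16× zero-padded
  re-transform inside the estimator — the SNR chain itself never
  zero-fills) with linear interpolation between grid points. The default
  conversion uses the *magnitude*-lineshape relation T2* = √3/(π·FWHM),
  because the magnitude of a Lorentzian FID has FWHM = √3/(πT2*);
  "absorption" (1/(π·FWHM), for phased spectra) and "plain" (1/FWHM)
  conversions are available. Short readouts truncate the FID and broaden
  the apparent line: at 1024 points × 5 kHz (205 ms window) a true
  T2* of 85 ms reads ~10% low; recovery tests therefore use 4096-point
  FIDs. This is a measurement-window property, not an estimator defect.
* Voxels landing exactly on a simulated loop wire are evaluated at a
  small offset along the loop normal and flagged with a warning.
* Degenerate inputs fail loudly: non-positive-definite Ψ, double NEB
  scaling, R not dividing the matrix, R exceeding the channel count,
  missing noise records, unknown container schema versions.

## Known limitations

* The g-factor maps describe retrospective uniform undersampling; the
  package does not reconstruct actually-undersampled data.
* B1⁺-corrected SNR maps are intentionally not a default output; the
  transmit module only *estimates* the steady-state loss.
* The ISMRMRD adapter is a thin optional hook and assumes one FID per
  acquisition record with standard encode-step indexing; vendor raw
  formats are out of scope.
* 3-D (multi-slice) CSI, spectral model fitting (Lorentzian/Voigt) and
  metabolite quantification are out of scope.
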