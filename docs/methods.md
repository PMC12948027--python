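# Methods

## Model

An SFXM elemental map C_Z(x, y) is treated as a photon-limited image: the
per-pixel fluorescence count is Poisson with mean proportional to
concentration × dwell time, plus a background that the spectrum-fitting
step subtracts using high-statistics information. Two consequences shape
the analysis:

1. element-free pixels fluctuate symmetrically about zero, so the map may
   be negative;
2. the Poisson fluctuations are uncorrelated between pixels, so their
   power spectral density is flat — a constant noise floor S_nf.

Because fluorescence intensity is proportional to concentration, the
amplitude entering the Fourier analysis is ψ = C^(1/2), extended to signed
form ψ = sign(C)·|C|^(1/2) so that negative background fluctuations are not
rectified (rectification would convert zero-mean noise into spurious
broadband power). The azimuthally averaged PSD of natural images declines
approximately linearly in log-log coordinates, motivating the two-component
model

    S(u_r) = P·u_r^a + S_nf,   a < 0.

The estimator fits the power law over a user-selected frequency window
below the knee and averages bins above it; the resolution is the
half-period at the frequency where the fitted trend is SNR_res times the
floor. SNR_res defaults to 5, the Rose criterion for reliable feature
detection; it is a free parameter, and δ_res is strictly increasing in it.

### Assumptions and failure modes

- The signal window must lie below the knee and the noise window above it;
  both are explicit inputs, mirroring interactive cursor selection in
  GUI-based tools. `suggest_fit_ranges` offers a two-segment
  piecewise-linear heuristic (split minimizing total squared residual in
  log-log space) as a starting point only; it is not part of the standard
  protocol.
- A pure-noise image yields a flat trend (a ≈ 0); the fit is returned with
  a validity flag rather than an exception, and knee/resolution derivation
  then refuses to extrapolate (`NoKneeError`).
- If S_nf exceeds the fitted trend at the lower fit bound, the knee lies
  below the fitted range and a warning is issued — the estimate is an
  extrapolation there.

## Numerical choices

- **Transform normalization.** Unnormalized forward DFT (`numpy.fft.fft2`).
  Total 2-D power equals N_total·Σψ² (Parseval, asserted to 1e-10 in
  tests). All resolution quantities depend only on S/S_nf and are invariant
  under rescaling; this invariance is tested to 1e-12.
- **Frequency grid.** Cycles per µm (not angular). For even N_x, u_x spans
  −1/(2Δ_x) … +(N_x/2−1)/(N_x/2)·1/(2Δ_x). Odd dimensions are padded with
  one row/column before transforming; the fill value is the mean of the
  lowest-decile pixels ("average low signal level"), approximating local
  background without injecting a sharp edge. The decile rule is a package
  choice, exposed as a parameter.
- **Anisotropic pitch.** Radii u_r and azimuths are evaluated on the true
  physical frequency grid, so Δ_x ≠ Δ_y scans (e.g. 1 µm × 2 µm) are
  handled without resampling. Maps are analyzed in stage coordinates; the
  scan-axis tilt θ is not folded into the pixel pitch, so resolutions are
  reported in scan coordinates.
- **Radial binning.** Linear bins over (0, u_max], bin value = arithmetic
  mean of member samples, bin center = midpoint; empty bins carry n = 0 and
  S = NaN. The DC sample is excluded by default (it dwarfs the trend); when
  included via flag it joins the first bin. Default bin count
  min(64, min(N)/2).
- **Sectors.** A sector is all samples within ±half_angle (default 30°) of
  one frequency axis, both half-planes, using true angles. The x-axis
  sector probes resolution along x. With 30° half-angles the two sectors
  and their complement partition the plane (boundary ties are impossible
  off the axes since tan 30° is irrational), a property asserted in tests.
- **Trend fit.** Unweighted OLS of log₁₀S on log₁₀u_r; weighting by bin
  occupancy is available behind a flag. Non-positive bins are excluded with
  a warning. The floor is the unweighted mean (median behind a flag).
- **Inverse-square distance fit.** Linearized (I^(−1/2) is linear in Δd)
  followed by a Levenberg–Marquardt refinement of I = α/(d_eff+Δd)²; with
  exact data both agree to ~1e-9 relative. A relative slope below 1e-9
  across the displacement span is treated as non-decaying data (infinite
  distance) and rejected, guarding against float noise in the linear fit.
- **Probe area.** A_beam = π·δ_x·δ_y, the ellipse generalization of the
  symmetric Airy-probe disc π·δ²; this reading reproduces both instrument
  stations' fluence rates from their measured fluxes and directional
  resolutions, which is why it was frozen.
- **Photodiode flux.** Φ = (V − V_dark)·g_s·10⁶·K(E): volts × (µA/V) →
  µA, ×10⁶ → pA, × K (photons pA⁻¹ s⁻¹). K is a supplied calibration
  constant for the specific diode and energy, never derived from the ideal
  silicon pair-creation energy. Dark subtraction is always applied even
  when negligible.
- **Limit of detection.** Blank pixels are rescaled about their mean by
  (t_blank/t_sample)^(1/2) — a pure width correction that matches the
  photon statistics of the sample dwell without shifting the blank's
  center. The threshold is the smallest concentration exceeded by at most
  fp_tolerance corrected blank pixels (default 0 → corrected maximum).
  This is deliberately empirical; decision-theoretic detection limits are
  out of scope.

## Synthetic data: what it emulates and what it does not

`make_phantom` filters white Gaussian noise by |u|^(a₀/2) so the field's
amplitude PSD has log-log slope a₀, shifts it non-negative (affecting only
the excluded DC bin) and squares it into a concentration field with a
requested mean; optional Gaussian hotspots emulate localized elemental
foci. `simulate_scan` convolves with a Gaussian PSF standing in for the
focal spot (real focal spots were measured as FWHMs, not profiles — the
Gaussian is a stand-in, and estimated δ_res need not equal the PSF FWHM;
only monotone correspondence is asserted), draws Poisson counts with
λ = counts_per_unit·C·t_dwell + background_rate·t_dwell, and subtracts the
known expected background, reproducing the negative-pixel statistics of
real background-subtracted maps. `make_powerlaw_psd` samples the 1-D model
directly with mean-one χ²(df)/df multiplicative scatter — the sampling law
of an averaged periodogram bin; its default df = 256 is the mean per-bin
sample count when a 128×128 map is binned into 64 radial bins.

Not emulated: full per-channel spectra and spectrum-fitting artifacts,
detector dead time/pile-up, scan-axis tilt, spatially varying background,
and element cross-talk. Passing tests therefore validate the estimator
against the stated statistical model of SFXM images, not against every
systematic present in real beamline data.

### Default study conditions

End-to-end checks use 128×128 phantoms at 1 µm pitch with spectral slope
−3 (typical of natural images), a 2 µm FWHM PSF, 100 detected counts per
(µg cm⁻²)·s, 20 background counts s⁻¹, and dwell times of 20/50/100 ms —
count levels at which the noise floor is clearly visible, the regime the
method targets. The 1-D fit fixture uses (P, a, S_nf) = (10³, −5, 10⁻²)
with SNR_res = 5 on a 128-point log-spaced grid over 0.5–40 µm⁻¹ (signal
window 0.5–4, noise window 15–40): error propagation of the χ²(256) bin
scatter through the fit gives ≈1% (1σ) in δ_res, comfortably inside the 5%
recovery bound asserted over 100 seeds. These sizes keep the full suite
under a minute.

## Known limitations

- δ_res is a statistical estimate tied to the chosen SNR threshold and fit
  windows; the window-selection sensitivity (a few percent on well-behaved
  PSDs) is quantifiable via `sensitivity_scan` and should be reported with
  the number.
- The power-law model can fail on images with strong periodic structure
  (Bragg-like peaks in the PSD) or on sector averages at radii where the
  sector contains few samples; empty bins are flagged, not imputed.
- The Wiener filter is computed but deliberately not applied to restore
  images; deconvolution is future work.
- The planar solid-angle formula ignores per-element obliquity; it is
  accurate to ~2 significant figures for the geometries it is used on.
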