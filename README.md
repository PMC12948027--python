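# xrfres

Single-image spatial-resolution estimation and beamline calibration for
scanning fluorescence X-ray microscopy (SFXM) elemental maps.

## The problem

An SFXM instrument raster-scans a focused X-ray spot across a sample and
records, per pixel, the characteristic fluorescence of each element. A
spectrum-fitting program turns the raw spectra into per-element maps of
areal mass concentration C_Z(x, y) (µg cm⁻²). The resolution actually
achieved in such a map depends not only on the focal spot but also on
photon statistics: trace elements imaged at short dwell times are noise
limited. Classical two-image methods (Fourier ring correlation) need two
independent scans; this package estimates resolution from a **single**
image via its power spectral density (PSD), and implements the
accompanying beamline-calibration arithmetic (photon flux, detector solid
angle, probe fluence, empirical detection limit).

## The method

Because fluorescence maps are background subtracted, element-free pixels
fluctuate on either side of zero. The analysis therefore works on the
signed amplitude

    ψ(x, y) = sign(C) · |C(x, y)|^(1/2),

whose unnormalized 2-D discrete Fourier transform Ψ(u_x, u_y) gives the
PSD S = |Ψ|². Azimuthal (or ±30° sector, for directional estimates)
averaging produces S(u_r), which for natural images falls as a power law
and flattens at the Poisson noise floor:

    S(u_r) ≈ P · u_r^a + S_nf,    a < 0.

Fitting log₁₀S against log₁₀u_r over a user-chosen window below the knee
gives (P, a); averaging bins above the knee gives S_nf. Then

    u_knee = (S_nf / P)^(1/a)             (trend meets floor)
    u_res  = (SNR_res · S_nf / P)^(1/a)   (trend = SNR_res × floor)
    δ_res  = 1 / (2 · u_res)              (half-period resolution)

with SNR_res = 5 by default (Rose criterion). The same quantities define
the Wiener filter W(u) = S(u)/(S(u) + S_nf), which is exactly ½ at the
knee. Only the ratio S/S_nf matters, so the estimate is independent of the
transform normalization.

Calibration helpers: Φ = (V − V_dark)·g_s·10⁶·K(E) for photodiode flux;
W̃ = W_beam/cos θ for oblique-incidence beam broadening; an inverse-square
fit I(Δd) = α/(d_eff + Δd)² for the effective detector distance;
Ω_eff = N_d·A_act/d_eff² for the collection solid angle;
A_beam = π·δ_x·δ_y and fluence rate Φ/A_beam; and an empirical limit of
detection comparing sample pixels against a blank scan whose histogram
width is rescaled by (t_blank/t_sample)^(1/2).

A synthetic-data module generates phantoms with a prescribed PSD slope,
blurs them with a Gaussian focal spot, and applies dwell-dependent Poisson
counting with background subtraction, so the whole pipeline is testable
against known ground truth.

## Worked example

Simulate a scan of a 128×128 phantom (PSD slope −3, 2 µm focal spot,
50 ms dwell) and estimate its resolution:

```sh
cat > phantom.yaml <<EOF
phantom: {shape: [128, 128], dx: 1.0, dy: 1.0, spectral_slope: -3.0,
          amplitude: 1.0, seed: 7}
scan:    {psf_fwhm_x: 2.0, psf_fwhm_y: 2.0, dwell: 0.05,
          counts_per_unit: 100.0, background_rate: 20.0, seed: 1}
EOF
xrfres simulate --config phantom.yaml --out map.h5
xrfres resolution map.h5 --signal-range 0.02:0.10 --noise-range 0.30:0.50 --snr 5
```

The report (abridged) reads

```json
"fit":        {"P": 2.908, "a": -2.924, "n_points": 7},
"noise_floor":{"S_nf": 1582.8, "n_points": 18},
"resolution": {"u_knee": 0.1160, "u_res": 0.0669,
               "delta_knee": 4.31, "delta_res": 7.48, "snr_res": 5.0}
```

The fitted trend slope −2.92 recovers the phantom's −3 spectral slope; the
trend crosses the noise floor at u_knee = 0.116 cycles µm⁻¹, and demanding
a signal 5× above the floor gives u_res = 0.067 cycles µm⁻¹, i.e. a
half-period resolution δ_res = 7.5 µm — coarser than the 2 µm optic
because at 50 ms dwell the image is photon-statistics limited. Re-running
with `dwell: 0.10` yields δ_res ≈ 6.1 µm: more photons, finer resolution.

Calibration one-liners:

```sh
xrfres solid-angle --nd 7 --area 40 --dist 14.4
# {"omega_eff_sr": 1.3503...}
xrfres fluence --flux 7.7e9 --resx 6.9 --resy 6.4 --dwell 0.05
# {"area_um2": 138.7, "rate_photons_per_um2_s": 5.55e7, "fluence_photons_per_um2": 2.78e6}
```

Other subcommands: `psd` (radial PSD as CSV), `sensitivity` (δ_res spread
over several signal-window choices), `calibrate-distance`, `lod`.

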