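"""Synthetic SFXM data with known ground truth.

Real elemental maps have three features the resolution pipeline must cope
with: a power-law PSD for the underlying concentration structure, blurring
by the finite focal spot, and dwell-time-dependent Poisson counting noise
that — after subtraction of a high-statistics background — leaves
element-free pixels fluctuating on either side of zero.  The generators
here reproduce each feature with controllable parameters so the analysis
can be validated end-to-end:

* :func:`make_phantom` builds a non-negative concentration field whose
  amplitude ψ = C^(1/2) has an azimuthally averaged PSD following a target
  log-log slope (spectrally filtered Gaussian noise), optionally with
  Gaussian hotspots emulating localized elemental foci.
* :func:`simulate_scan` blurs a map with a Gaussian point-spread function
  standing in for the focal spot, draws Poisson counts with expectation
  proportional to concentration and dwell time plus a background rate, and
  converts counts back to a concentration estimate by subtracting the
  known expected background — negative pixels appear where the true
  concentration is near zero, exactly as in background-subtracted real data.
* :func:`make_powerlaw_psd` samples the 1-D generative model
  S(u) = (P·u^a + S_nf)·X directly, with mean-one chi-squared multiplicative
  scatter mimicking the sampling distribution of averaged periodogram bins,
  for testing the trend/floor fitting in isolation.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .maps import ElementalMap
from .psd import RadialPSD

__all__ = [
    "PhantomSpec",
    "ScanSpec",
    "make_phantom",
    "simulate_scan",
    "make_powerlaw_psd",
    "FWHM_TO_SIGMA",
]

# Gaussian FWHM = 2·sqrt(2·ln 2)·σ
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a ground-truth concentration field.

    shape: (N_y, N_x) pixels; dx, dy: pixel pitch [µm]; spectral_slope:
    target log-log PSD slope a₀ < 0 of the field's amplitude spectrum;
    amplitude: mean concentration [µg cm⁻²]; hotspot_count/hotspot_scale:
    optional Gaussian foci (count, 1σ size in µm); seed: RNG seed.
    """

    shape: tuple[int, int] = (256, 256)
    dx: float = 1.0
    dy: float = 1.0
    spectral_slope: float = -3.0
    amplitude: float = 1.0
    hotspot_count: int = 0
    hotspot_scale: float = 5.0
    element: str = "Ca"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.spectral_slope < 0:
            raise ValueError("spectral_slope must be negative")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class ScanSpec:
    """Scanning / counting conditions for a simulated acquisition.

    psf_fwhm_x, psf_fwhm_y: focal-spot FWHM [µm]; dwell: t_dwell [s];
    counts_per_unit: expected detected counts per (µg cm⁻²)·s;
    background_rate: expected background counts per second; seed: RNG seed.
    """

    psf_fwhm_x: float = 2.0
    psf_fwhm_y: float = 2.0
    dwell: float = 0.05
    counts_per_unit: float = 100.0
    background_rate: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("psf_fwhm_x", "psf_fwhm_y", "dwell", "counts_per_unit"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")


def make_phantom(spec: PhantomSpec) -> ElementalMap:
    """Generate a non-negative concentration field with power-law spectrum.

    White Gaussian noise is filtered in the Fourier domain by |u|^(a₀/2) so
    the field's PSD falls as u^a₀; the field is then shifted to be
    non-negative (a constant offset changes only the excluded DC bin) and
    squared-amplitude-scaled so the concentration C = ψ² has the requested
    mean.  Optional Gaussian hotspots are added before the final scaling.
    """
    ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((ny, nx))
    ux = np.fft.fftfreq(nx, d=spec.dx)
    uy = np.fft.fftfreq(ny, d=spec.dy)
    u_r = np.hypot(ux[np.newaxis, :], uy[:, np.newaxis])
    filt = np.zeros_like(u_r)
    nonzero = u_r > 0
    filt[nonzero] = u_r[nonzero] ** (spec.spectral_slope / 2.0)
    psi = np.fft.ifft2(np.fft.fft2(white) * filt).real
    psi -= psi.min()  # non-negative amplitude; shifts only the DC bin

    conc = psi**2
    if spec.hotspot_count > 0:
        yy, xx = np.meshgrid(
            np.arange(ny) * spec.dy, np.arange(nx) * spec.dx, indexing="ij"
        )
        peak = conc.max() if conc.max() > 0 else 1.0
        for _ in range(spec.hotspot_count):
            cy = rng.uniform(0, ny * spec.dy)
            cx = rng.uniform(0, nx * spec.dx)
            conc += peak * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spec.hotspot_scale**2)
            )
    conc *= spec.amplitude / conc.mean()
    return ElementalMap(
        values=conc,
        dx=spec.dx,
        dy=spec.dy,
        element=spec.element,
        dwell=1.0,
        meta={"seed": spec.seed, "spectral_slope": spec.spectral_slope},
    )


def simulate_scan(emap: ElementalMap, spec: ScanSpec) -> ElementalMap:
    """Simulate acquiring a map: PSF blur, Poisson counts, background subtraction.

    Expected counts per pixel are λ = counts_per_unit·C_blur·t_dwell +
    background_rate·t_dwell; observed counts are Poisson(λ).  The returned
    concentration estimate is (counts − background_rate·t_dwell) /
    (counts_per_unit·t_dwell), i.e. the known expected background is
    subtracted as if modeled from high-statistics data, so empty pixels
    fluctuate symmetrically about zero and are negative about half the time.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_y = spec.psf_fwhm_y * FWHM_TO_SIGMA / emap.dy
    sigma_x = spec.psf_fwhm_x * FWHM_TO_SIGMA / emap.dx
    blurred = gaussian_filter(emap.values, sigma=(sigma_y, sigma_x), mode="nearest")
    lam = np.clip(
        spec.counts_per_unit * blurred * spec.dwell
        + spec.background_rate * spec.dwell,
        0.0,
        None,
    )
    counts = rng.poisson(lam).astype(float)
    est = (counts - spec.background_rate * spec.dwell) / (
        spec.counts_per_unit * spec.dwell
    )
    return ElementalMap(
        values=est,
        dx=emap.dx,
        dy=emap.dy,
        element=emap.element,
        dwell=spec.dwell,
        meta={**emap.meta, "scan_seed": spec.seed,
              "psf_fwhm": (spec.psf_fwhm_x, spec.psf_fwhm_y)},
    )


def make_powerlaw_psd(
    P: float,
    a: float,
    S_nf: float,
    u_grid: np.ndarray,
    scatter_df: float | None = 256.0,
    seed: int = 0,
) -> RadialPSD:
    """Sample a radial PSD from the trend-plus-floor generative model.

    S(u) = (P·u^a + S_nf)·X_u, with X_u independent mean-one multiplicative
    fluctuations distributed as χ²(scatter_df)/scatter_df — the sampling law
    of an average of scatter_df squared-magnitude frequency samples.  The
    default of 256 is the mean per-bin sample count when a 128×128 map is
    binned to 64 radial bins.  ``scatter_df=None`` (or ``inf``) gives the
    exact noiseless curve.
    """
    if not (a < 0 and P > 0 and S_nf >= 0):
        raise ValueError("need a < 0, P > 0, S_nf ≥ 0")
    u = np.asarray(u_grid, dtype=float)
    if np.any(u <= 0) or np.any(np.diff(u) <= 0):
        raise ValueError("u_grid must be positive and strictly increasing")
    mean_curve = P * u**a + S_nf
    if scatter_df is None or np.isinf(scatter_df):
        s = mean_curve.copy()
        n = np.ones_like(u, dtype=int)
    else:
        rng = np.random.default_rng(seed)
        s = mean_curve * rng.chisquare(scatter_df, size=u.shape) / scatter_df
        n = np.full(u.shape, int(round(scatter_df)))
    return RadialPSD(u_r=u, S=s, n=n)
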