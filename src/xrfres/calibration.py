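"""Beamline characterization: flux, geometry, solid angle, fluence, LOD.

These are the small closed-form computations that turn raw beamline
readings into the quantities a scanning fluorescence X-ray microscopy
(SFXM) experiment is planned around:

* absolute photon flux Φ from a calibrated photodiode behind a current
  preamplifier, Φ = (V − V_dark) · g_s · 10⁶ · K(E), where g_s is the
  preamplifier gain in µA V⁻¹ and K(E) the photodiode's photon-flux to
  photocurrent conversion in photons pA⁻¹ s⁻¹;
* beam broadening W̃ = W_beam / cos θ on a sample tilted by θ from normal
  incidence;
* the effective sample-to-detector distance d_eff from an inverse-square
  fit I(Δd) = α / (d_eff + Δd)² to intensities at a few detector
  displacements, and from it the effective collection solid angle
  Ω_eff = N_d · A_act / d_eff² (planar small-solid-angle approximation;
  per-element obliquity is ignored);
* probe area A_beam = π·δ_x·δ_y from the directional resolutions (the
  symmetric Airy case reduces to π·δ²), and fluence per time Φ/A_beam;
* an empirical limit of detection from the histogram of a blank scan,
  with the blank's distribution width rescaled by (t_blank/t_sample)^(1/2)
  to match the sample's photon statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "PhotodiodeReading",
    "BeamGeometry",
    "DisplacementSeries",
    "DetectorGeometry",
    "FluenceReport",
    "LodEstimate",
    "photon_flux",
    "effective_beam_width",
    "fit_detector_distance",
    "solid_angle",
    "beam_area",
    "fluence_rate",
    "fluence",
    "fluence_report",
    "lod_estimate",
]


class InvalidSignalError(ValueError):
    """Photodiode signal is not above the dark level."""


class FitFailureError(RuntimeError):
    """The inverse-square distance fit has no physical solution."""


@dataclass(frozen=True)
class PhotodiodeReading:
    """Preamplified photodiode measurement.

    V: output voltage [V]; g_s: gain sensitivity [µA V⁻¹]; K: photon-flux
    to photocurrent conversion K(E) [photons pA⁻¹ s⁻¹], a supplied
    calibration constant for the diode at the working energy; dark_V:
    dark-signal voltage [V].
    """

    V: float
    g_s: float
    K: float = 2382.0
    dark_V: float = 0.0

    def __post_init__(self) -> None:
        if not (self.g_s > 0 and self.K > 0):
            raise ValueError("gain sensitivity and conversion factor must be positive")


@dataclass(frozen=True)
class BeamGeometry:
    """Sample tilt θ [degrees, 0 ≤ θ < 90] and beam width at normal incidence [µm]."""

    theta: float
    W_beam: float

    def __post_init__(self) -> None:
        if not 0 <= self.theta < 90:
            raise ValueError("tilt must satisfy 0 ≤ θ < 90 degrees")
        if not self.W_beam > 0:
            raise ValueError("beam width must be positive")


@dataclass(frozen=True)
class DisplacementSeries:
    """Detector displacements Δd [mm] with mean fluorescence intensities [s⁻¹]."""

    displacement: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        dd = np.asarray(self.displacement, dtype=float)
        ii = np.asarray(self.intensity, dtype=float)
        if dd.shape != ii.shape or dd.ndim != 1:
            raise ValueError("displacement and intensity must be matching 1-D arrays")
        if np.unique(dd).size < 3:
            raise ValueError("need ≥ 3 distinct displacements")
        if np.any(ii <= 0):
            raise ValueError("intensities must be positive")
        object.__setattr__(self, "displacement", dd)
        object.__setattr__(self, "intensity", ii)


@dataclass(frozen=True)
class DetectorGeometry:
    """N_d active elements of area A_act [mm²] each at distance d_eff [mm]."""

    N_d: int
    A_act: float
    d_eff: float

    def __post_init__(self) -> None:
        if self.N_d < 1 or self.A_act <= 0 or self.d_eff <= 0:
            raise ValueError("need N_d ≥ 1, A_act > 0, d_eff > 0")


@dataclass(frozen=True)
class FluenceReport:
    """Flux Φ [photons s⁻¹], probe area [µm²], fluence rate [photons µm⁻² s⁻¹]
    and cumulative fluence [photons µm⁻²] at a stated dwell time."""

    phi: float
    area: float
    rate: float
    fluence: float
    t_dwell: float


@dataclass(frozen=True)
class LodEstimate:
    """Empirical detection limit.

    threshold: smallest concentration [µg cm⁻²] exceeded by at most
    ``fp_count`` width-corrected blank pixels; width_correction: the
    (t_blank/t_sample)^(1/2) factor applied to the blank distribution.
    """

    threshold: float
    width_correction: float
    fp_count: int


def photon_flux(r: PhotodiodeReading) -> float:
    """Absolute photon flux Φ = (V − dark)·g_s·10⁶·K in photons s⁻¹.

    The voltage times the gain gives the photocurrent in µA; the 10⁶
    converts to pA, matching the units of K(E).
    """
    if r.V <= r.dark_V:
        raise InvalidSignalError(
            f"signal voltage {r.V} V not above dark level {r.dark_V} V"
        )
    return (r.V - r.dark_V) * r.g_s * 1.0e6 * r.K


def effective_beam_width(g: BeamGeometry) -> float:
    """Beam width along the scan direction on a tilted sample: W̃ = W/cos θ."""
    return g.W_beam / np.cos(np.radians(g.theta))


def fit_detector_distance(s: DisplacementSeries, refine: bool = True) -> tuple[float, float]:
    """Fit I(Δd) = α/(d_eff + Δd)² and return (d_eff, α).

    The fit is linearized — I^(−1/2) is linear in Δd with slope 1/√α and
    intercept d_eff/√α — then optionally refined by nonlinear least squares
    on the original model (with exact data the two agree).

    Raises
    ------
    FitFailureError
        When the data are incompatible with a decaying inverse square law
        (e.g. constant intensity, implying infinite distance).
    """
    dd, ii = s.displacement, s.intensity
    y = ii ** -0.5
    slope, intercept = np.polyfit(dd, y, 1)
    # a relative slope below machine-noise level means the intensity does not
    # decay over the displacement span (infinite effective distance)
    if slope <= 0 or intercept <= 0 or slope * np.ptp(dd) < 1e-9 * intercept:
        raise FitFailureError(
            "intensities do not decay as an inverse square law with displacement"
        )
    d_eff = intercept / slope
    alpha = 1.0 / slope**2
    if refine:
        def resid(p: np.ndarray) -> np.ndarray:
            return p[1] / (p[0] + dd) ** 2 - ii

        sol = least_squares(resid, x0=[d_eff, alpha], method="lm")
        if sol.x[0] > 0 and sol.x[1] > 0:
            d_eff, alpha = float(sol.x[0]), float(sol.x[1])
    return float(d_eff), float(alpha)


def solid_angle(g: DetectorGeometry) -> float:
    """Effective collection solid angle Ω_eff = N_d·A_act/d_eff² [sr]."""
    return g.N_d * g.A_act / g.d_eff**2


def beam_area(delta_x: float, delta_y: float) -> float:
    """Probe area A_beam = π·δ_x·δ_y [µm²] from directional resolutions.

    For a symmetric Airy probe δ_x = δ_y = δ this is π·δ², the disc whose
    radius is the first-minimum resolution; the elliptical generalization
    covers astigmatic probes.
    """
    if not (delta_x > 0 and delta_y > 0):
        raise ValueError("resolutions must be positive")
    return np.pi * delta_x * delta_y


def fluence_rate(phi: float, area: float) -> float:
    """Fluence per time Φ/A_beam [photons µm⁻² s⁻¹]."""
    if not (phi > 0 and area > 0):
        raise ValueError("flux and area must be positive")
    return phi / area


def fluence(rate: float, t_dwell: float) -> float:
    """Cumulative fluence = rate · t_dwell [photons µm⁻²]."""
    if not (rate > 0 and t_dwell > 0):
        raise ValueError("rate and dwell time must be positive")
    return rate * t_dwell


def fluence_report(
    phi: float, delta_x: float, delta_y: float, t_dwell: float
) -> FluenceReport:
    """Convenience chain: flux + directional resolutions → full fluence report."""
    area = beam_area(delta_x, delta_y)
    rate = fluence_rate(phi, area)
    return FluenceReport(
        phi=phi, area=area, rate=rate, fluence=fluence(rate, t_dwell), t_dwell=t_dwell
    )


def dwell_width_correction(t_sample: float, t_blank: float) -> float:
    """Statistical width correction (t_blank/t_sample)^(1/2) between scans
    taken at different dwell times."""
    if not (t_sample > 0 and t_blank > 0):
        raise ValueError("dwell times must be positive")
    return float(np.sqrt(t_blank / t_sample))


def lod_estimate(
    sample_pixels: np.ndarray,
    blank_pixels: np.ndarray,
    t_sample: float,
    t_blank: float,
    fp_tolerance: int = 0,
) -> LodEstimate:
    """Empirical limit of detection from sample vs blank pixel histograms.

    The blank pixel values are rescaled about their mean by
    (t_blank/t_sample)^(1/2) so their spread matches the photon statistics
    of the sample dwell time; the threshold is then the smallest
    concentration exceeded by at most ``fp_tolerance`` corrected blank
    pixels (``fp_tolerance = 0`` gives the corrected-blank maximum).

    This is deliberately empirical; rigorous detection-limit theory with
    controlled false-positive/negative rates is out of scope.
    """
    sample = np.asarray(sample_pixels, dtype=float).ravel()
    blank = np.asarray(blank_pixels, dtype=float).ravel()
    if sample.size == 0 or blank.size == 0:
        raise ValueError("sample and blank pixel sets must be non-empty")
    if fp_tolerance < 0 or fp_tolerance >= blank.size:
        raise ValueError("fp_tolerance must be in [0, n_blank)")
    if blank.size < 100:
        warnings.warn(
            f"only {blank.size} blank pixels; detection limit has low statistics",
            stacklevel=2,
        )
    w = dwell_width_correction(t_sample, t_blank)
    corrected = blank.mean() + (blank - blank.mean()) * w
    # (fp_tolerance+1)-th largest corrected blank: at most fp_tolerance above it
    threshold = float(np.sort(corrected)[blank.size - 1 - fp_tolerance])
    fp = int(np.count_nonzero(corrected > threshold))
    return LodEstimate(threshold=threshold, width_correction=w, fp_count=fp)
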