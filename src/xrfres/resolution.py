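"""Power-law fit, noise floor, and SNR-thresholded resolution.

For photon-limited images the azimuthally averaged PSD follows a power-law
signal trend

    S(u_r) ≈ P · u_r^a,   a < 0,

at low spatial frequency, flattening into a constant noise floor S_nf at
high frequency because uncorrelated per-pixel Poisson noise is spectrally
flat.  The "knee" is the frequency where the fitted trend meets the floor,

    u_knee = (S_nf / P)^(1/a),

and the resolution-defining frequency requires the signal trend to exceed
the floor by a factor SNR_res (Rose criterion, default 5):

    u_res = (SNR_res · S_nf / P)^(1/a),   δ_res = 1 / (2 u_res),

a half-period spatial resolution.  The same trend and floor define the
Wiener filter W(u) = S(u) / (S(u) + S_nf), with W(u_knee) = 1/2.

All of these depend only on the ratio S/S_nf, so the estimate is invariant
under rescaling of the PSD (and hence under the DFT normalization choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .psd import RadialPSD

__all__ = [
    "FitRange",
    "PowerLawFit",
    "NoiseFloor",
    "ResolutionResult",
    "WienerCurve",
    "InsufficientDataError",
    "NoKneeError",
    "fit_signal_trend",
    "estimate_noise_floor",
    "knee_frequency",
    "resolution_frequency",
    "wiener_filter",
    "sensitivity_scan",
    "suggest_fit_ranges",
]


class InsufficientDataError(ValueError):
    """Too few usable PSD bins inside the requested fit range."""


class NoKneeError(ValueError):
    """The fitted trend never crosses the noise floor (e.g. slope a ≥ 0)."""


@dataclass(frozen=True)
class FitRange:
    """A spatial-frequency interval [u_lo, u_hi] in cycles µm⁻¹."""

    u_lo: float
    u_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.u_lo < self.u_hi:
            raise ValueError(f"need 0 < u_lo < u_hi, got [{self.u_lo}, {self.u_hi}]")

    def contains(self, u: np.ndarray) -> np.ndarray:
        return (u >= self.u_lo) & (u <= self.u_hi)


@dataclass(frozen=True)
class PowerLawFit:
    """Signal trend S(u) = P·u^a fitted over ``range`` on ``n_points`` bins.

    ``valid`` is False when the fitted slope is non-negative, which occurs
    legitimately on pure-noise images; downstream knee/resolution steps
    then refuse to extrapolate.
    """

    P: float
    a: float
    range: FitRange
    n_points: int

    @property
    def valid(self) -> bool:
        return self.a < 0

    def __call__(self, u: np.ndarray | float) -> np.ndarray | float:
        return self.P * np.asarray(u, dtype=float) ** self.a


@dataclass(frozen=True)
class NoiseFloor:
    """Flat noise-floor level S_nf averaged over ``n_points`` bins."""

    S_nf: float
    range: FitRange
    n_points: int


@dataclass(frozen=True)
class ResolutionResult:
    """Knee and resolution frequencies with their half-period lengths (µm,
    or whatever length unit the pixel pitch was expressed in)."""

    u_knee: float
    u_res: float
    delta_knee: float
    delta_res: float
    snr_res: float


@dataclass(frozen=True)
class WienerCurve:
    """Wiener filter W(u) = S(u)/(S(u) + S_nf) sampled on ``u``."""

    u: np.ndarray
    W: np.ndarray


def _in_range(psd: RadialPSD, rng: FitRange) -> tuple[np.ndarray, np.ndarray]:
    sel = rng.contains(psd.u_r) & psd.valid
    return psd.u_r[sel], psd.S[sel]


def fit_signal_trend(
    psd: RadialPSD,
    rng: FitRange,
    weight_by_counts: bool = False,
) -> PowerLawFit:
    """Fit log10 S = log10 P + a·log10 u by least squares over a range.

    Bins with S ≤ 0 (possible after mean-subtraction artifacts) are excluded
    with a warning.  ``weight_by_counts`` weights each bin by its sample
    count n; the default is unweighted.
    """
    u, s = _in_range(psd, rng)
    bad = s <= 0
    if np.any(bad):
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive PSD bins from signal fit",
            stacklevel=2,
        )
    u, s = u[~bad], s[~bad]
    if u.size < 2:
        raise InsufficientDataError(
            f"signal fit needs ≥ 2 usable bins in [{rng.u_lo}, {rng.u_hi}], "
            f"found {u.size}"
        )
    x, y = np.log10(u), np.log10(s)
    if weight_by_counts:
        sel = rng.contains(psd.u_r) & psd.valid & (psd.S > 0)
        w = psd.n[sel].astype(float)
    else:
        w = None
    a, logp = np.polyfit(x, y, 1, w=w)
    fit = PowerLawFit(P=float(10.0 ** logp), a=float(a), range=rng, n_points=int(u.size))
    if not fit.valid:
        warnings.warn(
            f"fitted slope a = {fit.a:.3g} is non-negative; trend flagged invalid",
            stacklevel=2,
        )
    return fit


def estimate_noise_floor(
    psd: RadialPSD,
    rng: FitRange,
    robust: bool = False,
) -> NoiseFloor:
    """Noise floor S_nf = mean of PSD bins above the approximate knee.

    ``robust=True`` uses the median instead of the mean for outlier
    resistance.
    """
    u, s = _in_range(psd, rng)
    if u.size < 1:
        raise InsufficientDataError(
            f"noise floor needs ≥ 1 bin in [{rng.u_lo}, {rng.u_hi}]"
        )
    level = float(np.median(s) if robust else np.mean(s))
    return NoiseFloor(S_nf=level, range=rng, n_points=int(u.size))


def _check_knee_inputs(fit: PowerLawFit, floor: NoiseFloor) -> None:
    if fit.a >= 0:
        raise NoKneeError(
            f"slope a = {fit.a:.3g} ≥ 0: trend never decays to the noise floor"
        )
    if not (fit.P > 0 and floor.S_nf > 0):
        raise NoKneeError("need P > 0 and S_nf > 0")
    if floor.S_nf >= fit(fit.range.u_lo):
        warnings.warn(
            "noise floor exceeds the fitted trend at the lower fit bound; "
            "the knee lies below the fitted frequency range",
            stacklevel=3,
        )


def knee_frequency(fit: PowerLawFit, floor: NoiseFloor) -> float:
    """Frequency u_knee where the signal trend equals the noise floor.

    Solves P·u^a = S_nf, i.e. u_knee = (S_nf/P)^(1/a).
    """
    _check_knee_inputs(fit, floor)
    return float((floor.S_nf / fit.P) ** (1.0 / fit.a))


def resolution_frequency(
    fit: PowerLawFit,
    floor: NoiseFloor,
    snr_res: float = 5.0,
) -> ResolutionResult:
    """Resolution frequency and half-period resolution at a given SNR.

    u_res solves P·u^a = snr_res·S_nf and δ_res = 1/(2·u_res); snr_res = 1
    reduces to the knee.  The default snr_res = 5 is the Rose criterion for
    a reliably detected feature.
    """
    if not snr_res > 0:
        raise ValueError("snr_res must be positive")
    u_knee = knee_frequency(fit, floor)
    u_res = float((snr_res * floor.S_nf / fit.P) ** (1.0 / fit.a))
    return ResolutionResult(
        u_knee=u_knee,
        u_res=u_res,
        delta_knee=1.0 / (2.0 * u_knee),
        delta_res=1.0 / (2.0 * u_res),
        snr_res=float(snr_res),
    )


def wiener_filter(
    fit: PowerLawFit,
    floor: NoiseFloor,
    u: np.ndarray,
) -> WienerCurve:
    """Wiener filter W(u) = S(u)/(S(u) + S_nf) with S(u) = P·u^a.

    W ∈ (0, 1), monotonically non-increasing for a < 0, and exactly 1/2 at
    the knee frequency.
    """
    _check_knee_inputs(fit, floor)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("frequency samples must be positive")
    s = fit(u)
    return WienerCurve(u=u, W=s / (s + floor.S_nf))


def sensitivity_scan(
    psd: RadialPSD,
    ranges: list[FitRange],
    noise_range: FitRange,
    snr_res: float = 5.0,
) -> tuple[list[ResolutionResult | None], float]:
    """Resolution estimates for several signal-range selections.

    Mirrors the protocol of re-fitting the signal trend over different
    frequency windows to probe how sensitive δ_res is to the selection.
    Returns one result per range (None where a range fails, with a warning)
    and the relative spread max/min − 1 of δ_res over the successes.
    """
    if len(ranges) < 2:
        raise ValueError("sensitivity scan needs ≥ 2 signal ranges")
    floor = estimate_noise_floor(psd, noise_range)
    results: list[ResolutionResult | None] = []
    for rng in ranges:
        try:
            fit = fit_signal_trend(psd, rng)
            results.append(resolution_frequency(fit, floor, snr_res))
        except (InsufficientDataError, NoKneeError) as exc:
            warnings.warn(f"range [{rng.u_lo}, {rng.u_hi}] failed: {exc}", stacklevel=2)
            results.append(None)
    deltas = [r.delta_res for r in results if r is not None]
    if not deltas:
        raise InsufficientDataError("every signal range failed")
    spread = max(deltas) / min(deltas) - 1.0
    return results, float(spread)


def suggest_fit_ranges(psd: RadialPSD) -> tuple[FitRange, FitRange]:
    """Automatic signal/noise range heuristic (not part of the standard
    manual-selection protocol).

    Fits a two-segment piecewise-linear model in log-log space, choosing
    the split that minimizes total squared residual; the left segment
    becomes the signal range, the right the noise range.  Intended as a
    starting point — inspect the PSD before trusting it.
    """
    sel = psd.valid & (psd.S > 0) & (psd.u_r > 0)
    u, s = psd.u_r[sel], psd.S[sel]
    if u.size < 6:
        raise InsufficientDataError("range heuristic needs ≥ 6 usable bins")
    x, y = np.log10(u), np.log10(s)

    def sse(xx: np.ndarray, yy: np.ndarray) -> float:
        if xx.size < 2:
            return 0.0
        coef = np.polyfit(xx, yy, 1)
        r = yy - np.polyval(coef, xx)
        return float(r @ r)

    best_k, best_cost = None, np.inf
    for k in range(3, u.size - 2):
        cost = sse(x[:k], y[:k]) + sse(x[k:], y[k:])
        if cost < best_cost:
            best_k, best_cost = k, cost
    assert best_k is not None
    signal = FitRange(float(u[0]), float(u[best_k - 1]))
    noise = FitRange(float(u[best_k]), float(u[-1]))
    return signal, noise
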