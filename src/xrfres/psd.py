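"""Power spectral density of elemental maps.

The resolution analysis works on the signed amplitude ψ(x, y) of a
concentration map rather than the concentration itself: for fluorescence,
C_Z ∝ detected intensity, so the amplitude entering the Fourier transform
is ψ = C^(1/2).  Background-subtracted maps contain negative pixels where
the element is absent; those get ψ = −|C|^(1/2) so that the Poisson
fluctuations about zero keep their sign structure instead of being
rectified into spurious high-frequency power.

The 2-D PSD is S(u_x, u_y) = |Ψ(u_x, u_y)|² with Ψ the unnormalized
forward discrete Fourier transform of ψ.  Only ratios of PSD values enter
the resolution estimate, so the transform normalization drops out; the
unnormalized forward convention is used throughout and asserted in tests.

Spatial frequencies are cycles per µm.  For an even number of pixels N_x
at pitch Δ_x, u_x runs from −1/(2Δ_x) to +b_x/(2Δ_x) with
b_x = (N_x/2 − 1)/(N_x/2), and analogously for u_y.  Anisotropic pitch
(Δ_x ≠ Δ_y) is handled by evaluating radii and azimuths on the true
physical frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .maps import ElementalMap, InvalidMapError

__all__ = [
    "AmplitudeMap",
    "PowerSpectrum2D",
    "RadialPSD",
    "SectorSpec",
    "signed_amplitude",
    "pad_to_even",
    "psd2d",
    "azimuthal_average",
    "sector_average",
    "default_n_bins",
]


@dataclass(frozen=True)
class AmplitudeMap:
    """Signed amplitude ψ(x, y) in (µg cm⁻²)^(1/2), with pixel pitch in µm."""

    values: np.ndarray
    dx: float
    dy: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PowerSpectrum2D:
    """2-D power spectral density S(u_x, u_y) ≥ 0 on a shifted frequency grid.

    ``ux_grid`` and ``uy_grid`` are 1-D axes in cycles µm⁻¹, monotonically
    increasing with zero frequency at index N//2 (numpy fftshift layout).
    """

    values: np.ndarray
    ux_grid: np.ndarray
    uy_grid: np.ndarray

    def radial_grid(self) -> np.ndarray:
        """Radial frequency u_r = (u_x² + u_y²)^(1/2) at every sample."""
        return np.hypot(self.ux_grid[np.newaxis, :], self.uy_grid[:, np.newaxis])

    def azimuth_grid(self) -> np.ndarray:
        """Azimuth folded to [0°, 90°]: angle between (u_x, u_y) and the x axis.

        Folding uses |u_x|, |u_y|, i.e. a sector about an axis automatically
        includes the reflected half-plane.
        """
        return np.degrees(
            np.arctan2(
                np.abs(self.uy_grid)[:, np.newaxis],
                np.abs(self.ux_grid)[np.newaxis, :],
            )
        )


@dataclass(frozen=True)
class RadialPSD:
    """Radially binned 1-D power spectrum.

    ``u_r`` are bin-center frequencies (strictly increasing), ``S`` the mean
    power of member samples (NaN where a bin is empty) and ``n`` the number
    of 2-D frequency samples per bin; ``n == 0`` flags an empty bin.
    """

    u_r: np.ndarray
    S: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u_r, dtype=float)
        if u.ndim != 1 or np.any(np.diff(u) <= 0):
            raise ValueError("bin centers u_r must be 1-D and strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-empty bins."""
        return self.n > 0


@dataclass(frozen=True)
class SectorSpec:
    """An azimuthal sector of half-width ``half_angle`` about a frequency axis.

    ``axis="horizontal"`` selects samples within ±half_angle of the u_x axis
    (both half-planes) and probes resolution along x; ``"vertical"``
    analogously for u_y / resolution along y.
    """

    axis: str
    half_angle: float = 30.0

    _ALIASES = {"horizontal": "horizontal", "x": "horizontal",
                "vertical": "vertical", "y": "vertical"}

    def __post_init__(self) -> None:
        key = str(self.axis).lower()
        if key not in self._ALIASES:
            raise ValueError(f"axis must be horizontal/x or vertical/y, got {self.axis!r}")
        object.__setattr__(self, "axis", self._ALIASES[key])
        if not 0 < self.half_angle <= 45:
            raise ValueError("half_angle must be in (0, 45] degrees")


def signed_amplitude(emap: ElementalMap) -> AmplitudeMap:
    """Signed square-root amplitude ψ of a concentration map.

    ψ = +|C|^(1/2) where C ≥ 0 and ψ = −|C|^(1/2) where C < 0, preserving
    the sign of background-subtraction fluctuations in element-free pixels.
    """
    c = emap.values
    psi = np.sign(c) * np.sqrt(np.abs(c))
    return AmplitudeMap(values=psi, dx=emap.dx, dy=emap.dy)


def low_signal_fill(values: np.ndarray, decile: float = 0.1) -> float:
    """Average low-signal level of a map: mean of its lowest-decile pixels.

    Used as the padding value so that appended rows/columns approximate
    local background without injecting a high-contrast edge.
    """
    flat = np.sort(values.ravel())
    k = max(1, int(np.ceil(decile * flat.size)))
    return float(flat[:k].mean())


def pad_to_even(emap: ElementalMap, fill: float | None = None) -> ElementalMap:
    """Pad a map with one row and/or column so both dimensions are even.

    Appended pixels take ``fill``; by default the map's average low signal
    level (mean of the lowest decile).  Even-dimension input is returned
    unchanged.
    """
    ny, nx = emap.shape
    if ny % 2 == 0 and nx % 2 == 0:
        return emap
    if fill is None:
        fill = low_signal_fill(emap.values)
    out = np.full((ny + ny % 2, nx + nx % 2), fill, dtype=float)
    out[:ny, :nx] = emap.values
    return emap.with_values(out)


def psd2d(amp: AmplitudeMap) -> PowerSpectrum2D:
    """2-D power spectral density S = |Ψ|² of a signed amplitude map.

    Ψ is the unnormalized forward DFT of ψ; the output grid is fftshifted
    so frequencies increase monotonically along each axis.

    Raises
    ------
    InvalidMapError
        If either dimension is odd; call :func:`pad_to_even` on the
        concentration map first.
    """
    ny, nx = amp.shape
    if ny % 2 or nx % 2:
        raise InvalidMapError(
            f"psd2d requires even dimensions, got {ny}×{nx}; apply pad_to_even first"
        )
    spec = np.fft.fftshift(np.fft.fft2(amp.values))
    s = np.abs(spec) ** 2
    ux = np.fft.fftshift(np.fft.fftfreq(nx, d=amp.dx))
    uy = np.fft.fftshift(np.fft.fftfreq(ny, d=amp.dy))
    return PowerSpectrum2D(values=s, ux_grid=ux, uy_grid=uy)


def default_n_bins(shape: tuple[int, int]) -> int:
    """Default radial bin count: min(64, floor(min(N_y, N_x)/2))."""
    return int(min(64, min(shape) // 2))


def _bin_radial(
    s_values: np.ndarray,
    radii: np.ndarray,
    mask: np.ndarray,
    n_bins: int,
) -> RadialPSD:
    """Bin selected PSD samples into linear radial bins over (0, u_max]."""
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    u = radii[mask]
    s = s_values[mask]
    if u.size == 0:
        raise ValueError("no frequency samples selected for radial binning")
    u_max = float(radii.max())  # full-grid extent, so sector bins are comparable
    edges = np.linspace(0.0, u_max, n_bins + 1)
    # bin i covers (edges[i], edges[i+1]]; a DC sample, when not excluded
    # upstream, is assigned to the first bin
    idx = np.digitize(u, edges, right=True) - 1
    idx[u == 0] = 0
    keep = idx >= 0
    idx, s = idx[keep], s[keep]
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=s, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if np.any(counts == 0):
        warnings.warn(
            f"{int((counts == 0).sum())} of {n_bins} radial bins are empty",
            stacklevel=3,
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialPSD(u_r=centers, S=means, n=counts)


def azimuthal_average(
    s2: PowerSpectrum2D,
    n_bins: int | None = None,
    exclude_dc: bool = True,
) -> RadialPSD:
    """Azimuthally averaged PSD S(u_r).

    Each 2-D sample is assigned to the linear radial bin containing its
    u_r = (u_x² + u_y²)^(1/2); the bin value is the arithmetic mean of the
    member samples.  The DC sample is excluded by default since it dwarfs
    the power-law trend.
    """
    if n_bins is None:
        n_bins = default_n_bins(s2.values.shape)
    radii = s2.radial_grid()
    mask = np.ones_like(radii, dtype=bool)
    if exclude_dc:
        mask &= radii > 0
    return _bin_radial(s2.values, radii, mask, n_bins)


def sector_average(
    s2: PowerSpectrum2D,
    sector: SectorSpec,
    n_bins: int | None = None,
    exclude_dc: bool = True,
) -> RadialPSD:
    """Directional PSD restricted to an azimuthal sector about one axis.

    Identical binning to :func:`azimuthal_average` but keeping only samples
    whose azimuth lies within ±half_angle of the chosen axis (the axis and
    its reflection, i.e. both half-planes).  Bins whose sector is empty at
    some radius are flagged with ``n == 0``.
    """
    if n_bins is None:
        n_bins = default_n_bins(s2.values.shape)
    radii = s2.radial_grid()
    az = s2.azimuth_grid()
    if sector.axis == "horizontal":
        mask = az <= sector.half_angle
    else:
        mask = (90.0 - az) <= sector.half_angle
    if exclude_dc:
        mask &= radii > 0
    return _bin_radial(s2.values, radii, mask, n_bins)
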