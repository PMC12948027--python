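"""Elemental concentration maps.

The central container is :class:`ElementalMap`, a 2-D grid of areal mass
concentration C_Z(x, y) in µg cm⁻² for a single element Z, together with
the pixel pitch of the raster scan and the per-pixel dwell time.  Maps
produced by spectrum-fitting programs are background subtracted, so pixels
free of the element fluctuate on either side of zero; negative values are
therefore allowed and meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InvalidMapError(ValueError):
    """Raised when a concentration map violates its structural invariants."""


@dataclass(frozen=True)
class ElementalMap:
    """A 2-D areal mass-concentration map with scan metadata.

    Parameters
    ----------
    values : ndarray, shape (N_y, N_x)
        Concentration C_Z(x, y) in µg cm⁻².  Row 0 is the top of the image
        and x is the fast scan axis.  May contain negative values from
        background subtraction.
    dx, dy : float
        Pixel pitch Δ_x, Δ_y in µm along the fast (x) and slow (y) axes.
    element : str
        Chemical symbol of the mapped element (e.g. ``"Ca"``).
    dwell : float
        Per-pixel exposure time t_dwell in seconds.
    """

    values: np.ndarray
    dx: float
    dy: float
    element: str = ""
    dwell: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidMapError(
                f"map must be a non-empty 2-D grid, got shape {arr.shape}"
            )
        if not (self.dx > 0 and self.dy > 0):
            raise InvalidMapError("pixel pitch dx, dy must be positive")
        if not self.dwell > 0:
            raise InvalidMapError("dwell time must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ElementalMap":
        """Return a copy of this map with replaced pixel values."""
        return replace(self, values=np.asarray(values, dtype=float))
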