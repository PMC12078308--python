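"""Viewing geometry: converting between cycles/pixel and cycles/degree.

Spatial frequency on a display is physically defined in cycles per pixel
(cpp), but visual neuroscience works in cycles per degree of visual angle
(cyc/deg).  The conversion factor is the display's pixels-per-degree, which
depends on monitor size, resolution and viewing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandGeometry",
    "pixels_per_degree",
    "DEFAULT_PIXELS_PER_DEGREE",
]


def pixels_per_degree(
    diagonal_inches: float = 27.0,
    resolution: tuple[int, int] = (2560, 1440),
    distance_cm: float = 64.0,
) -> float:
    """Pixels per degree of visual angle for a flat display.

    Defaults describe a 27-inch 16:9 monitor at 2560x1440 viewed from
    64 cm, which works out to ~47.8 px/deg.  The small-angle approximation
    is evaluated at the display centre (1 deg subtends ``d*tan(1deg)``).
    """
    w_px, h_px = resolution
    aspect = w_px / h_px
    diag_cm = diagonal_inches * 2.54
    width_cm = diag_cm * aspect / math.hypot(aspect, 1.0)
    px_per_cm = w_px / width_cm
    cm_per_deg = distance_cm * math.tan(math.radians(1.0))
    return px_per_cm * cm_per_deg


DEFAULT_PIXELS_PER_DEGREE = pixels_per_degree()


@dataclass(frozen=True)
class BandGeometry:
    """Spatial-frequency geometry of a pyramid decomposition.

    Parameters
    ----------
    pixels_per_degree : float
        Display resolution in pixels per degree of visual angle.
    n_scales : int
        Number of bandpass scales.  Scale ``s`` (1-based) is centred at
        ``2**-(s+1)`` cycles/pixel, i.e. an octave spacing starting one
        octave below the Nyquist frequency (0.5 cpp).
    """

    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    n_scales: int = 5

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")

    @property
    def center_frequency_cpp(self) -> np.ndarray:
        """Band centre frequencies in cycles/pixel, strictly decreasing."""
        s = np.arange(1, self.n_scales + 1)
        return 2.0 ** -(s + 1.0)

    @property
    def center_frequency_cpd(self) -> np.ndarray:
        """Band centre frequencies in cycles/degree."""
        return self.center_frequency_cpp * self.pixels_per_degree

    def cpd_to_cpp(self, cpd: float) -> float:
        return cpd / self.pixels_per_degree

    def cpp_to_cpd(self, cpp: float) -> float:
        return cpp * self.pixels_per_degree
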