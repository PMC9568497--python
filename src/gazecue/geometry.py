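"""Screen geometry and pixel/degree coordinate conversion.

Degrees are measured from the screen center with +x rightward and +y upward.
Pixels use the standard image convention: origin at the top-left corner with
+y downward. The conversion is a linear (small-angle) mapping; no tangent
correction is applied, because stimulus sizes are specified as flat visual
angles and the error over an ~18 degree display is negligible for this
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["ScreenGeometry", "convert_point", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display extent in visual angle and pixels plus viewing distance.

    Parameters
    ----------
    width_deg, height_deg : float
        Stimulus extent in degrees of visual angle (default 18.4 x 13.8).
    viewing_distance_cm : float
        Eye-to-screen distance in centimetres (default 75).
    width_px, height_px : int
        Pixel raster of the display. The angular extent is the quantity that
        matters for the analysis; the raster only anchors pixel-unit inputs
        and the synthetic annotation module. The default raster is chosen so
        the horizontal and vertical pixels-per-degree coincide.
    """

    width_deg: float = 18.4
    height_deg: float = 13.8
    viewing_distance_cm: float = 75.0
    width_px: int = 1280
    height_px: int = 960

    def __post_init__(self) -> None:
        for name in ("width_deg", "height_deg", "viewing_distance_cm",
                     "width_px", "height_px"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(
                    f"ScreenGeometry.{name} must be finite and > 0, got {value!r}")

    @property
    def ppd_x(self) -> float:
        """Horizontal pixels per degree."""
        return self.width_px / self.width_deg

    @property
    def ppd_y(self) -> float:
        """Vertical pixels per degree."""
        return self.height_px / self.height_deg

    def px_to_deg(self, x_px, y_px):
        """Map pixel coordinates (origin top-left, +y down) to centered degrees."""
        x_deg = (np.asarray(x_px, dtype=float) - self.width_px / 2.0) / self.ppd_x
        y_deg = (self.height_px / 2.0 - np.asarray(y_px, dtype=float)) / self.ppd_y
        return x_deg, y_deg

    def deg_to_px(self, x_deg, y_deg):
        """Inverse of :meth:`px_to_deg`."""
        x_px = np.asarray(x_deg, dtype=float) * self.ppd_x + self.width_px / 2.0
        y_px = self.height_px / 2.0 - np.asarray(y_deg, dtype=float) * self.ppd_y
        return x_px, y_px


DEFAULT_GEOMETRY = ScreenGeometry()


def convert_point(p, geometry: ScreenGeometry, direction: str):
    """Convert a single (x, y) point between pixel and degree coordinates.

    Parameters
    ----------
    p : tuple of float
        The point ``(x, y)`` in the source units.
    geometry : ScreenGeometry
    direction : {"px_to_deg", "deg_to_px"}

    Returns
    -------
    tuple of float
    """
    x, y = float(p[0]), float(p[1])
    if direction == "px_to_deg":
        out = geometry.px_to_deg(x, y)
    elif direction == "deg_to_px":
        out = geometry.deg_to_px(x, y)
    else:
        raise ConfigurationError(
            f"direction must be 'px_to_deg' or 'deg_to_px', got {direction!r}")
    return float(out[0]), float(out[1])
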