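"""Observation windows for TMA cores.

A tissue-microarray core is a circular punch (0.6 mm diameter in this design,
so a 300 um radius); rectangular windows are supported for cropped exports.
All spatial statistics need two things from the window: membership and the
distance from a point to the boundary, which is the censoring distance of the
Kaplan-Meier edge correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default core radius in microns (0.6 mm-diameter TMA punch).
DEFAULT_CORE_RADIUS_UM: float = 300.0


@dataclass(frozen=True)
class CircularWindow:
    """Circular observation window (center ``cx, cy`` and ``radius``, microns)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not (self.radius > 0 and np.isfinite(self.radius)):
            raise ValueError("window radius must be positive and finite")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def contains(self, x: np.ndarray, y: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        r = np.hypot(np.asarray(x) - self.cx, np.asarray(y) - self.cy)
        return r <= self.radius + atol

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance from interior points to the circle boundary (clipped at 0)."""
        r = np.hypot(np.asarray(x) - self.cx, np.asarray(y) - self.cy)
        return np.maximum(self.radius - r, 0.0)


@dataclass(frozen=True)
class RectWindow:
    """Axis-aligned rectangular window with extents in microns."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("rectangle extents must be increasing")

    @property
    def area(self) -> float:
        return float((self.xmax - self.xmin) * (self.ymax - self.ymin))

    def contains(self, x: np.ndarray, y: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.xmin - atol)
            & (x <= self.xmax + atol)
            & (y >= self.ymin - atol)
            & (y <= self.ymax + atol)
        )

    def boundary_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        d = np.minimum.reduce(
            [x - self.xmin, self.xmax - x, y - self.ymin, self.ymax - y]
        )
        return np.maximum(d, 0.0)


Window = CircularWindow | RectWindow


def infer_window(
    x: np.ndarray, y: np.ndarray, radius: float = DEFAULT_CORE_RADIUS_UM
) -> CircularWindow:
    """Infer a circular core window from cell coordinates.

    The circle is centered at the coordinate centroid with the default core
    radius, expanded (with a 1% margin) if any cell falls outside.  Used when
    a cell table carries no explicit window geometry.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        return CircularWindow(0.0, 0.0, radius)
    cx, cy = float(x.mean()), float(y.mean())
    rmax = float(np.hypot(x - cx, y - cy).max())
    return CircularWindow(cx, cy, max(radius, rmax * 1.01))
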