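"""Rectangular scan-grid geometry shared by all pipeline stages.

The indentation matrix is a cell-centred rectangular grid in the lateral
X-Y plane: point (i, j) sits at ``(x0 + i * pitch, y0 + j * pitch)`` with
``i`` running along X and ``j`` along Y.  The covered area extends half a
pitch beyond the outermost points, so an area of W x H mm scanned at pitch
``p`` holds ``round(W / p) * round(H / p)`` points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry"]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a cell-centred rectangular indentation grid.

    Parameters
    ----------
    pitch
        Spacing between adjacent points, mm.
    n_x, n_y
        Number of points along X and Y.
    x0, y0
        Position of point (0, 0) in mm.  Defaults to ``pitch / 2`` so the
        covered area has its corner at the origin.
    """

    pitch: float
    n_x: int
    n_y: int
    x0: float = None  # type: ignore[assignment]
    y0: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError(f"grid must hold at least one point, got {self.n_x} x {self.n_y}")
        if self.x0 is None:
            object.__setattr__(self, "x0", self.pitch / 2.0)
        if self.y0 is None:
            object.__setattr__(self, "y0", self.pitch / 2.0)

    @classmethod
    def from_extent(cls, width_x: float, width_y: float, pitch: float,
                    x_corner: float = 0.0, y_corner: float = 0.0) -> "GridGeometry":
        """Grid covering a ``width_x`` x ``width_y`` mm area at ``pitch`` mm."""
        n_x = int(round(width_x / pitch))
        n_y = int(round(width_y / pitch))
        return cls(pitch=pitch, n_x=n_x, n_y=n_y,
                   x0=x_corner + pitch / 2.0, y0=y_corner + pitch / 2.0)

    @property
    def n_points(self) -> int:
        return self.n_x * self.n_y

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.pitch * np.arange(self.n_x)

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.pitch * np.arange(self.n_y)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the covered area in mm."""
        h = self.pitch / 2.0
        return (self.x0 - h, self.x0 + (self.n_x - 1) * self.pitch + h,
                self.y0 - h, self.y0 + (self.n_y - 1) * self.pitch + h)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """X and Y coordinate arrays of shape (n_y, n_x), mm."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def oversampled(self, factor: int) -> "GridGeometry":
        """Geometry of the sub-pixel grid that splits each cell ``factor``-fold.

        The covered area is unchanged; each native cell maps onto a
        ``factor x factor`` block of sub-pixels.
        """
        if factor < 1:
            raise ValueError(f"oversample factor must be >= 1, got {factor}")
        sub = self.pitch / factor
        return GridGeometry(
            pitch=sub,
            n_x=self.n_x * factor,
            n_y=self.n_y * factor,
            x0=self.x0 - self.pitch / 2.0 + sub / 2.0,
            y0=self.y0 - self.pitch / 2.0 + sub / 2.0,
        )

    def matches(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        """True when two geometries describe the same set of points."""
        return (self.n_x == other.n_x and self.n_y == other.n_y
                and abs(self.pitch - other.pitch) <= tol
                and abs(self.x0 - other.x0) <= tol
                and abs(self.y0 - other.y0) <= tol)
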