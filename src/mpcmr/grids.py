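"""Time grids with trapezoid quadrature.

Every curve in this package (mean function, eigenfunctions, effect
function, basis functions) lives on a :class:`TimeGrid`, and every
integral over the time domain is a trapezoid-rule quadrature on that
grid.  Keeping the quadrature rule in one place makes the curve algebra
(inner products, transform matrices, effect reconstruction) exactly
consistent across modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing time points covering ``[t0, T]``.

    Attributes
    ----------
    points:
        1-D array of strictly increasing times.
    weights:
        Trapezoid quadrature weights; positive, summing to ``T - t0``.
    """

    points: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)
        d = np.diff(pts)
        w = np.zeros_like(pts)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, t_max: float, n_points: int, t_min: float = 0.0) -> "TimeGrid":
        return cls(np.linspace(t_min, t_max, n_points))

    @property
    def t_min(self) -> float:
        return float(self.points[0])

    @property
    def t_max(self) -> float:
        return float(self.points[-1])

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    def __len__(self) -> int:
        return self.points.size

    def integrate(self, values: np.ndarray) -> np.ndarray:
        """Trapezoid integral over the grid (last axis of ``values``)."""
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != len(self):
            raise ValueError("values do not match grid length")
        return values @ self.weights

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        """Quadrature inner product ``∫ f(t) g(t) dt``."""
        return float(self.integrate(np.asarray(f) * np.asarray(g)))
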