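"""Basis functions for the effect curve and the score-transform algebra.

The effect function is modelled as beta(t) = sum_l gamma_l b_l(t) for a
chosen basis {b_l}.  Substituting this into the pseudo-exposure model
turns the K principal-component scores xi into L transformed exposures

    xi* = B' xi,   B_kl = ∫ phi_k(t) b_l(t) dt,

so the same instrumental-variable fit applies with the transformed
scores, and the fitted gamma maps back to a curve via b(t).  When the
basis is the eigenfunctions themselves, B is the identity and the
transform is a no-op.

Polynomial bases are evaluated in the rescaled time u = (t - t0) / T to
keep the design well conditioned on domains reaching t = 50 and beyond;
all reported curves are still functions of the original t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import TimeGrid
from .fpca import FpcaModel

__all__ = ["BasisSet", "make_basis", "transform_matrix", "transform_scores"]


@dataclass(frozen=True)
class BasisSet:
    """L basis curves evaluated on a grid."""

    kind: str  # "eigenfunction" | "polynomial" | "custom"
    grid: TimeGrid
    curves: np.ndarray  # (L, n_grid)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if c.shape[1] != len(self.grid):
            raise ValueError("basis curves do not match the grid")
        if not np.all(np.isfinite(c)):
            raise ValueError("basis curves must be finite")
        object.__setattr__(self, "curves", c)

    @property
    def L(self) -> int:
        return self.curves.shape[0]

    def evaluate(self, t) -> np.ndarray:
        """Interpolate all basis curves at arbitrary times ``t`` -> (L, len(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack(
            [np.interp(t, self.grid.points, c) for c in self.curves], axis=0
        )


def make_basis(
    kind: str,
    grid: TimeGrid | None = None,
    degree: int | None = None,
    model: FpcaModel | None = None,
    curves: np.ndarray | None = None,
) -> BasisSet:
    """Construct a basis set.

    ``polynomial`` gives b_l(t) = u^(l-1), l = 1..degree+1, in rescaled
    time u = (t - t0)/T; ``eigenfunction`` reuses the fitted FPCA
    eigenfunctions; ``custom`` takes explicit curves.
    """
    if kind == "polynomial":
        if degree is None or degree < 0:
            raise ValueError("polynomial basis needs degree >= 0")
        if grid is None:
            raise ValueError("polynomial basis needs a grid")
        u = (grid.points - grid.t_min) / grid.span
        curves = np.stack([u**p for p in range(degree + 1)], axis=0)
        return BasisSet(kind="polynomial", grid=grid, curves=curves)
    if kind == "eigenfunction":
        if model is None:
            raise ValueError("eigenfunction basis needs a fitted FpcaModel")
        return BasisSet(
            kind="eigenfunction", grid=model.grid, curves=model.eigenfunctions.copy()
        )
    if kind == "custom":
        if grid is None or curves is None:
            raise ValueError("custom basis needs a grid and curves")
        return BasisSet(kind="custom", grid=grid, curves=np.asarray(curves, float))
    raise ValueError(f"unknown basis kind {kind!r}")


def transform_matrix(
    eigenfunctions: np.ndarray, basis: BasisSet, grid: TimeGrid
) -> np.ndarray:
    """B_kl = ∫ phi_k(t) b_l(t) dt under trapezoid quadrature."""
    phi = np.atleast_2d(np.asarray(eigenfunctions, dtype=float))
    if phi.shape[1] != len(grid):
        raise ValueError("eigenfunctions do not match the grid")
    if basis.curves.shape[1] != len(grid) or not np.allclose(
        basis.grid.points, grid.points
    ):
        raise ValueError("basis and eigenfunctions must share a grid")
    return (phi * grid.weights[None, :]) @ basis.curves.T  # (K, L)


def transform_scores(xi: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Transformed pseudo-exposures xi*_i = B' xi_i, one L-vector per subject."""
    xi = np.asarray(xi, dtype=float)
    B = np.asarray(B, dtype=float)
    if xi.ndim != 2 or xi.shape[1] != B.shape[0]:
        raise ValueError("score and transform-matrix dimensions do not conform")
    return xi @ B
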