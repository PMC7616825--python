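"""Sparse functional principal component analysis via PACE.

Longitudinal exposures measured at a few irregular times per subject
are decomposed with the Karhunen-Loeve expansion

    X(t) = mu(t) + sum_k xi_k phi_k(t) + e(t)

where ``phi_k`` are orthonormal eigenfunctions of the exposure
covariance operator, ``lambda_k = var(xi_k)`` the eigenvalues, and
``e(t)`` a residual.  Because per-subject data are too sparse to
project curves directly, the pipeline is the PACE one:

1. pool all measurements and estimate the mean curve ``mu(t)`` by
   local-linear kernel smoothing;
2. smooth the off-diagonal raw covariances
   ``(x_ij - mu)(x_ik - mu)`` to a surface ``G(s, t)``, and read the
   measurement-noise variance off the gap between the smoothed
   diagonal of raw products and ``G(t, t)``;
3. eigen-decompose the covariance operator under trapezoid quadrature;
4. recover per-subject scores ``xi_ik`` by best linear prediction
   (conditional expectation under joint normality), which shrinks
   scores toward zero according to how informative each subject's
   measurements are.

The scores are the "pseudo-exposures" that downstream modules treat as
exposures in a multivariable Mendelian randomization model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import TimeGrid

__all__ = [
    "SparseLongitudinal",
    "FpcaModel",
    "BandwidthError",
    "estimate_mean",
    "estimate_cov",
    "eigen_decompose",
    "pace_scores",
    "select_K",
    "fit_fpca",
]


class BandwidthError(RuntimeError):
    """Raised when a kernel bandwidth leaves grid points without support."""


@dataclass
class SparseLongitudinal:
    """Long-format sparse longitudinal records (subject_id, time, value).

    Subjects may have any positive number of measurements at arbitrary
    times inside the domain ``[t_min, t_max]``; the domain defaults to
    the observed time range.
    """

    records: pd.DataFrame
    t_min: float | None = None
    t_max: float | None = None
    subjects: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        df = self.records
        required = {"subject_id", "time", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("no records")
        df = df.loc[:, ["subject_id", "time", "value"]].copy()
        if not np.all(np.isfinite(df["time"])) or not np.all(np.isfinite(df["value"])):
            raise ValueError("non-finite time or value entries")
        if self.t_min is None:
            self.t_min = float(df["time"].min())
        if self.t_max is None:
            self.t_max = float(df["time"].max())
        if np.any(df["time"] < self.t_min - 1e-9) or np.any(df["time"] > self.t_max + 1e-9):
            raise ValueError("times outside the stated domain")
        df = df.sort_values(["subject_id", "time"], kind="stable").reset_index(drop=True)
        self.records = df
        self.subjects = df["subject_id"].unique()

    @property
    def n_subjects(self) -> int:
        return self.subjects.size

    def by_count(self):
        """Group subjects by number of observations.

        Yields ``(m, ids, times, values)`` with ``times`` and ``values``
        of shape ``(n_group, m)`` — batching subjects with equal counts
        makes the per-subject linear algebra vectorisable.
        """
        counts = self.records.groupby("subject_id", sort=False).size()
        order = self.records["subject_id"].to_numpy()
        t = self.records["time"].to_numpy()
        v = self.records["value"].to_numpy()
        for m in np.unique(counts.to_numpy()):
            ids = counts.index[counts.to_numpy() == m].to_numpy()
            mask = np.isin(order, ids)
            yield (
                int(m),
                ids,
                t[mask].reshape(-1, m),
                v[mask].reshape(-1, m),
            )


@dataclass
class FpcaModel:
    """Fitted sparse FPCA decomposition."""

    grid: TimeGrid
    mu: np.ndarray  # (n_grid,)
    eigenfunctions: np.ndarray  # (K, n_grid)
    eigenvalues: np.ndarray  # (K,), strictly descending
    sigma2: float
    scores: np.ndarray  # (n, K), row order = data.subjects
    fve: np.ndarray  # cumulative FVE over the positive spectrum
    subjects: np.ndarray

    @property
    def K(self) -> int:
        return self.eigenfunctions.shape[0]


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    out = 0.75 * (1.0 - u**2)
    out[np.abs(u) >= 1.0] = 0.0
    return out


def estimate_mean(
    data: SparseLongitudinal, grid: TimeGrid, bandwidth: float
) -> np.ndarray:
    """Local-linear Epanechnikov smooth of all pooled (time, value) pairs."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    t = data.records["time"].to_numpy()
    y = data.records["value"].to_numpy()
    mu = np.empty(len(grid))
    for i, g in enumerate(grid.points):
        d = t - g
        w = _epanechnikov(d / bandwidth)
        s0 = w.sum()
        if s0 <= 0:
            raise BandwidthError(
                f"no data within bandwidth {bandwidth} of grid point t={g:.3g}; "
                "widen the bandwidth"
            )
        s1 = w @ d
        s2 = w @ d**2
        t0 = w @ y
        t1 = (w * d) @ y
        det = s0 * s2 - s1**2
        if det <= 1e-12 * max(s0 * s2, 1e-300):
            # degenerate design (e.g. all data at one time): local constant
            mu[i] = t0 / s0
        else:
            mu[i] = (s2 * t0 - s1 * t1) / det
    return mu


def _kernel_weights(radius: int, spacing: float, bandwidth: float, p: int) -> np.ndarray:
    d = np.arange(-radius, radius + 1) * spacing
    return _epanechnikov(d / bandwidth) * d**p


def _binned_pairs(data: SparseLongitudinal, mu: np.ndarray, grid: TimeGrid):
    """Accumulate off-diagonal raw covariances and diagonal raw variances
    into bins located at the grid points (uniform grid assumed)."""
    n_grid = len(grid)
    spacing = grid.points[1] - grid.points[0]
    count = np.zeros((n_grid, n_grid))
    total = np.zeros((n_grid, n_grid))
    diag_count = np.zeros(n_grid)
    diag_total = np.zeros(n_grid)
    any_pairs = False
    for m, _ids, times, values in data.by_count():
        resid = values - np.interp(times, grid.points, mu)
        idx = np.clip(np.rint((times - grid.t_min) / spacing).astype(int), 0, n_grid - 1)
        np.add.at(diag_count, idx.ravel(), 1.0)
        np.add.at(diag_total, idx.ravel(), (resid**2).ravel())
        if m < 2:
            continue
        any_pairs = True
        prod = resid[:, :, None] * resid[:, None, :]
        ii = np.broadcast_to(idx[:, :, None], prod.shape)
        jj = np.broadcast_to(idx[:, None, :], prod.shape)
        off = ~np.eye(m, dtype=bool)
        off = np.broadcast_to(off, prod.shape)
        flat = ii[off] * n_grid + jj[off]
        np.add.at(count.ravel(), flat, 1.0)
        np.add.at(total.ravel(), flat, prod[off])
    if not any_pairs:
        raise ValueError("covariance needs at least one subject with >= 2 observations")
    return count, total, diag_count, diag_total


def _local_linear_2d(
    count: np.ndarray, total: np.ndarray, spacing: float, bandwidth: float
) -> np.ndarray:
    """Binned 2-D local-linear smooth on a uniform grid.

    With a product Epanechnikov kernel every weighted-least-squares
    moment is a separable convolution of the binned counts/sums, so the
    full surface costs a handful of 1-D correlations.
    """
    radius = int(np.ceil(bandwidth / spacing)) - 1
    if radius < 1:
        radius = 1
    k = {p: _kernel_weights(radius, spacing, bandwidth, p) for p in (0, 1, 2)}

    def corr2(arr: np.ndarray, p: int, q: int) -> np.ndarray:
        out = ndimage.correlate1d(arr, k[p], axis=0, mode="constant", cval=0.0)
        return ndimage.correlate1d(out, k[q], axis=1, mode="constant", cval=0.0)

    # local model 1 + ds + dt + ds*dt: the bilinear term removes the
    # corner bias a plain local plane suffers on product-form surfaces
    basis = [(0, 0), (1, 0), (0, 1), (1, 1)]
    M = {
        (p, q): corr2(count, p, q)
        for p in (0, 1, 2)
        for q in (0, 1, 2)
    }
    R = {pq: corr2(total, *pq) for pq in basis}
    if np.any(M[(0, 0)] <= 0):
        raise BandwidthError("covariance bandwidth leaves grid cells without support")
    N = np.stack(
        [
            np.stack([M[(p + a, q + b)] for (a, b) in basis], axis=-1)
            for (p, q) in basis
        ],
        axis=-2,
    )
    rhs = np.stack([R[pq] for pq in basis], axis=-1)
    det = np.linalg.det(N)
    good = np.abs(det) > 1e-12 * np.maximum(M[(0, 0)], 1e-300) ** 4
    smooth = np.empty_like(count)
    if np.any(good):
        sol = np.linalg.solve(N[good], rhs[good][..., None])[..., 0, 0]
        smooth[good] = sol
    smooth[~good] = (R[(0, 0)] / M[(0, 0)])[~good]
    return smooth


def _local_linear_1d(
    count: np.ndarray, total: np.ndarray, spacing: float, bandwidth: float
) -> np.ndarray:
    radius = max(int(np.ceil(bandwidth / spacing)) - 1, 1)
    k = {p: _kernel_weights(radius, spacing, bandwidth, p) for p in (0, 1, 2)}

    def corr(arr, p):
        return ndimage.correlate1d(arr, k[p], mode="constant", cval=0.0)

    s0, s1, s2 = corr(count, 0), corr(count, 1), corr(count, 2)
    t0, t1 = corr(total, 0), corr(total, 1)
    if np.any(s0 <= 0):
        raise BandwidthError("bandwidth leaves grid points without support")
    det = s0 * s2 - s1**2
    good = det > 1e-10 * np.maximum(s0 * s2, 1e-300)
    out = np.where(good, (s2 * t0 - s1 * t1) / np.where(good, det, 1.0), t0 / s0)
    return out


def estimate_cov(
    data: SparseLongitudinal,
    mu: np.ndarray,
    grid: TimeGrid,
    bandwidth: float,
) -> tuple[np.ndarray, float]:
    """Smooth raw cross-products to a covariance surface; estimate noise.

    Off-diagonal raw products from subjects with at least two
    observations are binned onto the grid and smoothed with a binned
    local-linear product-kernel smoother.  The measurement-noise
    variance ``sigma2`` is the average, over the central half of the
    domain, of the gap between the smoothed diagonal of raw products
    (which include the s = t nugget) and the surface diagonal, floored
    at zero.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    spacing = np.diff(grid.points)
    if np.ptp(spacing) > 1e-9 * spacing[0]:
        raise ValueError("covariance smoothing requires a uniform grid")
    spacing = float(spacing[0])
    count, total, diag_count, diag_total = _binned_pairs(data, mu, grid)
    surface = _local_linear_2d(count, total, spacing, bandwidth)
    surface = 0.5 * (surface + surface.T)
    diag_smooth = _local_linear_1d(diag_count, diag_total, spacing, bandwidth)
    lo, hi = grid.t_min + 0.25 * grid.span, grid.t_min + 0.75 * grid.span
    central = (grid.points >= lo) & (grid.points <= hi)
    sigma2 = float(np.mean(diag_smooth[central] - np.diag(surface)[central]))
    return surface, max(sigma2, 0.0)


def eigen_decompose(
    cov: np.ndarray, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the covariance operator under trapezoid quadrature.

    Solves the symmetrised weighted eigenproblem, drops non-positive
    eigenvalues, normalises eigenfunctions to unit quadrature norm and
    fixes their sign so that ``∫ phi_k(t) t dt >= 0`` (ties broken by
    ``∫ phi_k dt >= 0``).  Returned in strictly descending order.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariance surface contains non-finite entries")
    sw = np.sqrt(grid.weights)
    A = sw[:, None] * cov * sw[None, :]
    A = 0.5 * (A + A.T)
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > max(1e-12, 1e-12 * abs(vals[0]))
    vals, vecs = vals[keep], vecs[:, keep]
    phi = (vecs / sw[:, None]).T  # (K, n_grid), ∫ phi^2 dt = 1 by construction
    for k in range(phi.shape[0]):
        s = grid.inner(phi[k], grid.points)
        if abs(s) < 1e-8:
            s = grid.integrate(phi[k])
        if s < 0:
            phi[k] = -phi[k]
    return vals, phi


def select_K(eigenvalues: Sequence[float], threshold: float) -> int:
    """Smallest K whose cumulative eigenvalue fraction reaches the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("empty spectrum")
    frac = np.cumsum(lam) / lam.sum()
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def pace_scores(
    data: SparseLongitudinal,
    grid: TimeGrid,
    mu: np.ndarray,
    eigenfunctions: np.ndarray,
    eigenvalues: np.ndarray,
    sigma2: float,
) -> np.ndarray:
    """Best-linear-prediction (conditional expectation) PC scores.

    For subject i with observation times t_i and values x_i,

        xi_i = Lambda Phi_i' (Phi_i Lambda Phi_i' + sigma2 I)^{-1} (x_i - mu_i)

    where Phi_i holds the eigenfunctions linearly interpolated to t_i.
    Under joint normality this is E(xi_i | data), so scores are shrunk
    toward zero relative to direct projections.
    """
    K = eigenfunctions.shape[0]
    lam = np.asarray(eigenvalues, dtype=float)
    ridge = 0.0
    if sigma2 < 1e-10 * max(lam[0], 1.0):
        ridge = 1e-10 * max(lam[0], 1.0)
    out = np.empty((data.n_subjects, K))
    pos = {sid: i for i, sid in enumerate(data.subjects)}
    warned = False
    for m, ids, times, values in data.by_count():
        resid = values - np.interp(times, grid.points, mu)
        Phi = np.stack(
            [np.interp(times, grid.points, eigenfunctions[k]) for k in range(K)],
            axis=-1,
        )  # (ns, m, K)
        Sigma = np.einsum("smk,k,snk->smn", Phi, lam, Phi)
        Sigma[:, np.arange(m), np.arange(m)] += sigma2 + ridge
        try:
            sol = np.linalg.solve(Sigma, resid[:, :, None])[..., 0]
        except np.linalg.LinAlgError:
            if not warned:
                warnings.warn(
                    "singular within-subject covariance; ridge-stabilised solve",
                    RuntimeWarning,
                )
                warned = True
            Sigma[:, np.arange(m), np.arange(m)] += 1e-8 * max(lam[0], 1.0)
            sol = np.linalg.solve(Sigma, resid[:, :, None])[..., 0]
        xi = np.einsum("k,smk,sm->sk", lam, Phi, sol)
        rows = [pos[sid] for sid in ids]
        out[rows] = xi
    return out


def fit_fpca(
    data: SparseLongitudinal,
    grid_size: int = 101,
    fve_threshold: float = 0.95,
    K: int | None = None,
    mean_bandwidth: float | None = None,
    cov_bandwidth: float | None = None,
) -> FpcaModel:
    """Full PACE pipeline: mean, covariance, spectrum, scores.

    Bandwidths default to 10% (mean) and 15% (covariance surface) of
    the domain width.  The number of retained components is the
    smallest K explaining ``fve_threshold`` of the positive spectrum
    unless fixed explicitly.
    """
    grid = TimeGrid.uniform(data.t_max, grid_size, t_min=data.t_min)
    span = grid.span
    mean_bandwidth = 0.10 * span if mean_bandwidth is None else mean_bandwidth
    cov_bandwidth = 0.15 * span if cov_bandwidth is None else cov_bandwidth
    mu = estimate_mean(data, grid, mean_bandwidth)
    surface, sigma2 = estimate_cov(data, mu, grid, cov_bandwidth)
    lam_all, phi_all = eigen_decompose(surface, grid)
    fve = np.cumsum(lam_all) / lam_all.sum()
    k = select_K(lam_all, fve_threshold) if K is None else int(K)
    k = min(k, lam_all.size)
    lam, phi = lam_all[:k], phi_all[:k]
    scores = pace_scores(data, grid, mu, phi, lam, sigma2)
    return FpcaModel(
        grid=grid,
        mu=mu,
        eigenfunctions=phi,
        eigenvalues=lam,
        sigma2=sigma2,
        scores=scores,
        fve=fve,
        subjects=data.subjects,
    )
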