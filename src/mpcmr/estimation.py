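"""Instrumental-variable estimation of the effect-curve coefficients.

The pseudo-exposure model is a multivariable MR regression of the
outcome on L (transformed) principal-component scores, instrumented by
J genetic variants.  The estimator is the continuously-updating GMM
(CUE) with moment function g(beta) = E_n[Z (y - E beta)] and the
homoskedastic weighting Omega(beta) = E_n[Z Z'] E_n[(y - E beta)^2].
Because the weighting factorises into a fixed matrix times a scalar
residual variance, the CUE objective is a ratio of quadratic forms and
the minimiser is a k-class estimator: the implementation iterates

    beta <- [E'(P_Z - kappa I)E]^{-1} E'(P_Z - kappa I)y,
    kappa = objective(beta) / n

from the 2SLS start (kappa = 0) to convergence.  A naive association
fit (OLS of the outcome on the scores, no instruments) is provided as
the confounded benchmark.

Fitted coefficients map to an effect curve beta(t) = b(t)' gamma with
pointwise delta-method standard errors sqrt(b(t)' Sigma b(t)), and any
intervention contrast ∫ beta(t) a(t) dt is a linear functional of gamma
with the corresponding standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import TimeGrid
from .basis import BasisSet

__all__ = [
    "IvData",
    "GmmFit",
    "EffectCurve",
    "build_ivdata",
    "cue_gmm",
    "association_fit",
    "reconstruct_effect",
    "intervention_effect",
]


@dataclass(frozen=True)
class IvData:
    """Centered instrument, pseudo-exposure and outcome blocks."""

    Z: np.ndarray  # (n, J)
    E: np.ndarray  # (n, L)
    y: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        Z, E, y = (np.asarray(a, dtype=float) for a in (self.Z, self.E, self.y))
        E = E[:, None] if E.ndim == 1 else E
        if Z.shape[0] != E.shape[0] or Z.shape[0] != y.shape[0]:
            raise ValueError("row counts of Z, E, y differ")
        if Z.shape[1] < E.shape[1]:
            raise ValueError(
                f"under-identified: {Z.shape[1]} instruments for {E.shape[1]} exposures"
            )
        for name, a in (("Z", Z), ("E", E)):
            if np.any(np.abs(a.mean(axis=0)) > 1e-8 * (1 + np.abs(a).max())):
                raise ValueError(f"{name} is not mean-centered")
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def J(self) -> int:
        return self.Z.shape[1]

    @property
    def L(self) -> int:
        return self.E.shape[1]


@dataclass
class GmmFit:
    """Point estimate, covariance and GMM pieces of one fit."""

    beta_star: np.ndarray  # (L,)
    Sigma: np.ndarray  # (L, L), on the estimate scale (already / n)
    G_hat: np.ndarray | None  # (J, L) Jacobian E_n[-Z E']
    Omega_at_fit: np.ndarray | None  # (J, J)
    objective_value: float
    method: str  # "cue_gmm" | "association"
    converged: bool = True
    n: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.Sigma))


@dataclass(frozen=True)
class EffectCurve:
    """Fitted effect function with pointwise Wald bounds."""

    grid: TimeGrid
    beta_t: np.ndarray
    se_t: np.ndarray
    wald_lo: np.ndarray
    wald_hi: np.ndarray
    basis: BasisSet
    fit: GmmFit = field(repr=False, default=None)


def build_ivdata(
    Z_raw: np.ndarray,
    exposures: np.ndarray,
    y_raw: np.ndarray,
    subject_ids: Sequence | None = None,
) -> IvData:
    """Center all blocks; drop zero-variance instruments.

    If ``subject_ids`` is given, rows of every block are assumed to be
    aligned to it already; rows with non-finite entries in any block
    are dropped with a warning.
    """
    Z = np.asarray(Z_raw, dtype=float)
    E = np.asarray(exposures, dtype=float)
    E = E[:, None] if E.ndim == 1 else E
    y = np.asarray(y_raw, dtype=float)
    ok = np.isfinite(Z).all(axis=1) & np.isfinite(E).all(axis=1) & np.isfinite(y)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} rows with missing blocks")
        Z, E, y = Z[ok], E[ok], y[ok]
    keep = Z.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance instrument columns")
        Z = Z[:, keep]
    return IvData(
        Z=Z - Z.mean(axis=0), E=E - E.mean(axis=0), y=y - y.mean()
    )


def _cue_pieces(data: IvData):
    Z, E, y, n = data.Z, data.E, data.y, data.n
    M = Z.T @ Z / n
    Minv = np.linalg.inv(M)
    Szy = Z.T @ y / n
    SzE = Z.T @ E / n
    return M, Minv, Szy, SzE


def _cue_objective(data: IvData, beta: np.ndarray, Minv, Szy, SzE) -> float:
    g = Szy - SzE @ beta
    quad = float(g @ Minv @ g)
    resid = data.y - data.E @ beta
    s2 = float(resid @ resid) / data.n
    if s2 <= 0:
        # exact fit: zero residual implies zero moments, objective 0
        return 0.0 if quad < 1e-20 else np.inf
    return float(data.n * quad / s2)


def cue_gmm(
    data: IvData, tol: float = 1e-10, max_iter: int = 200
) -> GmmFit:
    """Continuously-updating GMM fit of the pseudo-exposure model."""
    n, J, L = data.n, data.J, data.L
    M, Minv, Szy, SzE = _cue_pieces(data)
    # P_Z cross-moments, all (L, L)/(L,)/scalar
    EPzE = n * SzE.T @ Minv @ SzE
    EPzy = n * SzE.T @ Minv @ Szy
    EtE = data.E.T @ data.E
    Ety = data.E.T @ data.y
    try:
        beta = np.linalg.solve(EPzE, EPzy)  # 2SLS start
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "singular first-stage moment matrix: instruments are too weak to "
            "point-identify; use the identification-robust LM region instead"
        ) from exc
    converged = False
    obj = _cue_objective(data, beta, Minv, Szy, SzE)
    for _ in range(max_iter):
        kappa = obj / n
        lhs = EPzE - kappa * EtE
        rhs = EPzy - kappa * Ety
        try:
            beta_new = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            break
        obj_new = _cue_objective(data, beta_new, Minv, Szy, SzE)
        step = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta)))
        beta, obj = beta_new, obj_new
        if step < tol:
            converged = True
            break
    if not converged:
        warnings.warn("CUE iteration did not converge; returning best iterate")
    resid = data.y - data.E @ beta
    s2 = float(resid @ resid) / n
    G_hat = -SzE
    if s2 <= 1e-24 * float(data.y @ data.y) / n:
        # numerically exact fit: no sampling variability to report
        return GmmFit(
            beta_star=beta,
            Sigma=np.zeros((L, L)),
            G_hat=G_hat,
            Omega_at_fit=np.zeros((J, J)),
            objective_value=0.0,
            method="cue_gmm",
            converged=True,
            n=n,
        )
    Omega = M * s2
    bread = G_hat.T @ np.linalg.solve(Omega, G_hat)
    try:
        Sigma = np.linalg.inv(bread) / n
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "weakly identified fit: G' Omega^{-1} G is singular; "
            "use the identification-robust LM region instead"
        ) from exc
    return GmmFit(
        beta_star=beta,
        Sigma=Sigma,
        G_hat=G_hat,
        Omega_at_fit=Omega,
        objective_value=obj,
        method="cue_gmm",
        converged=converged,
        n=n,
    )


def association_fit(scores: np.ndarray, y: np.ndarray) -> GmmFit:
    """Naive OLS of the outcome on the (centered) scores, no instruments.

    This is the confounded benchmark: when the trajectory shares
    confounders with the outcome the coefficients are biased.
    """
    import statsmodels.api as sm

    E = np.asarray(scores, dtype=float)
    E = E[:, None] if E.ndim == 1 else E
    E = E - E.mean(axis=0)
    y = np.asarray(y, dtype=float)
    y = y - y.mean()
    if E.shape[0] <= E.shape[1]:
        raise ValueError("need more subjects than exposures")
    res = sm.OLS(y, E).fit()
    if res.df_resid <= 0 or np.linalg.matrix_rank(E) < E.shape[1]:
        raise ValueError("rank-deficient design")
    return GmmFit(
        beta_star=np.asarray(res.params),
        Sigma=np.asarray(res.cov_params()),
        G_hat=None,
        Omega_at_fit=None,
        objective_value=float(res.ssr),
        method="association",
        n=E.shape[0],
    )


def reconstruct_effect(
    fit: GmmFit, basis: BasisSet, grid: TimeGrid | None = None, level: float = 0.95
) -> EffectCurve:
    """Map fitted coefficients to the effect curve with Wald bounds.

    beta(t) = b(t)' gamma, se(t) = sqrt(b(t)' Sigma b(t)).
    """
    from scipy import stats

    if basis.L != fit.beta_star.size:
        raise ValueError("basis dimension does not match the fit")
    grid = basis.grid if grid is None else grid
    b = basis.evaluate(grid.points)  # (L, n_grid)
    beta_t = b.T @ fit.beta_star
    var_t = np.einsum("lg,lm,mg->g", b, fit.Sigma, b)
    se_t = np.sqrt(np.maximum(var_t, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return EffectCurve(
        grid=grid,
        beta_t=beta_t,
        se_t=se_t,
        wald_lo=beta_t - z * se_t,
        wald_hi=beta_t + z * se_t,
        basis=basis,
        fit=fit,
    )


def intervention_effect(
    curve: EffectCurve, a: np.ndarray
) -> tuple[float, float]:
    """Expected outcome shift of a trajectory intervention a(t).

    Returns ``∫ beta(t) a(t) dt`` and its standard error via the linear
    functional w_l = ∫ b_l a dt of the fitted coefficients.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != curve.grid.points.shape:
        raise ValueError("intervention curve not on the effect-curve grid")
    effect = curve.grid.inner(curve.beta_t, a)
    b = curve.basis.evaluate(curve.grid.points)
    w = (b * curve.grid.weights[None, :]) @ a
    se = float(np.sqrt(max(w @ curve.fit.Sigma @ w, 0.0)))
    return float(effect), se
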