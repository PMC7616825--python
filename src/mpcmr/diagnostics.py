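"""Instrument strength and validity diagnostics.

Three checks accompany every multivariable MR fit on principal-component
pseudo-exposures:

* Sanderson-Windmeijer conditional F-statistics, one per pseudo-exposure
  — the strength of the instruments for that component once the other
  components' instrumented parts are accounted for;
* an over-identification statistic (the CUE objective at the fit,
  Hansen-J form) against chi-squared with J - L degrees of freedom;
* reconstructed time-varying genetic associations
  alpha_j(t) = sum_k [cov(Z_j, xi_k)/var(Z_j)] phi_k(t), the per-variant
  instrument-exposure curves implied by the FPCA expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimation import GmmFit, IvData
from .fpca import FpcaModel

__all__ = ["IvStrengthReport", "conditional_F", "overid_Q", "alpha_curves"]


@dataclass
class IvStrengthReport:
    conditional_F: np.ndarray  # (L,)
    overid_stat: float | None
    overid_df: int | None
    overid_p: float | None
    alpha_curves: np.ndarray | None  # (J, n_grid)


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef


def conditional_F(Z: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Sanderson-Windmeijer conditional F per pseudo-exposure.

    For exposure k: partial out of E_k the instrument-predicted parts of
    the other exposures (first-stage fitted values, i.e. 2SLS of E_k on
    E_{-k}), regress the residual on the instruments, and form the
    F-statistic with the Sanderson-Windmeijer numerator degrees of
    freedom J - L + 1.  With a single exposure this is the ordinary
    first-stage F.
    """
    Z = np.asarray(Z, dtype=float)
    E = np.asarray(E, dtype=float)
    E = E[:, None] if E.ndim == 1 else E
    n, J = Z.shape
    L = E.shape[1]
    if J <= L - 1:
        raise ValueError("need more instruments than conditioning exposures")
    if n <= J + L:
        raise ValueError("sample too small for the conditional F construction")
    Zc = Z - Z.mean(axis=0)
    Ec = E - E.mean(axis=0)
    out = np.empty(L)
    for k in range(L):
        target = Ec[:, k]
        if L > 1:
            others_hat = _ols_fit(Zc, np.delete(Ec, k, axis=1))
            target = target - _ols_fit(others_hat, target)
        total = float(target @ target)
        if total <= 1e-12 * float(Ec[:, k] @ Ec[:, k]):
            # no variation left once the other exposures' instrumented
            # parts are removed: conditionally irrelevant instruments
            out[k] = 0.0
            continue
        fitted = _ols_fit(Zc, target)
        ess = float(fitted @ fitted)
        rss = total - ess
        df_num = J - L + 1
        df_den = n - J - L  # intercept absorbed by centering + L-1 partialled
        out[k] = (ess / df_num) / (rss / df_den)
    return out


def overid_Q(data: IvData, fit: GmmFit) -> tuple[float | None, int | None, float | None]:
    """Over-identification (Hansen-J) test from the CUE objective.

    Returns ``(None, None, None)`` when J = L (just identified).
    """
    df = data.J - data.L
    if df <= 0:
        return None, None, None
    q = float(fit.objective_value)
    return q, df, float(stats.chi2.sf(q, df))


def per_variant_q(data: IvData, fit: GmmFit) -> np.ndarray:
    """Leave-one-out contribution of each instrument to the moment misfit.

    Plumbing for pleiotropy screening: the squared standardised moment
    per instrument at the fitted parameter.
    """
    resid = data.y - data.E @ fit.beta_star
    g = data.Z.T @ resid / data.n
    omega_diag = np.diag(data.Z.T @ data.Z / data.n) * float(resid @ resid) / data.n
    return data.n * g**2 / omega_diag


def alpha_curves(Z: np.ndarray, model: FpcaModel) -> np.ndarray:
    """Per-variant genetic association curves alpha_j(t) on the model grid."""
    Z = np.asarray(Z, dtype=float)
    var = Z.var(axis=0)
    ok = var > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance variants")
    Zc = Z[:, ok] - Z[:, ok].mean(axis=0)
    xi = model.scores - model.scores.mean(axis=0)
    coef = (Zc.T @ xi) / Zc.shape[0] / var[ok][:, None]  # (J_ok, K)
    curves = np.full((Z.shape[1], len(model.grid)), np.nan)
    curves[ok] = coef @ model.eigenfunctions
    return curves


def iv_strength_report(
    data: IvData, fit: GmmFit, model: FpcaModel | None = None
) -> IvStrengthReport:
    q, df, p = overid_Q(data, fit)
    return IvStrengthReport(
        conditional_F=conditional_F(data.Z, data.E),
        overid_stat=q,
        overid_df=df,
        overid_p=p,
        alpha_curves=alpha_curves(data.Z, model) if model is not None else None,
    )
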