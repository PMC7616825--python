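"""Synthetic cohort generator for time-varying Mendelian randomization.

Simulates the full data-generating process used throughout the test
suite: genetic variants act on a continuous exposure trajectory through
time-varying per-variant effect curves, the trajectory is confounded
with the outcome through shared Wiener-process and time-fixed
components, and the scalar outcome integrates the exposure against a
true effect function ``beta(t)`` over the study window ``[0, t_max]``.

The exposure model for subject ``i`` on the dense grid is

    X_i(t) = sum_j alpha_j(t) G_ij + U0_i + U_i(t) + eps_i(t)

with ``G_ij ~ Binomial(2, maf)`` i.i.d. dosages, ``U0 ~ N(0, 1)`` a
time-fixed confounder, and ``U`` and ``eps`` independent Wiener
processes scaled so their variance at ``t = t_max`` equals 1.  The
outcome is

    Y_i = ∫ beta(t) X_i(t) dt + 10 [U0_i + U_i(t_max)] + e_Y,i

with ``e_Y ~ N(0, 1)`` (an independent Wiener process evaluated at the
end of the window).  Only a sparse handful of exposure measurements per
subject is exposed to the analyst, mimicking cohort data where a
biomarker is measured at a few irregular ages.

Three instrument-exposure scenarios (A: sinusoidal genetic effect
curves, B and C: linear with different slope ranges) and six
exposure-outcome effect shapes (null, constant, increasing,
sign-change, early-age-only, late-age-only) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict

import numpy as np
import pandas as pd

from .grids import TimeGrid
from .fpca import SparseLongitudinal

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "AlphaFunctions",
    "DensePaths",
    "SimulatedDataset",
    "gen_genotypes",
    "gen_alpha",
    "gen_paths",
    "sparse_sample",
    "true_beta",
    "gen_outcome",
    "simulate",
    "genetic_r2_profile",
]

EXPOSURE_SCENARIOS = ("A", "B", "C")
OUTCOME_SCENARIOS = (1, 2, 3, 4, 5, 6)

# named substreams spawned from the master seed, so each component can
# be regenerated independently of the others
_STREAMS = ("genotypes", "coefficients", "paths", "sampling", "outcome")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated cohort."""

    n_subjects: int = 10_000
    n_variants: int = 30
    maf: float = 0.3
    exposure_scenario: str = "A"
    outcome_scenario: int = 3
    t_max: float = 50.0
    n_obs_per_subject: int = 10
    dense_grid_size: int = 501
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must lie strictly between 0 and 1")
        if self.exposure_scenario not in EXPOSURE_SCENARIOS:
            raise ValueError(f"unknown exposure scenario {self.exposure_scenario!r}")
        if self.outcome_scenario not in OUTCOME_SCENARIOS:
            raise ValueError(f"unknown outcome scenario {self.outcome_scenario!r}")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.n_obs_per_subject < 2:
            raise ValueError("n_obs_per_subject must be at least 2")
        if self.dense_grid_size < 50:
            raise ValueError("dense_grid_size must be at least 50")

    def grid(self) -> TimeGrid:
        return TimeGrid.uniform(self.t_max, self.dense_grid_size)

    def rngs(self) -> Dict[str, np.random.Generator]:
        """Independent substreams derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class GenotypeMatrix:
    """n x J dosage matrix with values in {0, 1, 2}."""

    dosages: np.ndarray
    variant_ids: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if d.shape[1] != len(self.variant_ids):
            raise ValueError("variant_ids do not match dosage columns")
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        object.__setattr__(self, "dosages", d)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class AlphaFunctions:
    """Per-variant genetic effect curves evaluated on the dense grid."""

    curves: np.ndarray  # (J, n_grid)
    scenario: str
    a: np.ndarray  # per-variant intercept-like parameter
    b: np.ndarray  # per-variant second parameter (offset or slope)


@dataclass(frozen=True)
class DensePaths:
    """Latent subject-level trajectories on the dense grid."""

    grid: TimeGrid
    exposure: np.ndarray  # (n, n_grid) X_i(t)
    confounder: np.ndarray  # (n, n_grid) U_i(t), Wiener
    confounder0: np.ndarray  # (n,) U0_i, time-fixed
    noise: np.ndarray  # (n, n_grid) eps_i(t), Wiener

    @property
    def n_subjects(self) -> int:
        return self.exposure.shape[0]


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything one simulation replicate produces."""

    config: SimConfig
    genotypes: GenotypeMatrix
    alpha: AlphaFunctions
    paths: DensePaths
    exposure: SparseLongitudinal
    outcome: np.ndarray
    beta_true: np.ndarray  # true beta(t) on the dense grid


def gen_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw i.i.d. Binomial(2, maf) dosages for every subject and variant."""
    rng = cfg.rngs()["genotypes"] if rng is None else rng
    d = rng.binomial(2, cfg.maf, size=(cfg.n_subjects, cfg.n_variants)).astype(float)
    ids = tuple(f"rs{j + 1}" for j in range(cfg.n_variants))
    return GenotypeMatrix(dosages=d, variant_ids=ids)


def gen_alpha(
    cfg: SimConfig, grid: TimeGrid, rng: np.random.Generator | None = None
) -> AlphaFunctions:
    """Draw per-variant effect curves ``alpha_j(t)`` for the scenario.

    Scenario A: ``alpha_j(t) = 0.05 sin(a_j t) + b_j`` with
    ``a_j, b_j ~ U(-0.1, 0.1)``.  Scenarios B and C are linear,
    ``alpha_j(t) = a_j + b_j t`` with ``a_j ~ U(-0.1, 0.1)`` and slope
    ranges ``U(-0.004, 0.004)`` (B) and ``U(-0.01, 0.01)`` (C).
    """
    rng = cfg.rngs()["coefficients"] if rng is None else rng
    J = cfg.n_variants
    t = grid.points
    a = rng.uniform(-0.1, 0.1, size=J)
    if cfg.exposure_scenario == "A":
        b = rng.uniform(-0.1, 0.1, size=J)
        curves = 0.05 * np.sin(a[:, None] * t[None, :]) + b[:, None]
    elif cfg.exposure_scenario == "B":
        b = rng.uniform(-0.004, 0.004, size=J)
        curves = a[:, None] + b[:, None] * t[None, :]
    else:  # "C"
        b = rng.uniform(-0.01, 0.01, size=J)
        curves = a[:, None] + b[:, None] * t[None, :]
    return AlphaFunctions(curves=curves, scenario=cfg.exposure_scenario, a=a, b=b)


def _wiener(
    rng: np.random.Generator, n: int, grid: TimeGrid, t_scale: float
) -> np.ndarray:
    """Wiener paths starting at 0 with Var(W(t_scale)) = 1."""
    dt = np.diff(grid.points) / t_scale
    inc = rng.normal(0.0, 1.0, size=(n, dt.size)) * np.sqrt(dt)[None, :]
    out = np.zeros((n, len(grid)))
    np.cumsum(inc, axis=1, out=out[:, 1:])
    return out


def gen_paths(
    cfg: SimConfig,
    G: GenotypeMatrix,
    alpha: AlphaFunctions,
    rng: np.random.Generator | None = None,
) -> DensePaths:
    """Assemble dense exposure trajectories from genetics plus noise."""
    grid = cfg.grid()
    if alpha.curves.shape[1] != len(grid):
        raise ValueError("alpha curves are not on the configured dense grid")
    if abs(grid.t_min) > 1e-12 or abs(grid.t_max - cfg.t_max) > 1e-12:
        raise ValueError("dense grid must cover [0, t_max]")
    rng = cfg.rngs()["paths"] if rng is None else rng
    n = G.n_subjects
    u0 = rng.normal(0.0, 1.0, size=n)
    u = _wiener(rng, n, grid, cfg.t_max)
    eps = _wiener(rng, n, grid, cfg.t_max)
    gene_score = G.dosages @ alpha.curves  # (n, n_grid)
    x = gene_score + u0[:, None] + u + eps
    return DensePaths(grid=grid, exposure=x, confounder=u, confounder0=u0, noise=eps)


def sparse_sample(
    paths: DensePaths, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SparseLongitudinal:
    """Expose a few measurement times per subject, chosen uniformly.

    Times are drawn without replacement from the dense grid, so the
    observed values are exact reads of the latent trajectory (any
    measurement error is part of the trajectory model itself).
    """
    if cfg.n_obs_per_subject > len(paths.grid):
        raise ValueError("more observations per subject than dense grid points")
    rng = cfg.rngs()["sampling"] if rng is None else rng
    n, m = paths.n_subjects, cfg.n_obs_per_subject
    n_grid = len(paths.grid)
    # vectorised without-replacement draw: argsort of uniforms per row
    keys = rng.random((n, n_grid))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    idx.sort(axis=1)
    times = paths.grid.points[idx]
    values = np.take_along_axis(paths.exposure, idx, axis=1)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), m),
            "time": times.ravel(),
            "value": values.ravel(),
        }
    )
    return SparseLongitudinal(df, t_min=0.0, t_max=cfg.t_max)


_BETA: Dict[int, Callable[[np.ndarray], np.ndarray]] = {
    1: lambda t: np.zeros_like(t),
    2: lambda t: np.full_like(t, 0.1),
    3: lambda t: 0.02 * t,
    4: lambda t: 0.5 - 0.02 * t,
    5: lambda t: 0.05 * (-t + 20.0) * (t < 20.0),
    6: lambda t: 0.05 * (t - 30.0) * (t > 30.0),
}


def true_beta(scenario: int, t, t_max: float = 50.0) -> np.ndarray:
    """True effect function ``beta(t)`` for outcome scenarios 1-6."""
    if scenario not in OUTCOME_SCENARIOS:
        raise ValueError(f"unknown outcome scenario {scenario!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > t_max):
        raise ValueError("t outside the [0, t_max] domain")
    return _BETA[scenario](t)


def gen_outcome(
    paths: DensePaths,
    scenario: int,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> np.ndarray:
    """Integrate the exposure against the true effect curve, add confounding."""
    t_max = paths.grid.t_max if t_max is None else t_max
    beta = true_beta(scenario, paths.grid.points, t_max=t_max)
    integral = paths.grid.integrate(paths.exposure * beta[None, :])
    eps_y = rng.normal(0.0, 1.0, size=paths.n_subjects)
    y = integral + 10.0 * (paths.confounder0 + paths.confounder[:, -1]) + eps_y
    return y


def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generative model for one replicate."""
    rngs = cfg.rngs()
    grid = cfg.grid()
    G = gen_genotypes(cfg, rngs["genotypes"])
    alpha = gen_alpha(cfg, grid, rngs["coefficients"])
    paths = gen_paths(cfg, G, alpha, rngs["paths"])
    sparse = sparse_sample(paths, cfg, rngs["sampling"])
    y = gen_outcome(paths, cfg.outcome_scenario, rngs["outcome"])
    beta = true_beta(cfg.outcome_scenario, grid.points, t_max=cfg.t_max)
    return SimulatedDataset(
        config=cfg,
        genotypes=G,
        alpha=alpha,
        paths=paths,
        exposure=sparse,
        outcome=y,
        beta_true=beta,
    )


def with_outcome(data: SimulatedDataset, scenario: int, seed: int) -> SimulatedDataset:
    """Re-draw the outcome under a different effect shape, reusing paths.

    Useful when several outcome models share one simulated exposure side.
    """
    rng = np.random.default_rng(seed)
    y = gen_outcome(data.paths, scenario, rng)
    cfg = replace(data.config, outcome_scenario=scenario)
    beta = true_beta(scenario, data.paths.grid.points, t_max=cfg.t_max)
    return replace(data, config=cfg, outcome=y, beta_true=beta)


def genetic_r2_profile(paths: DensePaths, G: GenotypeMatrix, stride: int = 5) -> np.ndarray:
    """Per-timepoint R-squared of the exposure on the genotype dosages.

    Regresses ``X(t)`` on all variants jointly at every ``stride``-th
    grid point and returns the R-squared profile — the instrument
    strength of the variants for the exposure at single timepoints.
    """
    Z = G.dosages - G.dosages.mean(axis=0)
    X = paths.exposure[:, ::stride]
    X = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Z, X, rcond=None)
    resid = X - Z @ coef
    tss = np.sum(X**2, axis=0)
    rss = np.sum(resid**2, axis=0)
    return 1.0 - rss / tss
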