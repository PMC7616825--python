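"""PACE pipeline: smoothers, spectrum, conditional-expectation scores."""

import numpy as np
import pandas as pd
import pytest

from mpcmr.fpca import (
    BandwidthError,
    SparseLongitudinal,
    eigen_decompose,
    estimate_cov,
    estimate_mean,
    fit_fpca,
    pace_scores,
    select_K,
)
from mpcmr.grids import TimeGrid

T = 50.0


def long_format(times, values):
    n, m = times.shape
    return SparseLongitudinal(
        pd.DataFrame(
            {
                "subject_id": np.repeat(np.arange(n), m),
                "time": times.ravel(),
                "value": values.ravel(),
            }
        ),
        t_min=0.0,
        t_max=T,
    )


def kl_model_sample(rng, n=2000, m=5, lam=(4.0, 1.0), sigma=0.5):
    """Two-component Karhunen-Loeve model with known spectrum.

    phi1 constant, phi2 centered linear, both unit-norm on [0, T].
    """
    phi1 = lambda t: np.full_like(t, 1.0 / np.sqrt(T))
    phi2 = lambda t: np.sqrt(12.0 / T**3) * (t - T / 2.0)
    times = np.sort(rng.uniform(0, T, size=(n, m)), axis=1)
    xi = rng.normal(0, 1, size=(n, 2)) * np.sqrt(lam)
    vals = xi[:, :1] * phi1(times) + xi[:, 1:] * phi2(times)
    vals = vals + rng.normal(0, sigma, size=(n, m))
    return long_format(times, vals), np.asarray(lam), sigma


class TestMean:
    def test_constant_data(self, rng):
        times = rng.uniform(0, T, size=(50, 4))
        data = long_format(times, np.full_like(times, 3.25))
        grid = TimeGrid.uniform(T, 101)
        np.testing.assert_allclose(estimate_mean(data, grid, 5.0), 3.25)

    def test_exact_on_linear_functions(self, rng):
        times = rng.uniform(0, T, size=(400, 4))
        data = long_format(times, 1.5 - 0.3 * times)
        grid = TimeGrid.uniform(T, 101)
        mu = estimate_mean(data, grid, 7.0)
        np.testing.assert_allclose(mu, 1.5 - 0.3 * grid.points, atol=1e-6)

    def test_matches_pointwise_means_on_balanced_design(self, rng):
        obs_t = np.linspace(0, T, 11)
        n = 3000
        times = np.tile(obs_t, (n, 1))
        values = 2.0 + 0.1 * times + rng.normal(0, 0.5, size=times.shape)
        data = long_format(times, values)
        grid = TimeGrid(obs_t)
        mu = estimate_mean(data, grid, 4.0)
        pointwise = values.mean(axis=0)
        np.testing.assert_allclose(mu, pointwise, atol=0.05)

    def test_tiny_bandwidth_raises(self, rng):
        times = rng.uniform(20, 30, size=(20, 3))
        data = long_format(times, np.ones_like(times))
        grid = TimeGrid.uniform(T, 51)
        with pytest.raises(BandwidthError, match="bandwidth"):
            estimate_mean(data, grid, 0.5)


class TestCovariance:
    def test_surface_symmetric(self, rng):
        data, *_ = kl_model_sample(rng, n=300)
        grid = TimeGrid.uniform(T, 51)
        mu = estimate_mean(data, grid, 5.0)
        surface, _ = estimate_cov(data, mu, grid, 7.5)
        np.testing.assert_array_equal(surface, surface.T)

    def test_known_spectrum_recovered(self, rng):
        # average over replicates: single-fit eigenvalues at n=2000 carry
        # Monte-Carlo noise of ~10% on the smaller component
        fits = []
        for _ in range(3):
            data, lam, sigma = kl_model_sample(rng, n=2000)
            fits.append(fit_fpca(data, K=2))
        lam_hat = np.mean([f.eigenvalues for f in fits], axis=0)
        sig_hat = np.mean([f.sigma2 for f in fits])
        assert lam_hat[0] == pytest.approx(lam[0], rel=0.15)
        assert lam_hat[1] == pytest.approx(lam[1], rel=0.15)
        assert sig_hat == pytest.approx(sigma**2, rel=0.3)

    def test_noiseless_dense_nugget_near_zero(self, rng):
        grid_t = np.linspace(0, T, 51)
        n = 300
        xi = rng.normal(0, 1, size=(n, 2))
        curves = xi[:, :1] / np.sqrt(T) + xi[:, 1:] * np.sqrt(12 / T**3) * (
            grid_t - T / 2
        )
        data = long_format(np.tile(grid_t, (n, 1)), curves)
        model = fit_fpca(data, K=2, grid_size=51)
        assert model.sigma2 < 0.01 * model.eigenvalues[0]

    def test_requires_repeat_measures(self, rng):
        times = rng.uniform(0, T, size=(30, 1))
        data = long_format(times, np.ones_like(times))
        grid = TimeGrid.uniform(T, 51)
        mu = estimate_mean(data, grid, 10.0)
        with pytest.raises(ValueError, match="2 observations"):
            estimate_cov(data, mu, grid, 10.0)


class TestEigen:
    def test_orthonormal_under_quadrature(self, rng):
        data, *_ = kl_model_sample(rng, n=800)
        model = fit_fpca(data, K=2)
        gram = (model.eigenfunctions * model.grid.weights[None, :]) @ model.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-6)

    def test_rank_one_surface(self):
        grid = TimeGrid.uniform(T, 201)
        phi = np.sqrt(12.0 / T**3) * (grid.points - T / 2.0)
        phi = phi / np.sqrt(grid.inner(phi, phi))  # unit norm under quadrature
        surface = np.outer(phi, phi)
        vals, funcs = eigen_decompose(surface, grid)
        assert vals[0] == pytest.approx(1.0, abs=1e-6)
        assert vals.size == 1
        err = min(
            np.max(np.abs(funcs[0] - phi)), np.max(np.abs(funcs[0] + phi))
        )
        assert err < 1e-6

    def test_dense_limit_matches_classical_pca(self, rng):
        # discretised covariance operator vs PCA of the curve matrix
        grid = TimeGrid.uniform(T, 201)
        n = 500
        basis = np.stack(
            [np.ones_like(grid.points), grid.points / T, (grid.points / T) ** 2]
        )
        X = rng.normal(0, 1, size=(n, 3)) @ (basis * [[2.0], [1.0], [0.5]])
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / n
        vals, _ = eigen_decompose(cov, grid)
        # classical PCA oracle: SVD of the quadrature-weighted curve matrix
        svals = (
            np.linalg.svd(
                Xc * np.sqrt(grid.weights)[None, :] / np.sqrt(n), compute_uv=False
            )
            ** 2
        )
        np.testing.assert_allclose(vals[:3], svals[:3], rtol=1e-6)

    def test_sign_convention_fixed(self):
        grid = TimeGrid.uniform(T, 201)
        phi = np.sqrt(12.0 / T**3) * (grid.points - T / 2.0)
        for s in (phi, -phi):
            _, funcs = eigen_decompose(np.outer(s, s), grid)
            assert grid.inner(funcs[0], grid.points) >= 0


class TestScores:
    def test_dense_noiseless_scores_are_projections(self, rng):
        grid_t = np.linspace(0, T, 101)
        grid = TimeGrid(grid_t)
        n = 200
        phi = np.stack(
            [
                np.full_like(grid_t, 1 / np.sqrt(T)),
                np.sqrt(12 / T**3) * (grid_t - T / 2),
            ]
        )
        xi_true = rng.normal(0, 1, size=(n, 2)) * np.sqrt([4.0, 1.0])
        curves = xi_true @ phi
        data = long_format(np.tile(grid_t, (n, 1)), curves)
        lam = np.array([4.0, 1.0])
        scores = pace_scores(data, grid, np.zeros_like(grid_t), phi, lam, sigma2=0.0)
        projections = (curves * grid.weights[None, :]) @ phi.T
        np.testing.assert_allclose(scores, projections, atol=1e-3)

    def test_subject_at_mean_has_zero_scores(self, rng):
        data, *_ = kl_model_sample(rng, n=400)
        model = fit_fpca(data, K=2)
        times = np.linspace(5, 45, 6)
        at_mean = long_format(
            times[None, :], np.interp(times, model.grid.points, model.mu)[None, :]
        )
        scores = pace_scores(
            at_mean, model.grid, model.mu, model.eigenfunctions,
            model.eigenvalues, model.sigma2,
        )
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_blup_shrinkage(self, rng):
        data, *_ = kl_model_sample(rng, n=2000)
        model = fit_fpca(data, K=2)
        sample_var = model.scores.var(axis=0)
        assert np.all(sample_var <= model.eigenvalues * 1.05)


class TestSelectK:
    @pytest.mark.parametrize(
        "lam,threshold,expected",
        [((3.0, 1.0), 0.75, 1), ((3.0, 1.0), 0.76, 2), ((5.0,), 1.0, 1)],
    )
    def test_threshold_rule(self, lam, threshold, expected):
        assert select_K(lam, threshold) == expected

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="spectrum"):
            select_K([], 0.9)


class TestOnSimulatedCohort:
    def test_two_components_reach_95_percent(self, fpca_b3):
        assert fpca_b3.fve[1] >= 0.95

    def test_eigenfunctions_approximately_linear(self, fpca_b3):
        # linear genetic effects + Wiener noise: leading eigenfunctions are
        # close to (but not exactly) linear in t
        t = fpca_b3.grid.points
        for k in range(2):
            phi = fpca_b3.eigenfunctions[k]
            resid = phi - np.polyval(np.polyfit(t, phi, 1), t)
            r2 = 1 - np.sum(resid**2) / np.sum((phi - phi.mean()) ** 2)
            assert r2 >= 0.80

    def test_descending_eigenvalues(self, fpca_b3):
        assert np.all(np.diff(fpca_b3.eigenvalues) < 0)
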