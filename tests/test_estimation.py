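"""CUE-GMM, association fit, effect-curve reconstruction, contrasts."""

import numpy as np
import pytest

from conftest import make_linear_iv
from mpcmr.basis import make_basis, transform_matrix, transform_scores
from mpcmr.estimation import (
    GmmFit,
    association_fit,
    build_ivdata,
    cue_gmm,
    intervention_effect,
    reconstruct_effect,
)
from mpcmr.grids import TimeGrid

T = 50.0


class TestBuildIvdata:
    def test_centers_all_blocks(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=500)
        data = build_ivdata(Z, E, y)
        assert np.allclose(data.Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(data.E.mean(axis=0), 0, atol=1e-10)
        assert abs(data.y.mean()) < 1e-10

    def test_already_centered_unchanged(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=500)
        Zc, Ec, yc = Z - Z.mean(0), E - E.mean(0), y - y.mean()
        data = build_ivdata(Zc, Ec, yc)
        np.testing.assert_allclose(data.Z, Zc, atol=1e-12)
        np.testing.assert_allclose(data.E, Ec, atol=1e-12)

    def test_constant_instrument_dropped(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=500)
        Z[:, 3] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            data = build_ivdata(Z, E, y)
        assert data.J == Z.shape[1] - 1

    def test_under_identified_rejected(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=500, J=10, L=2)
        with pytest.raises(ValueError, match="identified"):
            build_ivdata(Z[:, :1], E, y)


class TestCueGmm:
    def test_just_identified_equals_2sls_closed_form(self, rng):
        # with J = L the moment equations are solved exactly, so the CUE
        # minimiser coincides with the 2SLS closed form
        Z, E, y, _ = make_linear_iv(rng, n=3000, J=2, L=2, confounded=True)
        data = build_ivdata(Z, E, y)
        fit = cue_gmm(data)
        Pz = data.Z @ np.linalg.solve(data.Z.T @ data.Z, data.Z.T)
        tsls = np.linalg.solve(data.E.T @ Pz @ data.E, data.E.T @ Pz @ data.y)
        np.testing.assert_allclose(fit.beta_star, tsls, atol=1e-6)
        assert fit.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_wald_ratio_single_instrument(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=2000, J=1, L=1, confounded=True)
        data = build_ivdata(Z, E, y)
        fit = cue_gmm(data)
        wald = np.cov(data.Z[:, 0], data.y)[0, 1] / np.cov(data.Z[:, 0], data.E[:, 0])[0, 1]
        assert fit.beta_star[0] == pytest.approx(wald, rel=1e-8)

    def test_exact_model_recovered(self, rng):
        Z, E, _, beta = make_linear_iv(rng, n=800, J=6, L=2)
        y = E @ beta  # no outcome noise at all
        data = build_ivdata(Z, E, y)
        fit = cue_gmm(data)
        np.testing.assert_allclose(fit.beta_star, beta, atol=1e-8)
        assert fit.objective_value == pytest.approx(0.0, abs=1e-8)

    def test_consistent_under_confounding(self, rng):
        Z, E, y, beta = make_linear_iv(rng, n=20_000, J=10, L=2, confounded=True)
        fit = cue_gmm(build_ivdata(Z, E, y))
        np.testing.assert_allclose(fit.beta_star, beta, atol=4 * fit.se.max())

    def test_objective_is_minimal_at_estimate(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=1500, J=8, L=2)
        data = build_ivdata(Z, E, y)
        fit = cue_gmm(data)
        from mpcmr.estimation import _cue_objective, _cue_pieces

        _, Minv, Szy, SzE = _cue_pieces(data)
        at_fit = _cue_objective(data, fit.beta_star, Minv, Szy, SzE)
        for _ in range(25):
            other = fit.beta_star + rng.normal(0, 0.2, size=2)
            assert _cue_objective(data, other, Minv, Szy, SzE) >= at_fit - 1e-9

    def test_instrument_rescaling_equivariance(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=1500, J=8, L=2)
        fit1 = cue_gmm(build_ivdata(Z, E, y))
        Z2 = Z.copy()
        Z2[:, 0] *= 17.0
        fit2 = cue_gmm(build_ivdata(Z2, E, y))
        np.testing.assert_allclose(fit1.beta_star, fit2.beta_star, rtol=1e-8)

    def test_row_permutation_invariance(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=900, J=5, L=2)
        perm = rng.permutation(len(y))
        fit1 = cue_gmm(build_ivdata(Z, E, y))
        fit2 = cue_gmm(build_ivdata(Z[perm], E[perm], y[perm]))
        np.testing.assert_allclose(fit1.beta_star, fit2.beta_star, rtol=1e-10)


class TestAssociationFit:
    def test_orthogonal_design_coefficients(self, rng):
        n = 400
        E = rng.normal(size=(n, 2))
        q, _ = np.linalg.qr(E - E.mean(0))
        E = q  # orthonormal centered columns up to fp error
        y = rng.normal(size=n)
        fit = association_fit(E, y)
        yc = y - y.mean()
        expected = np.linalg.solve(
            (E - E.mean(0)).T @ (E - E.mean(0)), (E - E.mean(0)).T @ yc
        )
        np.testing.assert_allclose(fit.beta_star, expected, atol=1e-10)

    def test_equals_gmm_when_self_instrumenting(self, rng):
        Z, E, y, _ = make_linear_iv(rng, n=1000, J=2, L=2)
        ols = association_fit(E, y)
        gmm = cue_gmm(build_ivdata(E.copy(), E, y))
        np.testing.assert_allclose(ols.beta_star, gmm.beta_star, atol=1e-8)

    def test_biased_under_confounding_while_gmm_is_not(self, rng):
        Z, E, y, beta = make_linear_iv(rng, n=20_000, J=10, L=2, confounded=True)
        ols = association_fit(E, y)
        gmm = cue_gmm(build_ivdata(Z, E, y))
        ols_err = np.abs(ols.beta_star - beta).max()
        gmm_err = np.abs(gmm.beta_star - beta).max()
        assert ols_err > 10 * np.sqrt(np.diag(ols.Sigma)).max()  # real bias
        assert gmm_err < ols_err


class TestEffectCurve:
    def grid(self):
        return TimeGrid.uniform(T, 101)

    def test_eigenbasis_round_trip(self, fpca_b3):
        basis = make_basis("eigenfunction", model=fpca_b3)
        fit = GmmFit(
            beta_star=np.array([0.7, -0.2]),
            Sigma=np.eye(2) * 0.01,
            G_hat=None,
            Omega_at_fit=None,
            objective_value=0.0,
            method="cue_gmm",
        )
        curve = reconstruct_effect(fit, basis)
        grid = fpca_b3.grid
        back = (fpca_b3.eigenfunctions * grid.weights[None, :]) @ curve.beta_t
        np.testing.assert_allclose(back, fit.beta_star, atol=1e-6)

    def test_constant_basis_flat_curve(self):
        grid = self.grid()
        basis = make_basis("polynomial", grid=grid, degree=0)
        fit = GmmFit(
            beta_star=np.array([0.3]),
            Sigma=np.array([[0.04]]),
            G_hat=None,
            Omega_at_fit=None,
            objective_value=0.0,
            method="cue_gmm",
        )
        curve = reconstruct_effect(fit, basis)
        np.testing.assert_allclose(curve.beta_t, 0.3)
        np.testing.assert_allclose(curve.se_t, 0.2)
        np.testing.assert_allclose(curve.wald_hi - curve.wald_lo, 2 * 1.959964 * 0.2, rtol=1e-5)

    def test_se_matches_quadratic_form(self, rng):
        grid = self.grid()
        basis = make_basis("polynomial", grid=grid, degree=1)
        Sigma = np.diag([0.04, 0.09])
        fit = GmmFit(
            beta_star=np.array([0.1, 0.5]),
            Sigma=Sigma,
            G_hat=None,
            Omega_at_fit=None,
            objective_value=0.0,
            method="cue_gmm",
        )
        curve = reconstruct_effect(fit, basis)
        u = grid.points / T
        hand = np.sqrt(0.04 + 0.09 * u**2)
        np.testing.assert_allclose(curve.se_t, hand, rtol=1e-10)


class TestIntervention:
    def make_constant_curve(self, value=0.1, var=0.0004):
        grid = TimeGrid.uniform(T, 101)
        basis = make_basis("polynomial", grid=grid, degree=0)
        fit = GmmFit(
            beta_star=np.array([value]),
            Sigma=np.array([[var]]),
            G_hat=None,
            Omega_at_fit=None,
            objective_value=0.0,
            method="cue_gmm",
        )
        return reconstruct_effect(fit, basis)

    def test_unit_intervention_constant_effect(self):
        curve = self.make_constant_curve(0.1)
        effect, se = intervention_effect(curve, np.ones(101))
        assert effect == pytest.approx(5.0, rel=1e-10)  # 0.1 * 50
        assert se == pytest.approx(np.sqrt(0.0004) * 50, rel=1e-10)

    def test_zero_intervention(self):
        curve = self.make_constant_curve()
        effect, se = intervention_effect(curve, np.zeros(101))
        assert effect == 0.0
        assert se == 0.0

    def test_basis_curve_intervention(self, fpca_b3):
        basis = make_basis("eigenfunction", model=fpca_b3)
        fit = GmmFit(
            beta_star=np.array([0.7, -0.2]),
            Sigma=np.eye(2) * 0.01,
            G_hat=None,
            Omega_at_fit=None,
            objective_value=0.0,
            method="cue_gmm",
        )
        curve = reconstruct_effect(fit, basis)
        b1 = fpca_b3.eigenfunctions[0]
        effect, _ = intervention_effect(curve, b1)
        # orthonormality: only gamma_1 survives, times ∫ b1^2 dt = 1
        assert effect == pytest.approx(0.7, abs=1e-6)


class TestOnSimulatedCohort:
    def test_gmm_recovers_increasing_effect_and_association_is_biased(
        self, sim_b3, fpca_b3
    ):
        grid = fpca_b3.grid
        basis = make_basis("polynomial", grid=grid, degree=1)
        B = transform_matrix(fpca_b3.eigenfunctions, basis, grid)
        xi_star = transform_scores(fpca_b3.scores, B)
        data = build_ivdata(sim_b3.genotypes.dosages, xi_star, sim_b3.outcome)
        fit = cue_gmm(data)
        curve = reconstruct_effect(fit, basis)
        truth = 0.02 * grid.points
        tpts = [10.0, 20.0, 30.0, 40.0]
        idx = np.searchsorted(grid.points, tpts)
        # GMM point curve near the truth (a few SEs at n=2000)
        assert np.all(np.abs(curve.beta_t[idx] - truth[idx]) < 4 * curve.se_t[idx] + 0.05)
        assoc = association_fit(xi_star, sim_b3.outcome)
        acurve = reconstruct_effect(assoc, basis)
        # confounding pushes the association curve far outside its own CI
        assert np.any(np.abs(acurve.beta_t[idx] - truth[idx]) > 8 * acurve.se_t[idx])
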