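"""FOCE machinery: Omega parameterization, inner problem, likelihood, SEs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize

from mignlme import (
    CellTimeSeries,
    Dataset,
    GlucoseProgram,
    PopulationParameters,
    build_omega,
    default_start,
    foce_loglik,
    omega_to_correlation,
    reported_fit,
)
from mignlme import _kernels
from mignlme.foce import (
    FOCEConfig,
    central_gradient,
    central_hessian,
    foce_cell_general,
    individual_joint_loglik,
    inner_optimize,
)

PROG = GlucoseProgram(post_level=1.0)

factor_entries = st.floats(min_value=-2.0, max_value=2.0)


class TestOmegaParameterization:
    def test_reported_factor_reproduces_reported_covariance(self):
        """Exp-1 factor entries rebuild the printed covariance and correlation."""
        omega = build_omega(reported_fit(1).omega)
        # printed at 2 significant figures
        assert round(float(omega[0, 0]), 4) == 0.0058
        assert round(float(omega[0, 1]), 3) == 0.009
        assert omega[0, 2] == pytest.approx(12e-6, rel=0.02)
        assert round(float(omega[1, 1]), 3) == 0.055
        assert round(float(omega[1, 2]), 2) == 0.01
        assert round(float(omega[2, 2]), 3) == 0.065
        corr = omega_to_correlation(omega)
        assert round(float(corr[0, 1]), 2) == 0.51

    def test_exp3_correlation_k2_k4(self):
        corr = omega_to_correlation(build_omega(reported_fit(3).omega))
        assert round(float(corr[1, 2]), 2) == 0.86

    def test_diagonal_factor_gives_diagonal_matrix(self):
        omega = build_omega((0.3, 0.0, 0.0, 0.5, 0.0, 0.7))
        np.testing.assert_allclose(omega, np.diag([0.09, 0.25, 0.49]))
        np.testing.assert_allclose(omega_to_correlation(omega), np.eye(3))

    @given(w=st.tuples(*[factor_entries] * 6))
    def test_always_symmetric_psd(self, w):
        omega = build_omega(w)
        np.testing.assert_allclose(omega, omega.T)
        assert np.linalg.eigvalsh(omega).min() >= -1e-12

    def test_correlation_requires_positive_diagonal(self):
        with pytest.raises(ValueError):
            omega_to_correlation(np.diag([1.0, 0.0, 1.0]))


class TestIndividualLoglik:
    theta = default_start()

    def test_zero_residual_zero_eta_collapses_to_constants(self):
        """With a perfect fit at the prior mode only the normalizing
        constants remain."""
        pred = _kernels.mig1_pred(np.array([60.0]), self.theta.Mbar_s,
                                  self.theta.kbar2, self.theta.kbar4, PROG.ratio)
        cell = CellTimeSeries("c", np.array([60.0]), pred)
        value = individual_joint_loglik(self.theta, np.zeros(3), cell, PROG)
        omega = self.theta.omega_matrix()
        expected = -0.5 * np.log(2 * np.pi * self.theta.s) \
            - 0.5 * np.linalg.slogdet(2 * np.pi * omega)[1]
        assert value == pytest.approx(expected, rel=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        """Independent re-evaluation of the printed formula on a toy case."""
        times = np.array([-30.0, 30.0, 120.0, 600.0])
        eta = np.array([0.05, -0.2, 0.1])
        pred = _kernels.mig1_pred(
            times, self.theta.Mbar_s * np.exp(eta[0]),
            self.theta.kbar2 * np.exp(eta[1]),
            self.theta.kbar4 * np.exp(eta[2]), PROG.ratio,
        )
        data = pred + rng.normal(0, 100, size=4)
        cell = CellTimeSeries("c", times, data)
        omega = self.theta.omega_matrix()
        s = self.theta.s
        eps = data - pred
        oracle = sum(
            -0.5 * (e**2 / s + np.log(2 * np.pi * s)) for e in eps
        ) - 0.5 * eta @ np.linalg.inv(omega) @ eta \
          - 0.5 * np.linalg.slogdet(2 * np.pi * omega)[1]
        value = individual_joint_loglik(self.theta, eta, cell, PROG)
        assert value == pytest.approx(oracle, rel=1e-10)

    def test_larger_residual_lowers_loglik(self):
        times = np.array([120.0])
        pred = _kernels.mig1_pred(times, self.theta.Mbar_s, self.theta.kbar2,
                                  self.theta.kbar4, PROG.ratio)
        near = CellTimeSeries("a", times, pred + 50.0)
        far = CellTimeSeries("b", times, pred + 100.0)
        eta = np.zeros(3)
        assert individual_joint_loglik(self.theta, eta, near, PROG) > \
            individual_joint_loglik(self.theta, eta, far, PROG)


class TestInnerOptimize:
    theta = default_start()

    def test_no_observations_gives_prior_mode(self):
        cell = CellTimeSeries("empty", np.array([]), np.array([]))
        eta = inner_optimize(self.theta, cell, PROG)
        np.testing.assert_allclose(eta, 0.0, atol=1e-12)

    def test_linear_model_matches_ridge_solution(self, rng):
        """For a predictor linear in eta the mode has the GLS/ridge closed form."""
        a = rng.normal(100, 10, 5)
        B = rng.normal(0, 20, (5, 3))
        omega = build_omega((0.3, 0.1, 0.0, 0.4, -0.1, 0.5))
        s = 4.0
        d = a + B @ np.array([0.2, -0.3, 0.1]) + rng.normal(0, 2, 5)
        _, eta, _ = foce_cell_general(lambda e: a + B @ e, d, s, omega)
        closed = np.linalg.solve(B.T @ B / s + np.linalg.inv(omega), B.T @ (d - a) / s)
        np.testing.assert_allclose(eta, closed, atol=1e-7)

    def test_warm_start_basin_stability(self, rng):
        """On informative data the mode is independent of the starting point."""
        times = np.arange(-30.0, 1201.0, 90.0)
        eta_true = np.array([0.1, 0.3, -0.2])
        pred = _kernels.mig1_pred(
            times, self.theta.Mbar_s * np.exp(eta_true[0]),
            self.theta.kbar2 * np.exp(eta_true[1]),
            self.theta.kbar4 * np.exp(eta_true[2]), PROG.ratio,
        )
        cell = CellTimeSeries("c", times, pred + rng.normal(0, 50, times.size))
        a = inner_optimize(self.theta, cell, PROG, warm_start=None)
        b = inner_optimize(self.theta, cell, PROG, warm_start=[0.5, -0.5, 0.5])
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestFOCELoglik:
    def _toy_dataset(self, rng, n_cells=4, n_obs=6):
        theta = reported_fit(3)
        cells = []
        times = np.linspace(-30, 1200, n_obs)
        for i in range(n_cells):
            eta = rng.multivariate_normal(np.zeros(3), theta.omega_matrix())
            pred = _kernels.mig1_pred(
                times, theta.Mbar_s * np.exp(eta[0]), theta.kbar2 * np.exp(eta[1]),
                theta.kbar4 * np.exp(eta[2]), PROG.ratio,
            )
            cells.append(CellTimeSeries(f"c{i}", times,
                                        pred + rng.normal(0, 100, n_obs)))
        return Dataset(cells, PROG), theta

    def test_linear_gaussian_model_is_exact(self, rng):
        """On a model linear in eta, FOCE equals the closed-form marginal for
        any Omega, s and design (the Laplace expansion is exact)."""
        for _ in range(3):
            n = rng.integers(2, 9)
            a = rng.normal(10, 3, n)
            B = rng.normal(0, 2, (n, 3))
            omega = build_omega(tuple(rng.normal(0.2, 0.3, 6)))
            if np.linalg.det(omega) < 1e-12:
                continue
            s = float(rng.uniform(0.2, 3.0))
            d = a + B @ rng.multivariate_normal(np.zeros(3), omega) \
                + rng.normal(0, np.sqrt(s), n)
            contrib, _, _ = foce_cell_general(lambda e: a + B @ e, d, s, omega)
            S = B @ omega @ B.T + s * np.eye(n)
            resid = d - a
            exact = -0.5 * (resid @ np.linalg.solve(S, resid)
                            + np.linalg.slogdet(2 * np.pi * S)[1])
            assert contrib == pytest.approx(exact, rel=1e-8)

    def test_general_path_agrees_with_compiled_path(self, rng):
        """The pure-NumPy reference engine and the numba kernels implement the
        same approximation."""
        ds, theta = self._toy_dataset(rng)
        total_general = 0.0
        for cell in ds.cells:
            times = cell.times

            def predict(e, t=times):
                return _kernels.mig1_pred(
                    t, theta.Mbar_s * np.exp(e[0]), theta.kbar2 * np.exp(e[1]),
                    theta.kbar4 * np.exp(e[2]), PROG.ratio,
                )

            contrib, _, _ = foce_cell_general(
                predict, cell.intensities, theta.s, theta.omega_matrix(), fd_step=1e-6
            )
            total_general += contrib
        assert foce_loglik(theta, ds) == pytest.approx(total_general, rel=1e-6)

    def test_vanishing_omega_approaches_fixed_effects_likelihood(self, rng):
        """As Omega -> 0 the population likelihood tends to the likelihood of
        the median-parameter model (prior and Laplace determinants cancel)."""
        ds, theta = self._toy_dataset(rng)
        eps = 1e-6
        shrunk = PopulationParameters(theta.Mbar_s, theta.kbar2, theta.kbar4,
                                      theta.s, (eps, 0, 0, eps, 0, eps))
        value = foce_loglik(shrunk, ds)
        direct = 0.0
        for cell in ds.cells:
            pred = _kernels.mig1_pred(cell.times, theta.Mbar_s, theta.kbar2,
                                      theta.kbar4, PROG.ratio)
            e = cell.intensities - pred
            direct += -0.5 * np.sum(e**2 / theta.s + np.log(2 * np.pi * theta.s))
        assert value == pytest.approx(direct, rel=1e-6)

    def test_invariant_to_cell_and_observation_order(self, rng):
        ds, theta = self._toy_dataset(rng)
        reordered = Dataset(ds.cells[::-1], ds.program)
        assert foce_loglik(theta, ds) == pytest.approx(
            foce_loglik(theta, reordered), rel=1e-12
        )

    def test_invalid_theta_raises(self, rng):
        ds, theta = self._toy_dataset(rng)
        bad = PopulationParameters(theta.Mbar_s, theta.kbar2, theta.kbar4,
                                   theta.s, (0.0, 0, 0, 0.1, 0, 0.1))
        with pytest.raises(ValueError):
            foce_loglik(bad, ds)


def test_default_start_values():
    start = default_start()
    assert start.Mbar_s == 3300.0
    assert start.kbar2 == 0.02
    assert start.kbar4 == 0.005
    assert start.s == 40_000.0
    assert start.omega == (0.1, 0.0, 0.0, 0.1, 0.0, 0.1)


class TestFiniteDifferences:
    def test_gradient_and_hessian_on_known_quadratic(self):
        """f(x) = -1/2 x'Cx has gradient -Cx and Hessian -C; the SE of a
        quadratic log-likelihood with curvature c is 1/sqrt(c)."""
        C = np.array([[4.0, 1.0], [1.0, 9.0]])

        def f(x):
            return -0.5 * x @ C @ x

        x0 = np.array([0.3, -0.7])
        np.testing.assert_allclose(central_gradient(f, x0), -C @ x0, rtol=1e-6)
        hess = central_hessian(f, np.zeros(2), np.array([1e-4, 1e-4]))
        np.testing.assert_allclose(hess, -C, atol=1e-5)
        se = np.sqrt(np.diag(np.linalg.inv(-hess)))
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(C))), rtol=1e-5)

    @pytest.mark.parametrize("estimate, se, expected", [(2.0, 0.2, 10.0),
                                                        (-2.0, 0.2, 10.0)])
    def test_rse_definition(self, estimate, se, expected):
        assert 100.0 * abs(se / estimate) == pytest.approx(expected)


def test_reparameterization_consistency(rng):
    """Log-scale BFGS and a bound-constrained natural-scale optimizer find
    the same optimum on a small well-conditioned problem."""
    from mignlme import fit_population
    from mignlme.data import StudyDesign, generate_dataset

    theta_true = PopulationParameters(3300.0, 0.006, 0.01, 10_000.0,
                                      (0.2, 0.0, 0.0, 0.2, 0.0, 0.2))
    design = StudyDesign.uniform(12, PROG, fraction_sparse=0.0)
    ds = generate_dataset(theta_true, design, seed=4)
    fit = fit_population(ds, config=FOCEConfig(outer_maxiter=200))

    bounds = [(1e2, 1e5), (1e-4, 1.0), (1e-4, 1.0), (1e1, 1e7)] + [(-3, 3)] * 6

    def nll(vec):
        try:
            return -foce_loglik(PopulationParameters.from_vector(vec), ds)
        except ValueError:
            return 1e12

    res = optimize.minimize(nll, theta_true.to_vector(), method="Nelder-Mead",
                            bounds=bounds,
                            options={"maxiter": 8000, "xatol": 1e-10, "fatol": 1e-10})
    assert fit.log_likelihood == pytest.approx(-res.fun, abs=0.05)
    np.testing.assert_allclose(
        fit.theta_hat.to_vector()[:4], res.x[:4], rtol=0.02
    )
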