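"""FOCE estimation of the nonlinear mixed-effects Mig1 population model.

The population model places log-normal cell-to-cell variability on the
individual parameters,

    M_s = Mbar_s * exp(eta1),  k2 = kbar2 * exp(eta2),  k4 = kbar4 * exp(eta3),

with eta ~ N(0, Omega) and additive Gaussian measurement noise of variance
s.  Omega is parameterized as U U' with U upper triangular (entries
w11, w12, w13, w22, w23, w33), which is positive semi-definite and
symmetric by construction; the signs of U's diagonal are left free.

The marginal (population) likelihood

    L(theta) = prod_i  integral  p1(d_i | theta, eta_i) p2(eta_i | theta) d eta_i

has no closed form.  It is approximated by the Laplacian expansion of the
individual joint log-likelihood l_i around its conditional mode eta*_i,
with the Hessian replaced by its first-order (Gauss-Newton) approximation
-(grad eps)' R^-1 (grad eps) - Omega^-1 -- the first-order conditional
estimation (FOCE) method:

    log L_a = sum_i [ l_i(eta*_i) - 1/2 logdet( -Delta l_i(eta*_i) / 2 pi ) ].

Because the residual variance R = s is a constant scalar here (no
eta-dependence), the FOCE and FOCEI variants coincide.  log L_a is
maximized over the 10-vector theta = (Mbar_s, kbar2, kbar4, s, w11..w33)
by BFGS, with the strictly positive parameters optimized on the log scale.
Standard errors come from the inverse negative Hessian of log L_a on the
untransformed scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, TYPE_CHECKING

import numpy as np
from scipy import optimize

from . import _kernels
from .model import GlucoseProgram

if TYPE_CHECKING:  # pragma: no cover
    from .data import CellTimeSeries, Dataset

__all__ = [
    "PopulationParameters",
    "FOCEConfig",
    "FOCEFit",
    "build_omega",
    "omega_to_correlation",
    "default_start",
    "individual_joint_loglik",
    "inner_optimize",
    "foce_loglik",
    "fit_population",
    "compute_standard_errors",
    "foce_cell_general",
]

PARAM_NAMES = ("Mbar_s", "kbar2", "kbar4", "s", "w11", "w12", "w13", "w22", "w23", "w33")
_POSITIVE = np.array([True, True, True, True] + [False] * 6)


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, noise variance and Omega-factor entries (theta)."""

    Mbar_s: float
    kbar2: float
    kbar4: float
    s: float
    omega: tuple = (0.1, 0.0, 0.0, 0.1, 0.0, 0.1)

    def __post_init__(self) -> None:
        if not (self.Mbar_s > 0 and self.kbar2 > 0 and self.kbar4 > 0 and self.s > 0):
            raise ValueError("Mbar_s, kbar2, kbar4 and s must be strictly positive")
        if len(self.omega) != 6:
            raise ValueError("omega must hold the six factor entries w11..w33")

    def to_vector(self) -> np.ndarray:
        return np.array([self.Mbar_s, self.kbar2, self.kbar4, self.s, *self.omega])

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "PopulationParameters":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[0], vec[1], vec[2], vec[3], tuple(vec[4:10]))

    def omega_matrix(self) -> np.ndarray:
        return build_omega(self.omega)


def build_omega(factor: Sequence[float]) -> np.ndarray:
    """Omega = U U' from the six upper-triangular factor entries.

    Symmetric and positive semi-definite by construction, for any signs of
    the entries.
    """
    w = np.asarray(factor, dtype=float)
    if w.shape != (6,):
        raise ValueError("factor must have six entries (w11,w12,w13,w22,w23,w33)")
    u = np.array([[w[0], w[1], w[2]], [0.0, w[3], w[4]], [0.0, 0.0, w[5]]])
    return u @ u.T


def omega_to_correlation(omega: np.ndarray) -> np.ndarray:
    """Correlation matrix corr_ij = Omega_ij / sqrt(Omega_ii * Omega_jj)."""
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("all diagonal entries of Omega must be positive")
    sd = np.sqrt(d)
    return omega / np.outer(sd, sd)


def default_start() -> PopulationParameters:
    """Starting values: visual-inspection guesses shared by all experiments.

    Baseline intensity 3300 a.u.; k4 = 1/200 s^-1 from the ~200 s re-entry
    time scale; k2 = 1/50 s^-1 from the initial exit time scale; noise
    variance 40 000 (noise on the scale of a couple hundred intensity
    units); Omega factor diag(0.1) -- roughly +/-10% parameter spread with
    no covariance.
    """
    return PopulationParameters(3300.0, 0.02, 0.005, 40_000.0)


@dataclass
class FOCEConfig:
    """Numerical settings for the nested FOCE optimization."""

    inner_tol: float = 1e-6            # gradient-norm tolerance for eta*
    inner_maxit: int = 100
    outer_gtol: float = 1e-4           # BFGS gradient-norm tolerance
    outer_maxiter: int = 500
    fd_rel_step: float = 1e-4          # central-difference step for outer gradient
    hessian_rel_step: float = 1e-4     # central-difference step for the SE Hessian
    compute_se: bool = False


@dataclass
class FOCEFit:
    """Result of a population fit: estimates, likelihood, EBEs, diagnostics."""

    theta_hat: PopulationParameters
    log_likelihood: float
    ebes: np.ndarray                   # (n_cells, 3) conditional modes eta*_i
    cell_ids: list
    program: GlucoseProgram
    converged: bool
    n_iterations: int
    gradient_norm: float
    message: str = ""
    hessian: Optional[np.ndarray] = None        # 10x10, untransformed scale
    covariance: Optional[np.ndarray] = None     # inverse negative Hessian
    standard_errors: Optional[np.ndarray] = None
    rses: Optional[np.ndarray] = None
    se_message: str = ""

    @property
    def omega(self) -> np.ndarray:
        return self.theta_hat.omega_matrix()

    @property
    def correlation(self) -> np.ndarray:
        return omega_to_correlation(self.omega)

    def to_dict(self) -> dict:
        out = {
            "theta_hat": dict(zip(PARAM_NAMES, self.theta_hat.to_vector())),
            "log_likelihood": self.log_likelihood,
            "omega_matrix": self.omega.tolist(),
            "correlation_matrix": self.correlation.tolist(),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "gradient_norm": float(self.gradient_norm),
            "message": self.message,
        }
        if self.standard_errors is not None:
            out["standard_errors"] = dict(zip(PARAM_NAMES, self.standard_errors))
            out["rse_percent"] = dict(zip(PARAM_NAMES, self.rses))
            out["covariance"] = self.covariance.tolist()
        elif self.se_message:
            out["standard_errors"] = None
            out["se_message"] = self.se_message
        return out


# ---------------------------------------------------------------------------
# packing and single-cell wrappers


def _pack(dataset: "Dataset"):
    """Flatten a dataset into (times, data, offsets) relative to the shift."""
    shift = dataset.program.shift_time
    times, data, offsets = [], [], [0]
    for cell in dataset.cells:
        times.append(np.asarray(cell.times, dtype=float) - shift)
        data.append(np.asarray(cell.intensities, dtype=float))
        offsets.append(offsets[-1] + len(cell.times))
    if not times:
        raise ValueError("dataset holds no cells")
    return (
        np.concatenate(times),
        np.concatenate(data),
        np.asarray(offsets, dtype=np.int64),
    )


def _omega_pieces(theta: PopulationParameters):
    omega = theta.omega_matrix()
    detu = theta.omega[0] * theta.omega[3] * theta.omega[5]
    if abs(detu) < 1e-150:
        raise np.linalg.LinAlgError("Omega factor is singular (zero diagonal entry)")
    return np.linalg.inv(omega), 2.0 * np.log(abs(detu))


def individual_joint_loglik(
    theta: PopulationParameters,
    eta: Sequence[float],
    cell: "CellTimeSeries",
    program: GlucoseProgram,
) -> float:
    """Joint log-likelihood l_i(eta) of one cell's data and its random effects."""
    o_inv, logdet_o = _omega_pieces(theta)
    times = np.asarray(cell.times, dtype=float) - program.shift_time
    return float(
        _kernels.cell_loglik(
            np.asarray(eta, dtype=float),
            times,
            np.asarray(cell.intensities, dtype=float),
            theta.Mbar_s, theta.kbar2, theta.kbar4, theta.s,
            o_inv, logdet_o, program.ratio,
        )
    )


def inner_optimize(
    theta: PopulationParameters,
    cell: "CellTimeSeries",
    program: GlucoseProgram,
    warm_start: Optional[Sequence[float]] = None,
    tol: float = 1e-6,
    maxit: int = 100,
) -> np.ndarray:
    """Conditional mode eta*_i = argmax_eta l_i(eta) for one cell.

    Raises RuntimeError when the damped Gauss-Newton iteration has not
    reached the gradient tolerance within `maxit` iterations.
    """
    o_inv, logdet_o = _omega_pieces(theta)
    eta0 = np.zeros(3) if warm_start is None else np.asarray(warm_start, dtype=float)
    times = np.asarray(cell.times, dtype=float) - program.shift_time
    eta, _l, _jac, grad_norm, converged = _kernels.inner_optimize(
        eta0, times, np.asarray(cell.intensities, dtype=float),
        theta.Mbar_s, theta.kbar2, theta.kbar4, theta.s,
        o_inv, logdet_o, program.ratio, tol, maxit,
    )
    if not converged:
        raise RuntimeError(
            f"inner optimization did not converge (gradient norm {grad_norm:.3e})"
        )
    return eta


def foce_loglik(
    theta: PopulationParameters,
    dataset: "Dataset",
    warm: Optional[np.ndarray] = None,
    config: Optional[FOCEConfig] = None,
) -> float:
    """FOCE approximate population log-likelihood log L_a(theta) of a dataset."""
    config = config or FOCEConfig()
    times, data, offsets = _pack(dataset)
    if warm is None:
        warm = np.zeros((len(dataset.cells), 3))
    value, _ok = _kernels.foce_loglik_dataset(
        theta.to_vector(), times, data, offsets, dataset.program.ratio,
        warm, config.inner_tol, config.inner_maxit,
    )
    if np.isnan(value):
        raise ValueError("invalid theta: noise variance or Omega not usable")
    return float(value)


# ---------------------------------------------------------------------------
# finite differences


def central_gradient(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference gradient with per-coordinate step rel_step*(1+|x_k|)."""
    x = np.asarray(x, dtype=float)
    grad = np.empty_like(x)
    for k in range(x.size):
        h = rel_step * (1.0 + abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        grad[k] = (f(xp) - f(xm)) / (2.0 * h)
    return grad


def central_hessian(f: Callable, x: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Symmetric central-difference Hessian with per-coordinate steps."""
    x = np.asarray(x, dtype=float)
    n = x.size
    hess = np.empty((n, n))
    f0 = f(x)
    for k in range(n):
        hk = steps[k]
        xp, xm = x.copy(), x.copy()
        xp[k] += hk
        xm[k] -= hk
        hess[k, k] = (f(xp) - 2.0 * f0 + f(xm)) / hk**2
    for k in range(n):
        for l in range(k + 1, n):
            hk, hl = steps[k], steps[l]
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[k] += hk; xpp[l] += hl
            xpm[k] += hk; xpm[l] -= hl
            xmp[k] -= hk; xmp[l] += hl
            xmm[k] -= hk; xmm[l] -= hl
            hess[k, l] = hess[l, k] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * hk * hl
            )
    return hess


# ---------------------------------------------------------------------------
# outer estimation


def _transform(vec: np.ndarray) -> np.ndarray:
    z = vec.copy()
    z[_POSITIVE] = np.log(vec[_POSITIVE])
    return z


def _untransform(z: np.ndarray) -> np.ndarray:
    vec = z.copy()
    vec[_POSITIVE] = np.exp(z[_POSITIVE])
    return vec


_PENALTY = 1e12


def fit_population(
    dataset: "Dataset",
    start: Optional[PopulationParameters] = None,
    config: Optional[FOCEConfig] = None,
) -> FOCEFit:
    """Maximize log L_a over theta by BFGS on the log-transformed scale.

    Strictly positive parameters (Mbar_s, kbar2, kbar4, s) are optimized as
    their logarithms and back-transformed; the six Omega-factor entries are
    unconstrained.  The outer gradient uses central finite differences;
    per-cell conditional modes are warm-started between evaluations.  On
    non-convergence the best iterate is returned, flagged.
    """
    start = start or default_start()
    config = config or FOCEConfig()
    times, data, offsets = _pack(dataset)
    n_cells = offsets.size - 1
    r = dataset.program.ratio
    warm = np.zeros((n_cells, 3))
    n_evals = [0]

    def nll(z: np.ndarray) -> float:
        n_evals[0] += 1
        value, _ok = _kernels.foce_loglik_dataset(
            _untransform(z), times, data, offsets, r,
            warm, config.inner_tol, config.inner_maxit,
        )
        if not np.isfinite(value):
            return _PENALTY
        return -value

    def grad(z: np.ndarray) -> np.ndarray:
        return central_gradient(nll, z, config.fd_rel_step)

    z0 = _transform(start.to_vector())
    res = optimize.minimize(
        nll, z0, jac=grad, method="BFGS",
        options={"gtol": config.outer_gtol, "maxiter": config.outer_maxiter},
    )
    theta_hat = PopulationParameters.from_vector(_untransform(res.x))

    # refresh EBEs and the likelihood at the optimum
    final_warm = warm.copy()
    loglik, inner_ok = _kernels.foce_loglik_dataset(
        theta_hat.to_vector(), times, data, offsets, r,
        final_warm, config.inner_tol, config.inner_maxit,
    )
    fit = FOCEFit(
        theta_hat=theta_hat,
        log_likelihood=float(loglik),
        ebes=final_warm,
        cell_ids=[cell.cell_id for cell in dataset.cells],
        program=dataset.program,
        converged=bool(res.success and inner_ok),
        n_iterations=int(res.nit),
        gradient_norm=float(np.linalg.norm(res.jac)),
        message=str(res.message),
    )
    if config.compute_se:
        compute_standard_errors(fit, dataset, config)
    return fit


def compute_standard_errors(
    fit: FOCEFit,
    dataset: "Dataset",
    config: Optional[FOCEConfig] = None,
) -> FOCEFit:
    """Asymptotic SEs from the inverse negative Hessian of log L_a.

    The Hessian is computed by central finite differences directly on the
    untransformed 10-vector (no log transform), so the resulting SEs and
    RSE = 100*|SE/estimate| refer to the original parameterization.  If the
    negative Hessian is not positive definite the SEs are reported as
    unavailable, with a diagnostic message.  Modifies and returns `fit`.
    """
    config = config or FOCEConfig()
    times, data, offsets = _pack(dataset)
    r = dataset.program.ratio
    warm = fit.ebes.copy()

    def logla(vec: np.ndarray) -> float:
        value, _ok = _kernels.foce_loglik_dataset(
            vec, times, data, offsets, r, warm, config.inner_tol, config.inner_maxit
        )
        return value if np.isfinite(value) else -_PENALTY

    vec = fit.theta_hat.to_vector()
    steps = np.maximum(config.hessian_rel_step * np.abs(vec), 1e-6)
    hess = central_hessian(logla, vec, steps)
    fit.hessian = hess
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        fit.se_message = "negative Hessian is singular; SEs unavailable"
        return fit
    diag = np.diag(cov)
    if np.any(diag <= 0):
        fit.se_message = (
            "negative Hessian is not positive definite at the optimum; "
            "SEs unavailable"
        )
        return fit
    fit.covariance = cov
    fit.standard_errors = np.sqrt(diag)
    fit.rses = 100.0 * np.abs(fit.standard_errors / vec)
    return fit


# ---------------------------------------------------------------------------
# generic FOCE for arbitrary observation models (reference path)


def foce_cell_general(
    predict: Callable[[np.ndarray], np.ndarray],
    data: np.ndarray,
    s: float,
    omega: np.ndarray,
    eta0: Optional[np.ndarray] = None,
    tol: float = 1e-9,
    maxit: int = 200,
    fd_step: float = 1e-6,
):
    """FOCE contribution of a single individual for an arbitrary model.

    `predict(eta)` maps the 3-vector of random effects to the expected
    observations.  Implements the same damped Gauss-Newton inner problem and
    first-order Laplace correction as the production kernels, in plain
    NumPy; used for toy models (where the approximation is provably exact)
    and as a cross-check of the compiled path.

    Returns (contribution to log L_a, eta*, l_i(eta*)).
    """
    data = np.asarray(data, dtype=float)
    omega = np.asarray(omega, dtype=float)
    o_inv = np.linalg.inv(omega)
    _sign, logdet_o = np.linalg.slogdet(omega)
    n = data.size
    eta = np.zeros(3) if eta0 is None else np.asarray(eta0, dtype=float)

    def loglik(e):
        eps = data - predict(e)
        return (
            -0.5 * (eps @ eps / s + n * np.log(2.0 * np.pi * s))
            - 0.5 * e @ o_inv @ e
            - 0.5 * (logdet_o + 3.0 * np.log(2.0 * np.pi))
        )

    def jacobian(e, pred0):
        jac = np.empty((n, 3))
        for k in range(3):
            h = fd_step * (1.0 + abs(e[k]))
            ep = e.copy()
            ep[k] += h
            jac[:, k] = (predict(ep) - pred0) / h
        return jac

    l_cur = loglik(eta)
    for _ in range(maxit):
        pred = predict(eta)
        jac = jacobian(eta, pred)
        eps = data - pred
        g = jac.T @ eps / s - o_inv @ eta
        if np.linalg.norm(g) < tol:
            break
        hess = jac.T @ jac / s + o_inv
        lam = 0.0
        for _trial in range(30):
            cand = eta + np.linalg.solve(hess + lam * np.eye(3), g)
            l_new = loglik(cand)
            if l_new > l_cur - 1e-13:
                eta, l_cur = cand, l_new
                break
            lam = 1e-4 if lam == 0.0 else lam * 10.0
        else:
            break
    pred = predict(eta)
    jac = jacobian(eta, pred)
    curv = jac.T @ jac / s + o_inv
    _sign, logdet_curv = np.linalg.slogdet(curv)
    contribution = l_cur - 0.5 * (logdet_curv - 3.0 * np.log(2.0 * np.pi))
    return contribution, eta, l_cur
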