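"""EBE-based diagnostics for a fitted population model.

Covers the empirical-Bayes side of the analysis: tabulating the per-cell
conditional modes (EBEs), eta-shrinkage (the warning signal that individual
data are too weak for EBE-based conclusions), normal-distribution summaries
of EBE scatter with standard-deviation ellipses, and sampling-based RSEs
for the entries of Omega and its correlation matrix, which are nonlinear
functions of several estimated parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .foce import FOCEFit, build_omega, omega_to_correlation

__all__ = [
    "ebe_table",
    "eta_shrinkage",
    "EBESummary",
    "ebe_distribution_summary",
    "omega_uncertainty_sampling",
]


def ebe_table(fit: FOCEFit) -> pd.DataFrame:
    """EBEs as a table with one row per fitted cell (cell_id, eta1..eta3)."""
    return pd.DataFrame(
        {
            "cell_id": fit.cell_ids,
            "eta1": fit.ebes[:, 0],
            "eta2": fit.ebes[:, 1],
            "eta3": fit.ebes[:, 2],
        }
    )


def _ebe_matrix(ebes) -> np.ndarray:
    if isinstance(ebes, FOCEFit):
        return np.asarray(ebes.ebes, dtype=float)
    if isinstance(ebes, pd.DataFrame):
        return ebes[["eta1", "eta2", "eta3"]].to_numpy(dtype=float)
    return np.asarray(ebes, dtype=float)


def eta_shrinkage(ebes, omega: np.ndarray) -> np.ndarray:
    """Per-dimension eta-shrinkage in percent.

    shrinkage_k = 100 * (1 - sd(eta*_k across cells) / sqrt(Omega_kk)),
    with the uncorrected (population) standard deviation of the EBEs.
    Values approaching 100% mean the EBEs have collapsed onto the
    population mode; values above ~20-30% make EBE-based diagnostics
    unreliable.
    """
    mat = _ebe_matrix(ebes)
    if mat.ndim != 2 or mat.shape[1] != 3 or mat.shape[0] < 2:
        raise ValueError("need a (n_cells, 3) EBE array with at least 2 cells")
    omega = np.asarray(omega, dtype=float)
    diag = np.diag(omega)
    if np.any(diag <= 0):
        raise ValueError("Omega diagonal must be positive")
    sd_ebe = mat.std(axis=0, ddof=0)
    return 100.0 * (1.0 - sd_ebe / np.sqrt(diag))


@dataclass(frozen=True)
class EBESummary:
    """Normal-distribution summary of one EBE pair (scatter-plot overlay)."""

    dims: Tuple[int, int]
    mean: np.ndarray                  # (2,)
    covariance: np.ndarray            # (2, 2), uncorrected
    correlation: float
    semi_axes_1sd: np.ndarray         # (2,) principal semi-axis lengths
    semi_axes_2sd: np.ndarray
    orientation: float                # radians, first principal axis vs x
    degenerate: bool


def ebe_distribution_summary(ebes, dims: Tuple[int, int] = (2, 3)) -> EBESummary:
    """Sample moments and 1/2-sd ellipse geometry for a pair of EBE columns.

    `dims` are 1-based random-effect indices (default (2, 3): the pair
    associated with k2 and k4).  The ellipse axes are the square roots of
    the covariance eigenvalues; identical EBEs yield a degenerate summary,
    flagged rather than raised.
    """
    mat = _ebe_matrix(ebes)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 cells for a distribution summary")
    i, j = (d - 1 for d in dims)
    sub = mat[:, [i, j]]
    mean = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, ddof=0)
    var = np.diag(cov)
    degenerate = bool(np.any(var <= 0) or np.linalg.det(cov) <= 0)
    corr = float(cov[0, 1] / np.sqrt(var[0] * var[1])) if not np.any(var <= 0) else np.nan
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(np.maximum(evals, 0.0))
    orientation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EBESummary(
        dims=tuple(dims),
        mean=mean,
        covariance=cov,
        correlation=corr,
        semi_axes_1sd=semi,
        semi_axes_2sd=2.0 * semi,
        orientation=orientation,
        degenerate=degenerate,
    )


def omega_uncertainty_sampling(
    fit: FOCEFit,
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> dict:
    """Sampling-based RSEs for the entries of Omega and its correlation.

    Draws parameter vectors from the asymptotic normal N(theta_hat, cov)
    restricted to the six factor entries, rebuilds Omega = U U' and the
    correlation matrix per draw (PSD by construction, so no rejection
    step), and reports 100*sd/|point estimate| per entry, plus the raw
    sds.  Requires standard errors to have been computed.
    """
    if fit.covariance is None:
        raise ValueError("fit carries no parameter covariance; compute SEs first")
    rng = np.random.default_rng(seed)
    w_hat = np.asarray(fit.theta_hat.omega, dtype=float)
    cov_w = fit.covariance[4:10, 4:10]
    draws = rng.multivariate_normal(w_hat, cov_w, size=int(n_samples), method="svd")

    u = np.zeros((draws.shape[0], 3, 3))
    u[:, 0, 0] = draws[:, 0]
    u[:, 0, 1] = draws[:, 1]
    u[:, 0, 2] = draws[:, 2]
    u[:, 1, 1] = draws[:, 3]
    u[:, 1, 2] = draws[:, 4]
    u[:, 2, 2] = draws[:, 5]
    omegas = u @ u.transpose(0, 2, 1)
    d = np.sqrt(np.diagonal(omegas, axis1=1, axis2=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        corrs = omegas / (d[:, :, None] * d[:, None, :])

    omega_hat = build_omega(w_hat)
    corr_hat = omega_to_correlation(omega_hat)
    sd_omega = omegas.std(axis=0, ddof=0)
    sd_corr = np.nanstd(corrs, axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse_omega = 100.0 * sd_omega / np.abs(omega_hat)
        rse_corr = 100.0 * sd_corr / np.abs(corr_hat)
    rse_omega[sd_omega == 0] = 0.0  # no spread -> no relative uncertainty
    rse_corr[sd_corr == 0] = 0.0
    np.fill_diagonal(rse_corr, 0.0)  # diagonal is identically 1
    return {
        "omega_hat": omega_hat,
        "correlation_hat": corr_hat,
        "sd_omega": sd_omega,
        "sd_correlation": sd_corr,
        "rse_omega": rse_omega,
        "rse_correlation": rse_corr,
        "n_samples": int(n_samples),
    }
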