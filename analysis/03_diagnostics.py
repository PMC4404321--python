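#!/usr/bin/env python
"""EBE diagnostics for the fitted populations.

Reads the per-cell empirical Bayes estimates from 02_fit_nlme.py and, per
experiment: computes eta-shrinkage (should stay well below the 20-30%
feasibility ceiling for 15-observation cells), summarizes the (eta2, eta3)
scatter with 1- and 2-sd normal ellipses, and -- where standard errors
were computed -- derives sampling-based RSEs for the entries of Omega and
its correlation matrix.  Writes results/diagnostics/ and an EBE scatter
figure per experiment.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from mignlme import eta_shrinkage, omega_uncertainty_sampling
from mignlme.diagnostics import ebe_distribution_summary
from mignlme.foce import FOCEFit, PopulationParameters
from mignlme.model import GlucoseProgram

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_fit(exp: int) -> tuple[FOCEFit, pd.DataFrame]:
    blob = json.loads((ROOT / "nlme" / f"exp{exp}_fit.json").read_text())
    ebes = pd.read_csv(ROOT / "nlme" / f"exp{exp}_ebes.csv")
    theta = blob["theta_hat"]
    fit = FOCEFit(
        theta_hat=PopulationParameters(
            theta["Mbar_s"], theta["kbar2"], theta["kbar4"], theta["s"],
            tuple(theta[k] for k in ("w11", "w12", "w13", "w22", "w23", "w33")),
        ),
        log_likelihood=blob["log_likelihood"],
        ebes=ebes[["eta1", "eta2", "eta3"]].to_numpy(),
        cell_ids=ebes["cell_id"].tolist(),
        program=GlucoseProgram(post_level=1.0),
        converged=blob["converged"],
        n_iterations=blob["n_iterations"],
        gradient_norm=blob["gradient_norm"],
    )
    return fit, ebes


def ellipse_points(summary, scale):
    angle = np.linspace(0, 2 * np.pi, 200)
    circ = np.column_stack([np.cos(angle), np.sin(angle)])
    rot = np.array([[np.cos(summary.orientation), -np.sin(summary.orientation)],
                    [np.sin(summary.orientation), np.cos(summary.orientation)]])
    pts = circ * (scale * summary.semi_axes_1sd) @ rot.T
    return pts + summary.mean


def main() -> None:
    out = ROOT / "diagnostics"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for exp in (1, 2, 3, 4):
        fit, ebes = load_fit(exp)
        shrink = eta_shrinkage(fit, fit.omega)
        rows.append({"experiment": exp,
                     **{f"eta{k + 1}_shrinkage_pct": round(float(v), 1)
                        for k, v in enumerate(shrink)}})
        summ = ebe_distribution_summary(fit, dims=(2, 3))
        print(f"exp {exp}: shrinkage {np.round(shrink, 1)} %, "
              f"EBE corr(eta2,eta3) = {summ.correlation:.2f}")

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ebes["eta2"], ebes["eta3"], s=12, c="crimson", zorder=3)
        for scale, alpha in ((1, 0.35), (2, 0.2)):
            ax.fill(*ellipse_points(summ, scale).T, color="grey", alpha=alpha, lw=0)
            pop = ebe_distribution_summary(
                np.random.default_rng(0).multivariate_normal(
                    [0, 0, 0], fit.omega, 20000), dims=(2, 3))
            ax.plot(*ellipse_points(pop, scale).T, color="black", lw=1)
        ax.set_xlabel(r"$\eta_2$ (k2)")
        ax.set_ylabel(r"$\eta_3$ (k4)")
        ax.set_title(f"experiment {exp} EBEs")
        fig.tight_layout()
        fig.savefig(out / f"exp{exp}_ebe_scatter.png", dpi=120)
        plt.close(fig)

        blob = json.loads((ROOT / "nlme" / f"exp{exp}_fit.json").read_text())
        if blob.get("covariance"):
            fit.covariance = np.asarray(blob["covariance"])
            unc = omega_uncertainty_sampling(fit, n_samples=100_000, seed=17)
            (out / f"exp{exp}_omega_rse.json").write_text(json.dumps(
                {k: np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
                 for k, v in unc.items()}, indent=1))
            print(f"  Omega RSEs (%):\n{np.round(unc['rse_omega'], 0)}")
    pd.DataFrame(rows).to_csv(out / "shrinkage.csv", index=False)
    print(f"wrote diagnostics to {out}")


if __name__ == "__main__":
    main()
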