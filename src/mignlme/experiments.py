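"""The four glucose-shift experiments and their reported population fits.

Each experiment followed ~50 cells through an instantaneous downshift of
extracellular glucose from 4% to an intermediate level, sampling nuclear
Mig1-GFP intensity up to 15 times per cell over about 20 minutes.  The
published FOCE estimates of the population parameters (medians, noise
variance, and the six entries of the upper-triangular factor of the
random-effect covariance) are recorded here; they drive the Monte-Carlo
prediction stage and serve as realistic ground truth for the synthetic
data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .foce import PopulationParameters
from .model import GlucoseProgram

__all__ = ["ExperimentInfo", "EXPERIMENTS", "experiment_info", "reported_fit"]


@dataclass(frozen=True)
class ExperimentInfo:
    """Design and reported population estimate for one glucose-shift dataset."""

    number: int
    n_cells: int
    glucose_pre: float
    glucose_post: float
    reported: PopulationParameters

    @property
    def program(self) -> GlucoseProgram:
        return GlucoseProgram(post_level=self.glucose_post, pre_level=self.glucose_pre)


EXPERIMENTS = {
    1: ExperimentInfo(
        number=1,
        n_cells=56,
        glucose_pre=4.0,
        glucose_post=1.5,
        reported=PopulationParameters(
            Mbar_s=3.27e3,
            kbar2=0.00579,
            kbar4=0.00846,
            s=8.73e3,
            omega=(0.0653, 0.0391, 47.5e-6, 0.231, 0.0398, 0.255),
        ),
    ),
    2: ExperimentInfo(
        number=2,
        n_cells=46,
        glucose_pre=4.0,
        glucose_post=1.5,
        reported=PopulationParameters(
            Mbar_s=3.36e3,
            kbar2=0.00473,
            kbar4=0.00971,
            s=38.1e3,
            omega=(0.0712, 0.0447, -0.0377, 0.144, 0.193, 0.439),
        ),
    ),
    3: ExperimentInfo(
        number=3,
        n_cells=46,
        glucose_pre=4.0,
        glucose_post=1.0,
        reported=PopulationParameters(
            Mbar_s=3.64e3,
            kbar2=0.00592,
            kbar4=0.00999,
            s=20.8e3,
            omega=(0.0624, 0.0568, -0.0649, 0.313, 0.526, 0.567),
        ),
    ),
    4: ExperimentInfo(
        number=4,
        n_cells=46,
        glucose_pre=4.0,
        glucose_post=0.5,
        reported=PopulationParameters(
            Mbar_s=3.14e3,
            kbar2=0.00815,
            kbar4=0.0229,
            s=24.1e3,
            omega=(0.0228, 0.0691, -0.0322, 0.252, 0.281, 0.432),
        ),
    ),
}


def experiment_info(number: int) -> ExperimentInfo:
    try:
        return EXPERIMENTS[number]
    except KeyError:
        raise ValueError(f"unknown experiment id: {number!r} (expected 1-4)") from None


def reported_fit(number: int) -> PopulationParameters:
    """Published population-parameter estimates for experiment 1-4."""
    return experiment_info(number).reported
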