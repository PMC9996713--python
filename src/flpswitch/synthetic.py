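"""Synthetic four-condition time-course generator with known ground truth.

The generator emulates the statistical shape of the experimental readout the
inference stages assume: four series (ON and OFF switch, each at 0 and 1 uM
4-OHT) of ten percent-CAR values over a ten-day window, normalised to the
global maximum across all series, with additive observation noise clipped to
[0, 100].  Because the study's measured values are not machine-readable and
its fitted constants are not published in the available text, the shipped
ground truth is a *synthetic* parameter set chosen for the qualitative shape
of the real data: under induction the ON switch rises to a high plateau and
the OFF switch falls correspondingly, while the uninduced series show a small
basal drift from leaky nuclear localisation.  Changing the shipped truth is a
breaking change gated by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import TimeCourseDataset
from .ga import DEFAULT_DOSE_MAP, simulate_datasets
from .observables import DoseCondition, SolverConfig, normalize_to_global_max
from .reduced import ReducedParameters

__all__ = ["SyntheticConfig", "generate_datasets", "default_truth",
           "noiseless_datasets"]

#: synthetic ground truth (all fitted values inside the [0, 1] search box);
#: NOT the study's fitted constants, which are unavailable
_DEFAULT_TRUTH = dict(
    alpha_a=0.90,   # strong constitutive FlpO expression
    alpha_b=0.20,   # leak-pathway expression driving basal switching
    beta_p=0.03,    # slow recombinase turnover
    beta_d=0.70,    # inducer cleared in ~1.4 days
    K_a=0.90,       # efficient 4-OHT-dependent nuclear import
    K_b=0.25,       # leaky nuclear import
    k1=0.90, k2=0.80,   # fast forward inversions
    k3=0.06, k4=0.05,   # slow locking excisions
    k_r=0.15,       # shared reverse recombination; sets the induced plateau
    delta=0.10,     # excised-loop dilution
)


def default_truth() -> ReducedParameters:
    """The fixed, versioned synthetic ground-truth parameter set."""
    return ReducedParameters(**_DEFAULT_TRUTH)


@dataclass(frozen=True)
class SyntheticConfig:
    truth: ReducedParameters = field(default_factory=default_truth)
    doses_uM: tuple[float, ...] = (0.0, 1.0)
    days: tuple[float, ...] = tuple(float(d) for d in range(1, 11))
    noise_sd: float = 3.0            # percentage points
    seed: int = 0
    apply_global_max_normalization: bool = True
    dose_map: DoseCondition = DEFAULT_DOSE_MAP

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(d < 0 or d > 10 for d in self.days):
            raise ValueError("observation days must lie within [0, 10]")


def noiseless_datasets(truth: ReducedParameters,
                       doses_uM=(0.0, 1.0),
                       days=tuple(float(d) for d in range(1, 11)),
                       dose_map: DoseCondition = DEFAULT_DOSE_MAP,
                       solver: SolverConfig | None = None
                       ) -> list[TimeCourseDataset]:
    """Exact model output at the observation days, one dataset per condition."""
    days = np.asarray(days, dtype=float)
    skeleton = [TimeCourseDataset(orientation, dose, days, np.zeros_like(days))
                for dose in doses_uM for orientation in ("ON", "OFF")]
    preds = simulate_datasets(truth, skeleton, dose_map, solver)
    return [d.with_values(np.clip(p, 0.0, 100.0))
            for d, p in zip(skeleton, preds)]


def generate_datasets(config: SyntheticConfig | None = None
                      ) -> tuple[list[TimeCourseDataset], dict]:
    """Simulate the truth, add Gaussian observation noise, clip and normalise.

    Returns the four datasets and a ground-truth record (parameters, seed,
    noise level) for parameter-recovery tests.  The truth must be simulable;
    a solver failure propagates as an error.
    """
    config = config or SyntheticConfig()
    clean = noiseless_datasets(config.truth, config.doses_uM, config.days,
                               config.dose_map)
    rng = np.random.default_rng(config.seed)
    noisy = []
    for d in clean:
        values = d.percent_car + rng.normal(0.0, config.noise_sd,
                                            size=len(d)) if config.noise_sd > 0 \
            else d.percent_car.copy()
        noisy.append(d.with_values(np.clip(values, 0.0, 100.0)))
    if config.apply_global_max_normalization:
        noisy = normalize_to_global_max(noisy)
    truth_record = {
        "parameters": config.truth.to_dict(),
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "doses_uM": list(config.doses_uM),
        "days": list(config.days),
        "normalized": config.apply_global_max_normalization,
    }
    return noisy, truth_record
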