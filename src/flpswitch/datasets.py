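"""Time-course dataset container shared by generation, I/O and inference."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ORIENTATIONS", "TimeCourseDataset"]

ORIENTATIONS = ("ON", "OFF")


@dataclass(frozen=True)
class TimeCourseDataset:
    """One observed or synthetic percent-CAR series for a (switch, dose) condition.

    ``orientation`` is "ON" (expression rises under induction) or "OFF"
    (the mirrored construct: expression falls). ``days`` and ``percent_car``
    are equal-length; percentages live on [0, 100].
    """

    orientation: str
    dose_uM: float
    days: np.ndarray
    percent_car: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "days", np.asarray(self.days, dtype=float))
        object.__setattr__(self, "percent_car",
                           np.asarray(self.percent_car, dtype=float))
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.dose_uM < 0:
            raise ValueError("dose_uM must be >= 0")
        if self.days.ndim != 1 or self.days.shape != self.percent_car.shape:
            raise ValueError("days and percent_car must be equal-length 1-D arrays")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.percent_car < 0) or np.any(self.percent_car > 100):
            raise ValueError("percent_car values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def key(self) -> tuple[str, float]:
        return (self.orientation, self.dose_uM)

    def with_values(self, percent_car) -> "TimeCourseDataset":
        return TimeCourseDataset(self.orientation, self.dose_uM, self.days,
                                 np.asarray(percent_car, dtype=float))
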