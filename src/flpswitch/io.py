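"""File I/O, run configuration and provenance helpers.

Time courses travel as tidy CSV (columns: switch, dose_uM, day, percent_car);
fit results as JSON carrying seed, config hash and package version; ABC runs
as one particles CSV per threshold plus an acceptance-log CSV (epsilon,
particles assessed, acceptance percent).  Config files are flat YAML with
unknown keys rejected, and the config hash changes iff the content does.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .abc_smc import ABCConfig, ABCResult
from .datasets import ORIENTATIONS, TimeCourseDataset
from .ga import FitResult, GAConfig
from .reduced import FITTED_PARAMETER_NAMES

__all__ = ["read_timecourses", "write_timecourses", "write_fit_result",
           "read_fit_result", "write_abc_result", "write_records_csv",
           "config_hash", "RunConfig", "load_run_config"]

TIMECOURSE_COLUMNS = ("switch", "dose_uM", "day", "percent_car")


def read_timecourses(path, expected_points: int | None = 10
                     ) -> list[TimeCourseDataset]:
    """Load and validate the four (orientation x dose) series from tidy CSV."""
    df = pd.read_csv(path)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[(df["percent_car"] < 0) | (df["percent_car"] > 100)]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: percent_car outside [0, 100] at lines {lines}")
    bad_switch = df[~df["switch"].isin(ORIENTATIONS)]
    if len(bad_switch):
        lines = (bad_switch.index + 2).tolist()
        raise ValueError(f"{path}: unknown switch value at lines {lines}")
    datasets = []
    for (switch, dose), grp in df.groupby(["switch", "dose_uM"], sort=True):
        grp = grp.sort_values("day")
        if expected_points is not None and len(grp) != expected_points:
            raise ValueError(
                f"{path}: series ({switch}, {dose} uM) has {len(grp)} points, "
                f"expected {expected_points}")
        datasets.append(TimeCourseDataset(
            switch, float(dose), grp["day"].to_numpy(),
            grp["percent_car"].to_numpy()))
    orientations = {d.orientation for d in datasets}
    doses = {d.dose_uM for d in datasets}
    if len(datasets) != 4 or len(orientations) != 2 or len(doses) != 2:
        present = sorted(d.key for d in datasets)
        expected = [(o, dd) for o in sorted(orientations or ORIENTATIONS)
                    for dd in sorted(doses or {0.0, 1.0})]
        absent = [k for k in expected if k not in present]
        raise ValueError(
            f"{path}: expected 4 series covering 2 switches x 2 doses; "
            f"missing {absent or 'combinations'}; present {present}")
    return sorted(datasets, key=lambda d: (d.dose_uM, d.orientation))


def write_timecourses(datasets: Sequence[TimeCourseDataset], path) -> None:
    rows = [{"switch": d.orientation, "dose_uM": d.dose_uM,
             "day": day, "percent_car": v}
            for d in datasets for day, v in zip(d.days, d.percent_car)]
    pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS)).to_csv(path, index=False)


def config_hash(config) -> str:
    """Stable short hash of a config object's content."""
    if hasattr(config, "__dataclass_fields__"):
        config = asdict(config)
    blob = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _version() -> str:
    from . import __version__
    return __version__


def write_fit_result(result: FitResult, path, config: GAConfig | None = None
                     ) -> None:
    payload = {
        "parameters": {n: result.parameters[n] for n in FITTED_PARAMETER_NAMES},
        "error": result.error,
        "per_dataset_error": {f"{k[0]}@{k[1]}uM": v
                              for k, v in result.per_dataset_error.items()},
        "n_evaluations": result.n_evaluations,
        "seed": result.seed,
        "config_hash": config_hash(config) if config is not None else None,
        "package_version": _version(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_fit_result(path) -> dict:
    return json.loads(Path(path).read_text())


def write_abc_result(result: ABCResult, outdir,
                     config: ABCConfig | None = None) -> None:
    """One particles CSV per threshold plus the acceptance-log CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, pop in enumerate(result.populations, start=1):
        df = pd.DataFrame(pop.particles, columns=list(FITTED_PARAMETER_NAMES))
        df.insert(0, "weight", pop.weights)
        df.insert(1, "error", pop.errors)
        df.to_csv(outdir / f"population_{i:02d}.csv", index=False)
    log = pd.DataFrame(result.log_table())
    log.to_csv(outdir / "acceptance_log.csv", index=False)
    meta = {
        "converged": result.converged,
        "stalled_epsilon": result.stalled_epsilon,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": config.seed if config is not None else None,
        "package_version": _version(),
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_records_csv(records: list[dict], path) -> None:
    """Write any scan's ``to_records()`` output as a tidy CSV."""
    pd.DataFrame(records).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration (flat YAML; unknown keys rejected)."""

    model: str = "reduced"
    seed: int = 0
    alpha_d_at_1uM: float = 1.0
    oht0_at_1uM: float = 0.0
    rtol: float = 1e-7
    atol: float = 1e-9
    noise_sd: float = 3.0
    normalize: bool = True
    ga: dict = field(default_factory=dict)
    abc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("reduced", "mechanistic"):
            raise ValueError("model must be 'reduced' or 'mechanistic'")


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
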