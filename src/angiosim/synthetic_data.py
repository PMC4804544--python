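"""Xenograft-like synthetic observation series.

Real mouse-xenograft efficacy studies measure tumour volume by caliper
roughly twice a week in cohorts of 3-10 animals and report the group
mean +- SD, with volumes spanning ~50-3000 mm^3 over a few weeks.  This
module emulates that structure on top of the simulator: one ground-truth
parameter set per arm (the ODE model assumes a homogeneous cohort),
multiplicative lognormal measurement noise per animal and timepoint —
caliper error scales with tumour size and volumes must stay positive — and
per-time mean/SD summaries.  It exists so that simulation and calibration
can be exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import GrowthParams, TumourState
from .fitting import REFERENCE_V0_OVER_K0, ObservationSeries
from .pharmacokinetics import PkParams, Regimen, build_regimen
from .simulation import SolverOptions, simulate

__all__ = [
    "SyntheticSpec",
    "generate_series",
    "make_regimen",
    "write_series",
    "read_series",
    "TWICE_WEEKLY_DAYS",
]

#: Nine twice-weekly administrations over four weeks, the reference schedule.
TWICE_WEEKLY_DAYS = (1.0, 4.0, 8.0, 11.0, 15.0, 18.0, 22.0, 25.0, 29.0)

#: Default infusion duration: a 30-minute intravenous infusion, in days.
DEFAULT_INFUSION_DURATION = 1.0 / 48.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic observation arm.

    truth: the generating growth parameters; v0: initial volume (mm^3,
    k0 defaults to v0 / (200/625)); regimen: dosing schedule for a treated
    arm (None for control); obs_times: measurement days; n_animals: cohort
    size; noise_cv: coefficient of variation of the multiplicative
    lognormal measurement noise; seed: RNG seed making the arm
    reproducible.
    """

    truth: GrowthParams
    obs_times: tuple[float, ...]
    v0: float = 200.0
    k0: Optional[float] = None
    regimen: Optional[Regimen] = None
    pk: Optional[PkParams] = None
    n_animals: int = 10
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        times = tuple(float(t) for t in self.obs_times)
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])) or not times:
            raise ValueError("obs_times must be non-empty and strictly increasing")
        object.__setattr__(self, "obs_times", times)
        if self.regimen is not None and self.pk is None:
            object.__setattr__(self, "pk", PkParams())

    @property
    def initial_state(self) -> TumourState:
        k0 = self.k0 if self.k0 is not None else self.v0 / REFERENCE_V0_OVER_K0
        return TumourState(V=self.v0, K=k0)


def generate_series(
    spec: SyntheticSpec, opts: Optional[SolverOptions] = None
) -> ObservationSeries:
    """Simulate the truth and summarise noisy per-animal measurements.

    Each animal's measurement at each time is the truth volume times a
    lognormal factor with unit mean and coefficient of variation
    `noise_cv`; the series reports the per-time cohort mean and SD
    (ddof=1; SDs are zero when noise_cv is 0 or n_animals is 1).
    """
    span = (0.0, float(spec.obs_times[-1]))
    traj = simulate(
        spec.truth,
        spec.initial_state,
        span,
        regimen=spec.regimen,
        pk=spec.pk,
        opts=opts,
    )
    truth_volumes = np.interp(spec.obs_times, traj.times, traj.V)

    if spec.noise_cv == 0.0:
        means = truth_volumes
        sds = np.zeros_like(truth_volumes)
    else:
        rng = np.random.default_rng(spec.seed)
        # lognormal with unit mean: sigma^2 = ln(1 + cv^2), mu = -sigma^2/2
        sigma2 = np.log1p(spec.noise_cv**2)
        factors = rng.lognormal(
            mean=-sigma2 / 2.0,
            sigma=np.sqrt(sigma2),
            size=(spec.n_animals, len(truth_volumes)),
        )
        samples = truth_volumes[None, :] * factors
        means = samples.mean(axis=0)
        sds = (
            samples.std(axis=0, ddof=1)
            if spec.n_animals > 1
            else np.zeros_like(truth_volumes)
        )
    return ObservationSeries(
        times=np.asarray(spec.obs_times),
        volumes=means,
        sds=sds,
        group="control" if spec.regimen is None else "treatment",
        regimen=spec.regimen,
    )


def make_regimen(
    dosage: float,
    weight: float = 0.025,
    days: Sequence[float] = TWICE_WEEKLY_DAYS,
    duration: float = DEFAULT_INFUSION_DURATION,
) -> Regimen:
    """Dosing schedule with absolute dose = dosage (mg/kg) x weight (kg)
    at each administration day; duration is the infusion length in days."""
    return build_regimen(dosage=dosage, weight=weight, days=days, duration=duration)


def write_series(path: Union[str, Path], series: ObservationSeries) -> None:
    """Write a series as CSV with columns time_day, volume_mm3[, sd_mm3]."""
    data = {"time_day": series.times, "volume_mm3": series.volumes}
    if series.sds is not None:
        data["sd_mm3"] = series.sds
    pd.DataFrame(data).to_csv(path, index=False)


def read_series(
    path: Union[str, Path],
    group: str = "control",
    regimen: Optional[Regimen] = None,
) -> ObservationSeries:
    """Read an observation CSV (time_day, volume_mm3, optional sd_mm3).

    Malformed rows are reported with their line number; a missing sd
    column reads as absent SDs.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_day", "volume_mm3"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    for col in df.columns:
        bad = df[df[col].isna()]
        if not bad.empty:
            lineno = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(f"{path}:{lineno}: missing value in column {col!r}")
    return ObservationSeries(
        times=df["time_day"].to_numpy(float),
        volumes=df["volume_mm3"].to_numpy(float),
        sds=df["sd_mm3"].to_numpy(float) if "sd_mm3" in df.columns else None,
        group=group,
        regimen=regimen,
    )
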