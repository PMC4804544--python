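"""Two-stage local least-squares calibration against tumour-volume series.

Stage one fits the free-growth model to the control arm of an experiment
over (lambda1, c, d, K0) by bounded nonlinear least squares (trust-region
reflective).  Stage two fits the treatment model to a treated arm over
(lambda1, c, beta, p, K0), holding d at the control estimate — endogenous
angiogenesis inhibition is assumed unaffected by an anti-VEGF agent — and
capping lambda1 at the control estimate so the fit can only express a
direct antitumour effect, never an accelerated intrinsic growth rate.
Initial points follow the reference parameter set (control stage) and the
control estimates (treatment stage); the initial carrying capacity is tied
to the first observed volume through the reference V0/K0 ratio.

The cost is the plain model-minus-observed residual at each observation
time.  Reported diagnostics: RMSE (dividing by the number of observations),
NRMSE (RMSE over the observed range, in percent) and the first-order
optimality measure (infinity norm of the projected gradient at the
solution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model_core import GrowthParams, TumourState
from .pharmacokinetics import PkParams, Regimen
from .simulation import SimulationError, SolverOptions, simulate

__all__ = [
    "ObservationSeries",
    "FitConfig",
    "FitResult",
    "residuals",
    "fit_control",
    "fit_treatment",
    "fit_dose_chain",
    "goodness_of_fit",
]

#: Reference V0/K0 ratio (200/625) used to seed the initial carrying capacity.
REFERENCE_V0_OVER_K0 = 200.0 / 625.0

#: Free parameters of each fitting stage, in optimisation order.
CONTROL_FREE = ("lambda1", "c", "d", "K0")
TREATMENT_FREE = ("lambda1", "c", "beta", "p", "K0")

# c must stay strictly positive (the growth model rejects c <= 0); this is
# the smallest value the solver may reach in place of the paper's plain
# non-negativity bound.
_C_FLOOR = 1e-10

#: Solver settings for fits: slightly looser than the simulation default,
#: still far below observational noise, and ~4x faster per evaluation.
FIT_SOLVER_OPTIONS = SolverOptions(rel_tol=1e-7, abs_tol=1e-9)


@dataclass(frozen=True)
class ObservationSeries:
    """A tumour-volume time series (the unit of fitting).

    times in days, volumes (group means) in mm^3, sds optional per-time
    standard deviations; a treatment-group series carries the regimen that
    produced it.
    """

    times: np.ndarray
    volumes: np.ndarray
    sds: Optional[np.ndarray] = None
    group: str = "control"
    regimen: Optional[Regimen] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if self.sds is not None:
            object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if times.ndim != 1 or times.shape != volumes.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(volumes <= 0):
            raise ValueError("volumes must be positive")
        if self.group not in ("control", "treatment"):
            raise ValueError(f"group must be 'control' or 'treatment' (got {self.group!r})")
        if self.group == "treatment" and self.regimen is None:
            raise ValueError("a treatment series must carry its regimen")

    @property
    def v0(self) -> float:
        """First observed volume, used as the fixed initial tumour volume."""
        return float(self.volumes[0])


@dataclass(frozen=True)
class FitConfig:
    """Knobs of one least-squares stage.

    All mappings are keyed by parameter name; entries missing from
    `initial_point` / bounds fall back to the stage defaults.  With
    `sd_weighted` the residuals are divided by the observation SDs
    (default off: the plain unweighted cost).
    """

    free_parameters: tuple[str, ...] = ()
    initial_point: dict[str, float] = field(default_factory=dict)
    lower_bounds: dict[str, float] = field(default_factory=dict)
    upper_bounds: dict[str, float] = field(default_factory=dict)
    function_tolerance: float = 1e-6
    sd_weighted: bool = False
    prescan: bool = False
    solver_options: SolverOptions = FIT_SOLVER_OPTIONS


@dataclass(frozen=True)
class FitResult:
    """Estimates and goodness of fit of one least-squares stage."""

    estimates: dict[str, float]
    rmse: float
    nrmse: float  # percent of the observed range; NaN for a zero range
    foo: float  # first-order optimality (projected-gradient infinity norm)
    converged: bool
    residuals: np.ndarray
    series: ObservationSeries = field(repr=False, compare=False, default=None)

    @property
    def v0_over_k0(self) -> float:
        """Fitted initial-state ratio, used to seed the treatment stage."""
        return self.series.v0 / self.estimates["K0"]


def _params_from_candidate(
    candidate: dict[str, float], fixed: GrowthParams
) -> tuple[GrowthParams, float]:
    """Split a candidate into GrowthParams overrides and the initial K0."""
    k0 = candidate["K0"]
    overrides = {k: v for k, v in candidate.items() if k != "K0"}
    return replace(fixed, **overrides), k0


def residuals(
    candidate: dict[str, float],
    series: ObservationSeries,
    fixed: GrowthParams,
    pk: Optional[PkParams] = None,
    opts: Optional[SolverOptions] = None,
) -> np.ndarray:
    """Model-minus-observed volumes (mm^3) at the observation times.

    The simulation starts at the first observation time from
    (V0 = first observed volume, K0 = candidate K0) and, for a treatment
    series, is driven by the series' regimen.
    """
    opts = opts or FIT_SOLVER_OPTIONS
    params, k0 = _params_from_candidate(candidate, fixed)
    v0 = series.v0
    if k0 <= params.v_star or v0 <= params.v_star:
        raise SimulationError(
            f"candidate {candidate} puts the initial state outside the vascular regime"
        )
    span = (float(series.times[0]), float(series.times[-1]))
    try:
        traj = simulate(
            params,
            TumourState(V=v0, K=k0),
            span,
            regimen=series.regimen,
            pk=pk,
            opts=opts,
        )
    except SimulationError as exc:
        raise SimulationError(f"simulation failed for candidate {candidate}: {exc}") from exc
    model = np.interp(series.times, traj.times, traj.V)
    return model - series.volumes


def goodness_of_fit(
    res: np.ndarray, series: ObservationSeries, foo: float = math.nan
) -> tuple[float, float, float]:
    """(RMSE mm^3, NRMSE percent of observed range, first-order optimality)."""
    res = np.asarray(res, dtype=float)
    rmse = float(np.sqrt(np.mean(res**2)))
    vrange = float(series.volumes.max() - series.volumes.min())
    nrmse = 100.0 * rmse / vrange if vrange > 0 else math.nan
    return rmse, nrmse, foo


def _run_stage(
    series: ObservationSeries,
    free: Sequence[str],
    x0: dict[str, float],
    lower: dict[str, float],
    upper: dict[str, float],
    fixed: GrowthParams,
    pk: Optional[PkParams],
    config: FitConfig,
) -> FitResult:
    """Shared bounded trust-region-reflective driver for both stages."""
    if len(series.times) < len(free):
        import warnings

        warnings.warn(
            f"{len(series.times)} observations for {len(free)} free parameters: "
            "the fit is under-determined",
            stacklevel=3,
        )
    names = tuple(free)
    x0_vec = np.array([x0[n] for n in names])
    lo = np.array([lower[n] for n in names])
    hi = np.array([upper[n] for n in names])
    if np.any(x0_vec < lo) or np.any(x0_vec > hi):
        raise ValueError(f"initial point {x0} outside bounds")

    weights = None
    if config.sd_weighted:
        if series.sds is None:
            raise ValueError("sd_weighted requires a series with SDs")
        weights = np.where(series.sds > 0, series.sds, 1.0)

    def vector_residuals(x: np.ndarray) -> np.ndarray:
        candidate = {**x0, **dict(zip(names, x))}
        r = residuals(candidate, series, fixed, pk=pk, opts=config.solver_options)
        return r / weights if weights is not None else r

    if config.prescan:
        x0_vec = _coarse_prescan(vector_residuals, x0_vec, lo, hi)

    sol = least_squares(
        vector_residuals,
        x0_vec,
        bounds=(lo, hi),
        method="trf",
        ftol=config.function_tolerance,
        xtol=1e-10,
        gtol=1e-10,
    )
    estimates = {**x0, **dict(zip(names, sol.x))}
    raw = residuals(estimates, series, fixed, pk=pk, opts=config.solver_options)
    rmse, nrmse, foo = goodness_of_fit(raw, series, foo=float(sol.optimality))
    return FitResult(
        estimates=estimates,
        rmse=rmse,
        nrmse=nrmse,
        foo=foo,
        converged=bool(sol.success),
        residuals=raw,
        series=series,
    )


def _coarse_prescan(fun, x0: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Deterministic one-at-a-time grid scan replacing manual initial-point
    tuning: each free parameter tries x0 scaled by {1/4, 1/2, 1, 2, 4}
    (clipped to bounds) and keeps the best, in a fixed parameter order."""
    best = x0.copy()
    best_cost = 0.5 * float(np.sum(fun(best) ** 2))
    for i in range(len(x0)):
        for factor in (0.25, 0.5, 2.0, 4.0):
            trial = best.copy()
            trial[i] = np.clip(x0[i] * factor, lo[i], hi[i])
            try:
                cost = 0.5 * float(np.sum(fun(trial) ** 2))
            except SimulationError:
                continue
            if cost < best_cost:
                best, best_cost = trial, cost
    return best


def fit_control(
    series: ObservationSeries,
    config: Optional[FitConfig] = None,
    reference: Optional[GrowthParams] = None,
) -> FitResult:
    """Stage one: fit (lambda1, c, d, K0) to a control series.

    Defaults: initial lambda1/c/d from the reference parameter set, initial
    K0 tied to V0 by the reference 200/625 ratio, lower bounds 0 except
    K0 >= V0 (an untreated growth curve must not start by shrinking).
    """
    if series.group != "control":
        raise ValueError("fit_control expects a control-group series")
    config = config or FitConfig()
    reference = reference or GrowthParams()
    v0 = series.v0
    x0 = {
        "lambda1": reference.lambda1,
        "c": reference.c,
        "d": reference.d,
        "K0": v0 / REFERENCE_V0_OVER_K0,
        **config.initial_point,
    }
    lower = {
        "lambda1": 0.0, "c": _C_FLOOR, "d": 0.0, "K0": v0,
        **config.lower_bounds,
    }
    upper = {
        "lambda1": np.inf, "c": np.inf, "d": np.inf, "K0": np.inf,
        **config.upper_bounds,
    }
    free = config.free_parameters or CONTROL_FREE
    return _run_stage(series, free, x0, lower, upper, reference, None, config)


def fit_treatment(
    series: ObservationSeries,
    control_fit: FitResult,
    pk: PkParams,
    config: Optional[FitConfig] = None,
    warm_start: Optional[FitResult] = None,
) -> FitResult:
    """Stage two: fit (lambda1, c, beta, p, K0) to a treated series.

    d stays fixed at the control estimate; lambda1 is bounded above by the
    control estimate; beta/p start from the reference treatment values
    (1, 0); K0 starts from the control-arm V0/K0 ratio and is freed only
    when the first observation coincides with the first dose (otherwise
    the pre-treatment carrying capacity is not separately observable and
    K0 stays at its seeded value).  For multi-dose-level protocols pass the
    next-lower dose level's result as `warm_start`: its lambda1, c, beta
    and p seed the initial point.
    """
    if series.group != "treatment":
        raise ValueError("fit_treatment expects a treatment-group series")
    if not control_fit.converged:
        raise ValueError("the control-stage fit did not converge")
    config = config or FitConfig()
    v0 = series.v0

    source = warm_start or control_fit
    x0 = {
        "lambda1": source.estimates["lambda1"],
        "c": source.estimates["c"],
        "beta": source.estimates.get("beta", 1.0),
        "p": source.estimates.get("p", 0.0),
        "K0": v0 / control_fit.v0_over_k0,
        **config.initial_point,
    }
    lam1_cap = control_fit.estimates["lambda1"]
    x0["lambda1"] = min(x0["lambda1"], lam1_cap)
    lower = {
        "lambda1": 0.0, "c": _C_FLOOR, "beta": 0.0, "p": 0.0, "K0": v0,
        **config.lower_bounds,
    }
    upper = {
        "lambda1": lam1_cap, "c": np.inf, "beta": np.inf, "p": np.inf,
        "K0": np.inf, **config.upper_bounds,
    }
    # d (and alpha, v_star, lambda2) come from here; everything else is
    # overridden by the candidate at each evaluation.
    fixed = replace(GrowthParams(), d=control_fit.estimates["d"])

    free = config.free_parameters
    if not free:
        free = TREATMENT_FREE
        first_dose = series.regimen.events[0].t_D if series.regimen.events else None
        if first_dose is None or not math.isclose(
            series.times[0], first_dose, abs_tol=1e-9
        ):
            free = tuple(n for n in free if n != "K0")
    return _run_stage(series, free, x0, lower, upper, fixed, pk, config)


def fit_dose_chain(
    control: ObservationSeries,
    treatments: Sequence[ObservationSeries],
    pk: PkParams,
    control_config: Optional[FitConfig] = None,
    treatment_config: Optional[FitConfig] = None,
) -> tuple[FitResult, list[FitResult]]:
    """Fit a control arm, then each treatment arm ordered by dose level,
    warm-starting every arm from the nearest lower dose level's result."""
    control_fit = fit_control(control, config=control_config)
    results: list[FitResult] = []
    warm: Optional[FitResult] = None
    for series in treatments:
        fit = fit_treatment(
            series, control_fit, pk, config=treatment_config, warm_start=warm
        )
        results.append(fit)
        warm = fit
    return control_fit, results
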