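"""Numerical integration of the coupled growth + pharmacokinetic system.

The growth ODEs are integrated with an adaptive Runge-Kutta scheme
(``scipy.integrate.solve_ivp``, RK45) driven by the plasma concentration of
the antiangiogenic agent.  The bi-exponential forcing is discontinuous in
slope at every infusion start and end, so the integration is restarted at
each such breakpoint; within a segment the right-hand side is smooth.  The
dense solution is then sampled onto a uniform output grid (0.1 day by
default), on which plateau detection and the treatment-effect endpoints
operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    DOMAIN_FLOOR,
    DomainError,
    GrowthParams,
    TumourState,
    _abnormality,
    _stimulation,
)
from .pharmacokinetics import (
    PLASMA_DENSITY_KG_PER_ML,
    PkParams,
    Regimen,
    hybrid_constants,
    regimen_concentration,
    to_growth_units,
)

__all__ = [
    "SolverOptions",
    "Trajectory",
    "PlateauResult",
    "SimulationError",
    "simulate",
    "detect_plateau",
    "growth_inhibition",
    "growth_delay",
]


class SimulationError(RuntimeError):
    """Integration failed or the state left the vascular-phase domain."""


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive-solver settings and the output-grid resolution.

    rel_tol/abs_tol are the RK45 tolerances (abs_tol in mm^3);
    output_grid_step (day) fixes the uniform grid trajectories are sampled
    on — plateau detection counts consecutive grid samples, so the default
    0.1 day makes its ten-sample window equal one day of agreement.
    """

    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    output_grid_step: float = 0.1
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be positive")
        if not 0 < self.output_grid_step <= 1.0:
            raise ValueError("output_grid_step must be in (0, 1] day")
        if not self.max_step > 0:
            raise ValueError("max_step must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Solution sampled on a uniform time grid.

    times in days; V, K in mm^3; I is the driving drug concentration in
    mg/kg at each sample (all zeros for free growth).
    """

    times: np.ndarray
    V: np.ndarray
    K: np.ndarray
    I: np.ndarray

    def volume_at(self, t: float) -> float:
        """Tumour volume at time t by linear interpolation on the grid."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"t={t} outside trajectory span "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, self.V))

    def first_crossing(self, ref_volume: float) -> float:
        """First time V crosses ref_volume from below (linear interpolation).

        Raises ValueError if the trajectory never reaches ref_volume.
        """
        above = self.V >= ref_volume
        if above[0]:
            return float(self.times[0])
        idx = np.argmax(above)
        if not above[idx]:
            raise ValueError(f"trajectory never reaches {ref_volume} mm^3")
        t0, t1 = self.times[idx - 1], self.times[idx]
        v0, v1 = self.V[idx - 1], self.V[idx]
        return float(t0 + (ref_volume - v0) / (v1 - v0) * (t1 - t0))


@dataclass(frozen=True)
class PlateauResult:
    """Time and value of the growth plateau, if attained."""

    t_plateau: float
    plateau_value: float
    attained: bool


def _concentration_function(
    regimen: Optional[Regimen],
    pk: Optional[PkParams],
    constant_conc: Optional[float],
    plasma_density: float,
) -> tuple[Callable[[float], float], list[float]]:
    """Drug concentration in growth units (mg/kg) and the forcing breakpoints."""
    if constant_conc is not None:
        return (lambda t: constant_conc), []
    if regimen is None:
        return (lambda t: 0.0), []
    if pk is None:
        raise ValueError("a regimen requires PK parameters")
    consts = hybrid_constants(pk)

    # Pre-flattened per-event scalars keep this cheap: the right-hand side
    # calls it at every internal solver stage.
    a, b, A, B = consts.a, consts.b, consts.A, consts.B
    Aa, Bb = A / a, B / b
    events = [
        (
            e.t_D,
            e.T,
            e.D / e.T,
            Aa * (1.0 - math.exp(-a * e.T)),
            Bb * (1.0 - math.exp(-b * e.T)),
        )
        for e in regimen.events
    ]
    exp = math.exp

    def conc(t):
        total = 0.0
        for t_start, dur, rate, end_a, end_b in events:
            tau = t - t_start
            if tau < 0.0:
                break  # events are time-ordered; later ones have not started
            if tau <= dur:
                total += rate * (
                    Aa * (1.0 - exp(-a * tau)) + Bb * (1.0 - exp(-b * tau))
                )
            else:
                tau -= dur
                total += rate * (end_a * exp(-a * tau) + end_b * exp(-b * tau))
        return total / plasma_density

    breaks: list[float] = []
    for e in regimen.events:
        breaks.extend((e.t_D, e.t_D + e.T))
    return conc, breaks


def simulate(
    growth: GrowthParams,
    init: TumourState,
    span: tuple[float, float],
    regimen: Optional[Regimen] = None,
    pk: Optional[PkParams] = None,
    opts: Optional[SolverOptions] = None,
    constant_conc: Optional[float] = None,
    plasma_density: float = PLASMA_DENSITY_KG_PER_ML,
) -> Trajectory:
    """Integrate the (V, K) system over `span` days.

    With a `regimen` (and `pk`) the treated equations are driven by the
    superposed infusion concentration, converted to mg/kg; with
    `constant_conc` the drug level is held fixed (saturating-exposure
    studies); otherwise growth is free.  Dose start/end times are enforced
    as integration restarts so the non-smooth forcing never straddles an
    accepted step.
    """
    opts = opts or SolverOptions()
    t0, t1 = float(span[0]), float(span[1])
    if t1 < t0:
        raise ValueError(f"span must satisfy t1 >= t0 (got {span})")
    conc, breaks = _concentration_function(regimen, pk, constant_conc, plasma_density)

    if t1 == t0:
        return Trajectory(
            times=np.array([t0]),
            V=np.array([init.V]),
            K=np.array([init.K]),
            I=np.array([float(conc(t0))]),
        )

    v_star = growth.v_star

    def rhs(t, y):
        v_hat, k_hat = y[0] - v_star, y[1] - v_star
        if v_hat < DOMAIN_FLOOR or k_hat < DOMAIN_FLOOR:
            raise DomainError(
                f"state left the vascular regime at t={t:.6g} "
                f"(V={y[0]:.6g}, K={y[1]:.6g})"
            )
        i_t = conc(t)
        dV = -growth.lambda1 * v_hat * math.log(v_hat / k_hat)
        abnormality = _abnormality(growth.beta, float(v_hat), growth.p)
        dK = (
            -growth.lambda2 * k_hat
            + _stimulation(growth.c, growth.alpha, abnormality, i_t, v_hat)
            - growth.d * k_hat * v_hat ** (2.0 / 3.0)
        )
        return (dV, dK)

    n_steps = max(1, math.ceil((t1 - t0) / opts.output_grid_step))
    grid = np.linspace(t0, t1, n_steps + 1)

    edges = sorted({t0, t1, *(b for b in breaks if t0 < b < t1)})
    V_out = np.empty_like(grid)
    K_out = np.empty_like(grid)
    V_out[0], K_out[0] = init.V, init.K
    y = np.array([init.V, init.K], dtype=float)

    for seg_start, seg_end in zip(edges[:-1], edges[1:]):
        try:
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method="RK45",
                rtol=opts.rel_tol,
                atol=opts.abs_tol,
                max_step=opts.max_step,
                dense_output=True,
            )
        except DomainError as exc:
            raise SimulationError(str(exc)) from exc
        if not sol.success:
            raise SimulationError(
                f"integration failed in [{seg_start:.6g}, {seg_end:.6g}]: {sol.message}"
            )
        mask = (grid > seg_start) & (grid <= seg_end)
        if mask.any():
            vals = sol.sol(grid[mask])
            V_out[mask] = vals[0]
            K_out[mask] = vals[1]
        y = sol.y[:, -1]

    I_out = np.array([float(conc(t)) for t in grid])
    return Trajectory(times=grid, V=V_out, K=K_out, I=I_out)


def detect_plateau(traj: Trajectory, min_duration: float = 10.0) -> PlateauResult:
    """Find the growth plateau on a uniform-grid trajectory.

    The plateau is attained at the first sample from which V and K,
    reported to whole mm^3 (nearest integer, the display resolution), agree
    on one repeated value for at least `min_duration` days; that repeated
    value is the plateau value.  Two conventions matter here:

    * nearest-integer comparison, because the plateau is approached from
      below — a 12412.94 asymptote is reported as 12413, a value
      truncation would never attain;
    * a duration (default ten days, ten steps of an adaptive solver whose
      near-plateau steps are of order a day) rather than a sample count,
      so that a transient shared band one integer below the asymptote,
      which the slowly converging V and K can occupy together for a few
      days, is not mistaken for the plateau.
    """
    rV = np.rint(traj.V)
    rK = np.rint(traj.K)
    equal = rV == rK
    n = len(equal)
    start = None
    for i in range(n + 1):
        ok = i < n and equal[i] and (
            start is None or i == 0 or not equal[i - 1] or rV[i] == rV[i - 1]
        )
        if ok:
            if start is None:
                start = i
        else:
            if start is not None:
                last = i - 1
                if traj.times[last] - traj.times[start] >= min_duration:
                    return PlateauResult(
                        t_plateau=float(traj.times[start]),
                        plateau_value=float(rV[start]),
                        attained=True,
                    )
            # a run broken by a value change may restart at this sample
            start = i if (i < n and equal[i]) else None
    return PlateauResult(t_plateau=math.nan, plateau_value=math.nan, attained=False)


def growth_inhibition(
    treated: Trajectory, untreated: Trajectory, t_eval: float
) -> float:
    """Percent tumour growth inhibition at t_eval:
    100 (V_untreated - V_treated) / V_untreated."""
    v_u = untreated.volume_at(t_eval)
    v_t = treated.volume_at(t_eval)
    return 100.0 * (v_u - v_t) / v_u


def growth_delay(
    treated: Trajectory, untreated: Trajectory, ref_volume: float
) -> float:
    """Days by which treatment delays the first crossing of ref_volume."""
    return treated.first_crossing(ref_volume) - untreated.first_crossing(ref_volume)
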