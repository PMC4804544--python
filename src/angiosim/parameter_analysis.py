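"""One-at-a-time perturbation study and plateau-based parameter bounds.

The plateau volume of an untreated tumour, ``V_ss = V* + (c/(alpha d))^(3/2)``,
depends only on the stimulation/inhibition balance ``c/d`` (for fixed
``alpha``); the Gompertz constant ``lambda1`` shifts the time at which the
plateau is reached but not its value.  This module quantifies both effects
by simulation (one-at-a-time perturbations of lambda1, c, d), maps the
analytic plateau over a (c, d) grid, and inverts the plateau formula to
derive the parameter ranges that keep a simulated tumour biologically
plausible: a plateau no larger than a prescribed cap, and a carrying
capacity that is non-decreasing at the initial state (no self-regressing
vasculature in untreated growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model_core import DomainError, GrowthParams, TumourState, steady_state_volume
from .simulation import PlateauResult, SolverOptions, detect_plateau, simulate

__all__ = [
    "PerturbationRecord",
    "ParameterBounds",
    "one_at_a_time",
    "oat_table",
    "plateau_surface",
    "valid_parameter_bounds",
]

#: Initial state used throughout the perturbation study.
DEFAULT_ANCHOR = TumourState(V=200.0, K=625.0)

#: Simulation horizon long enough for every perturbed run to plateau.
DEFAULT_HORIZON = 300.0

#: Parameters whose perturbation the study covers.
OAT_PARAMETERS = ("lambda1", "c", "d")


@dataclass(frozen=True)
class PerturbationRecord:
    """Outcome of perturbing one growth parameter.

    plateau_variation is the percent change of the plateau value relative
    to the reference run (0 for the reference itself).
    """

    parameter: str
    perturbation: float  # signed percent
    value: float  # the perturbed numeric value
    plateau_value: float  # mm^3
    t_plateau: float  # day
    plateau_variation: float  # percent vs reference


@dataclass(frozen=True)
class ParameterBounds:
    """Biologically-acceptable ranges for c and d.

    Upper c / lower d keep the plateau at or below `plateau_cap`; lower c /
    upper d keep dK/dt >= 0 at the anchor state (carrying capacity must not
    self-regress in untreated growth).
    """

    c_range: tuple[float, float]
    d_range: tuple[float, float]
    plateau_cap: float
    anchor_state: TumourState


def _reference_plateau(
    params: GrowthParams, init: TumourState, horizon: float, opts: SolverOptions
) -> PlateauResult:
    traj = simulate(params, init, (0.0, horizon), opts=opts)
    result = detect_plateau(traj)
    if not result.attained:
        raise RuntimeError(
            f"no plateau within {horizon} days; lengthen the horizon"
        )
    return result


def one_at_a_time(
    params: GrowthParams,
    target: str,
    pct: float,
    opts: Optional[SolverOptions] = None,
    init: TumourState = DEFAULT_ANCHOR,
    horizon: float = DEFAULT_HORIZON,
    reference: Optional[PlateauResult] = None,
) -> PerturbationRecord:
    """Simulate free growth with `target` perturbed by `pct` percent.

    The record carries the plateau value/time of the perturbed run and the
    percent variation of the plateau versus the unperturbed reference run
    (recomputed here unless supplied).
    """
    if target not in OAT_PARAMETERS:
        raise ValueError(f"target must be one of {OAT_PARAMETERS} (got {target!r})")
    opts = opts or SolverOptions()
    perturbed = params.perturbed(target, pct)  # GrowthParams validation applies
    if reference is None:
        reference = _reference_plateau(params, init, horizon, opts)
    result = _reference_plateau(perturbed, init, horizon, opts)
    variation = (
        100.0
        * (result.plateau_value - reference.plateau_value)
        / reference.plateau_value
    )
    return PerturbationRecord(
        parameter=target,
        perturbation=pct,
        value=getattr(perturbed, target),
        plateau_value=result.plateau_value,
        t_plateau=result.t_plateau,
        plateau_variation=variation,
    )


def oat_table(
    params: GrowthParams,
    percentages: Sequence[float] = (20.0, -20.0),
    targets: Sequence[str] = OAT_PARAMETERS,
    opts: Optional[SolverOptions] = None,
    init: TumourState = DEFAULT_ANCHOR,
    horizon: float = DEFAULT_HORIZON,
) -> list[PerturbationRecord]:
    """The full one-at-a-time study: every target at every percentage,
    preceded by one reference record per target (perturbation 0)."""
    opts = opts or SolverOptions()
    reference = _reference_plateau(params, init, horizon, opts)
    records: list[PerturbationRecord] = []
    for target in targets:
        records.append(
            PerturbationRecord(
                parameter=target,
                perturbation=0.0,
                value=getattr(params, target),
                plateau_value=reference.plateau_value,
                t_plateau=reference.t_plateau,
                plateau_variation=0.0,
            )
        )
        for pct in percentages:
            records.append(
                one_at_a_time(
                    params, target, pct, opts=opts, init=init,
                    horizon=horizon, reference=reference,
                )
            )
    return records


def plateau_surface(
    c_values: Sequence[float],
    d_values: Sequence[float],
    params: GrowthParams,
) -> np.ndarray:
    """Analytic plateau volume (mm^3) on the grid product of c and d values.

    Shape (len(c_values), len(d_values)); no simulation involved, the
    plateau depends on (c, d) only through the steady-state formula.
    """
    c = np.asarray(c_values, dtype=float)[:, None]
    d = np.asarray(d_values, dtype=float)[None, :]
    if np.any(c <= 0) or np.any(d <= 0):
        raise DomainError("c and d grids must be strictly positive")
    return params.v_star + (c / (params.alpha * d)) ** 1.5


def valid_parameter_bounds(
    params: GrowthParams,
    plateau_cap: float = 1e6,
    anchor: TumourState = DEFAULT_ANCHOR,
) -> ParameterBounds:
    """Ranges of c and d yielding biologically acceptable behaviour.

    Upper bound of c (and lower bound of d): the plateau
    ``V* + (c/(alpha d))^(3/2)`` must not exceed `plateau_cap`, giving
    ``c_max = alpha d (cap - V*)^(2/3)`` and
    ``d_min = c / (alpha (cap - V*)^(2/3))`` with the partner parameter at
    its current value.  Lower bound of c (and upper bound of d): dK/dt >= 0
    at the anchor state with lambda2 = 0, i.e. stimulation must at least
    balance inhibition at the start of growth:
    ``c_min = alpha d (K0 - V*) / (V0 - V*)^(1/3)`` and
    ``d_max = c (V0 - V*)^(1/3) / (alpha (K0 - V*))``.
    """
    v_hat = anchor.V - params.v_star
    k_hat = anchor.K - params.v_star
    if v_hat <= 0 or k_hat <= 0:
        raise DomainError("anchor state must lie in the vascular regime")
    if plateau_cap <= anchor.K:
        raise DomainError("plateau_cap must exceed the anchor carrying capacity")
    cap_hat = (plateau_cap - params.v_star) ** (2.0 / 3.0)
    c_max = params.alpha * params.d * cap_hat
    d_min = params.c / (params.alpha * cap_hat)
    c_min = params.alpha * params.d * k_hat / v_hat ** (1.0 / 3.0)
    d_max = params.c * v_hat ** (1.0 / 3.0) / (params.alpha * k_hat)
    return ParameterBounds(
        c_range=(c_min, c_max),
        d_range=(d_min, d_max),
        plateau_cap=plateau_cap,
        anchor_state=anchor,
    )
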