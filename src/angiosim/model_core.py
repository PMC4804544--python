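"""Vascular tumour growth model with a dynamic carrying capacity.

The tumour is described by two coupled state variables: the total volume
``V`` (mm^3) and the carrying capacity ``K`` (mm^3), i.e. the maximal volume
the current vasculature can sustain.  Growth is Gompertzian in the
vascularised excess ``V - V*``, where ``V*`` is the avascular threshold
volume at which the angiogenic switch occurs (a sphere of 1 mm diameter by
default).  The carrying capacity responds to tumour-secreted proangiogenic
stimulators (coefficient ``c``), endogenous inhibitors (coefficient ``d``)
and, under anti-VEGF therapy, to the plasma drug concentration ``I`` which
competes with stimulator clearance (``alpha``) modulated by the abnormal
vessel phenotype (``beta``, ``p``):

    dV/dt = -lambda1 (V - V*) ln((V - V*)/(K - V*))
    dK/dt = -lambda2 (K - V*)
            + c (beta + (V - V*)^p)(V - V*) / (alpha (beta + (V - V*)^p) + I)
            - d (K - V*)(V - V*)^(2/3)

With ``I = 0`` the stimulation term collapses to ``(c/alpha)(V - V*)``; the
untreated system then admits the post-vascular dormancy steady state

    V_ss = V* + (c / (alpha d))^(3/2),

independent of lambda1, lambda2, beta and p.  As ``I -> infinity`` the
system contracts to ``(V*, V*)``: an unbounded drug exposure shuts the
vasculature down to the avascular floor, never below it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

__all__ = [
    "SPHERE_1MM_VOLUME",
    "GrowthParams",
    "TumourState",
    "DomainError",
    "rhs_treated",
    "rhs_untreated",
    "steady_state_volume",
    "sphere_volume",
    "radius_from_volume",
    "read_growth_params",
    "write_growth_params",
]

#: Volume of a sphere of diameter 1 mm, the conventional avascular limit
#: size for mouse tumours.  Displayed rounded as 0.52 mm^3.
SPHERE_1MM_VOLUME = math.pi / 6.0

#: States closer to the avascular floor than this (in mm^3) are treated as
#: having left the vascular regime, where the model is defined.
DOMAIN_FLOOR = 1e-12


class DomainError(ValueError):
    """The model was evaluated outside its vascular-phase domain."""


@dataclass(frozen=True)
class GrowthParams:
    """Coefficients of the vascular growth model.

    Parameters
    ----------
    lambda1 : float
        Gompertzian growth constant, day^-1.
    lambda2 : float
        Natural endothelial loss rate, day^-1.  Defaults to 0: spontaneous
        loss of functional vasculature is negligible on xenograft
        timescales and the reference parameterisation omits it.
    c : float
        Proangiogenic stimulation coefficient, mg/(day mm^(3p) kg).
        Strictly positive: a non-positive value would make the carrying
        capacity self-regressing even for an untreated tumour.
    d : float
        Endogenous angiogenesis-inhibition coefficient, day^-1 mm^-2.
    alpha : float
        Stimulator clearance parameter, mg/(mm^(3p) kg); strictly positive.
    beta : float
        Vessel-abnormality offset, mm^(3p).
    p : float
        Vessel-abnormality exponent, dimensionless.
    v_star : float
        Avascular threshold volume V*, mm^3.  Defaults to the exact volume
        of a 1 mm diameter sphere.
    """

    lambda1: float = 0.192
    lambda2: float = 0.0
    c: float = 5.85
    d: float = 0.00873
    alpha: float = 1.0
    beta: float = 1.0
    p: float = 0.0
    v_star: float = SPHERE_1MM_VOLUME

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be > 0 (got {self.c}): non-positive "
                             "stimulation yields a self-regressing carrying capacity")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0 (got {self.alpha})")
        for name in ("lambda1", "lambda2", "d", "beta", "p", "v_star"):
            val = getattr(self, name)
            if val < 0 or not math.isfinite(val):
                raise ValueError(f"{name} must be finite and >= 0 (got {val})")
        if not math.isfinite(self.lambda1):
            raise ValueError("lambda1 must be finite")

    def perturbed(self, name: str, pct: float) -> "GrowthParams":
        """Return a copy with parameter `name` scaled by (1 + pct/100)."""
        value = getattr(self, name) * (1.0 + pct / 100.0)
        return replace(self, **{name: value})


@dataclass(frozen=True)
class TumourState:
    """Instantaneous (V, K) state in mm^3."""

    V: float
    K: float


def _validate_state(V: float, K: float, v_star: float) -> tuple[float, float]:
    """Return the excess volumes (V - V*, K - V*), raising outside the domain."""
    v_hat = V - v_star
    k_hat = K - v_star
    if v_hat < DOMAIN_FLOOR or k_hat < DOMAIN_FLOOR:
        raise DomainError(
            f"state (V={V}, K={K}) is not in the vascular regime "
            f"(both must exceed v_star={v_star} by at least {DOMAIN_FLOOR})"
        )
    return v_hat, k_hat


def _abnormality(beta: float, x: float, p: float) -> float:
    """beta + x^p with x^0 == 1 for every x >= 0 (so p = 0 reduces the
    factor to beta + 1) and overflow saturating to +inf."""
    if p == 0.0:
        return beta + 1.0
    if x == 0.0:
        return beta
    if p * math.log(x) > 700.0:  # exp overflow threshold for float64
        return math.inf
    return beta + float(x) ** float(p)


def _stimulation(c: float, alpha: float, abnormality: float, conc: float,
                 v_hat: float) -> float:
    """c (beta + v^p) v / (alpha (beta + v^p) + I), written as
    c v / (alpha + I/(beta + v^p)) so that an overflowing abnormality
    factor saturates the term at its drug-free value instead of NaN."""
    if conc == 0.0:
        return c * v_hat / alpha
    return c * v_hat / (alpha + conc / abnormality)


def rhs_treated(
    state: TumourState, params: GrowthParams, conc: float
) -> tuple[float, float]:
    """Rates (dV/dt, dK/dt) in mm^3/day under drug concentration `conc` (mg/kg).

    Raises
    ------
    DomainError
        If V or K does not exceed the avascular floor, or conc < 0.
    """
    if conc < 0:
        raise DomainError(f"drug concentration must be >= 0 (got {conc})")
    v_hat, k_hat = _validate_state(state.V, state.K, params.v_star)
    dV = -params.lambda1 * v_hat * math.log(v_hat / k_hat)
    abnormality = _abnormality(params.beta, v_hat, params.p)
    stimulation = _stimulation(params.c, params.alpha, abnormality, conc, v_hat)
    inhibition = params.d * k_hat * v_hat ** (2.0 / 3.0)
    dK = -params.lambda2 * k_hat + stimulation - inhibition
    return dV, dK


def rhs_untreated(state: TumourState, params: GrowthParams) -> tuple[float, float]:
    """Rates (dV/dt, dK/dt) for free growth; identical to `rhs_treated` at conc 0."""
    v_hat, k_hat = _validate_state(state.V, state.K, params.v_star)
    dV = -params.lambda1 * v_hat * math.log(v_hat / k_hat)
    dK = (
        -params.lambda2 * k_hat
        + (params.c / params.alpha) * v_hat
        - params.d * k_hat * v_hat ** (2.0 / 3.0)
    )
    return dV, dK


def steady_state_volume(params: GrowthParams) -> float:
    """Post-vascular dormancy plateau V* + (c/(alpha d))^(3/2), mm^3.

    Raises
    ------
    DomainError
        If d == 0, in which case no finite plateau exists.
    """
    if params.d <= 0:
        raise DomainError("steady state requires d > 0 (no finite plateau otherwise)")
    return params.v_star + (params.c / (params.alpha * params.d)) ** 1.5


def sphere_volume(diameter: float) -> float:
    """Volume (mm^3) of a sphere of the given diameter (mm)."""
    if diameter < 0:
        raise DomainError(f"diameter must be >= 0 (got {diameter})")
    return math.pi / 6.0 * diameter ** 3


def radius_from_volume(volume: float) -> float:
    """Radius (mm) of a sphere of the given volume (mm^3)."""
    if volume < 0:
        raise DomainError(f"volume must be >= 0 (got {volume})")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# Flat-file parameter I/O
# ---------------------------------------------------------------------------

_PARAM_KEYS = ("lambda1", "lambda2", "c", "d", "alpha", "beta", "p", "v_star")


def read_growth_params(path: Union[str, Path]) -> GrowthParams:
    """Read growth parameters from a flat CSV (key,value rows or a one-row
    table with named columns) or a flat JSON object.

    Recognised keys: lambda1, lambda2, c, d, alpha, beta, p, v_star.
    Missing keys take the reference defaults.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat JSON object")
        values = {k: float(v) for k, v in data.items()}
    else:
        import pandas as pd

        df = pd.read_csv(path)
        cols = [str(c).strip() for c in df.columns]
        if set(_PARAM_KEYS) & set(cols):
            # one-row wide table
            values = {k: float(df.iloc[0][k]) for k in cols if k in _PARAM_KEYS}
        elif len(cols) == 2:
            # key,value long table (header optional but harmless)
            values = {}
            first = pd.read_csv(path, header=None)
            for _, row in first.iterrows():
                key = str(row.iloc[0]).strip()
                if key in _PARAM_KEYS:
                    values[key] = float(row.iloc[1])
        else:
            raise ValueError(f"{path}: unrecognised parameter CSV layout")
    unknown = set(values) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return GrowthParams(**values)


def write_growth_params(path: Union[str, Path], params: GrowthParams) -> None:
    """Write growth parameters as a two-column key,value CSV."""
    path = Path(path)
    lines = ["key,value"]
    lines += [f"{k},{getattr(params, k)!r}" for k in _PARAM_KEYS]
    path.write_text("\n".join(lines) + "\n")
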