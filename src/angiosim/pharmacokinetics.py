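"""Two-compartment intravenous-infusion pharmacokinetics of an anti-VEGF agent.

The drug enters the central compartment (plasma plus well-perfused organs,
volume ``Vc``) at the constant rate ``D/T`` for the infusion duration ``T``
(zero-order absorption), exchanges with a peripheral compartment at
first-order rates ``k12``/``k21`` and is eliminated from the central
compartment at rate ``ke``.  The plasma concentration is the bi-exponential

    during infusion (0 <= t - tD <= T):
        I(t) = (D/T) [ (A/a)(1 - e^{-a (t-tD)}) + (B/b)(1 - e^{-b (t-tD)}) ]
    after infusion (t - tD > T):
        I(t) = (D/T) [ (A/a)(1 - e^{-aT}) e^{-a (t-tD-T)}
                     + (B/b)(1 - e^{-bT}) e^{-b (t-tD-T)} ]

in the hybrid macro-rates a > b > 0, the roots of
``x^2 - (k12+k21+ke) x + k21 ke = 0`` (so ``a b = k21 ke`` and
``a + b = k12 + k21 + ke``), with coefficients
``A = (a - k21)/(Vc (a - b))`` and ``B = (b - k21)/(Vc (b - a))``,
``A + B = 1/Vc``.  The system is linear, so a multi-dose schedule is the
superposition of single-dose curves.

The growth model consumes concentration per unit body mass (mg/kg); the
plasma output (mg/ml) is converted by dividing by the blood plasma density,
1.025e-3 kg/ml by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PLASMA_DENSITY_KG_PER_ML",
    "PkParams",
    "HybridConstants",
    "DoseEvent",
    "Regimen",
    "hybrid_constants",
    "infusion_concentration",
    "regimen_concentration",
    "to_growth_units",
    "read_pk_params",
    "read_regimen",
]

#: Typical blood plasma density, kg/ml (1.025 g/ml).
PLASMA_DENSITY_KG_PER_ML = 1.025e-3


@dataclass(frozen=True)
class PkParams:
    """Micro-constants of the two-compartment model.

    Vc in ml; k12, k21, ke in day^-1.  Reference mouse values for
    bevacizumab: Vc=7.975, k12=0.7536, k21=0.3144, ke=0.3888.
    """

    Vc: float = 7.975
    k12: float = 0.7536
    k21: float = 0.3144
    ke: float = 0.3888

    def __post_init__(self) -> None:
        for name in ("Vc", "k12", "k21", "ke"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 (got {getattr(self, name)})")
        s = self.k12 + self.k21 + self.ke
        if s * s <= 4.0 * self.k21 * self.ke:
            raise ValueError("rate constants must give distinct real hybrid roots")


@dataclass(frozen=True)
class HybridConstants:
    """Macro-rates a > b > 0 (day^-1) and coefficients A, B (ml^-1)."""

    a: float
    b: float
    A: float
    B: float


def hybrid_constants(pk: PkParams) -> HybridConstants:
    """Hybrid macro-constants from the micro-constants.

    ``b`` is the slow root 0.5 (S - sqrt(S^2 - 4 k21 ke)) with
    S = k12 + k21 + ke, and ``a = k21 ke / b`` the fast one.
    """
    s = pk.k12 + pk.k21 + pk.ke
    disc = s * s - 4.0 * pk.k21 * pk.ke
    if disc <= 0:
        raise ValueError("non-positive discriminant: hybrid roots are not real/distinct")
    b = 0.5 * (s - math.sqrt(disc))
    a = pk.k21 * pk.ke / b
    A = (a - pk.k21) / (pk.Vc * (a - b))
    B = (b - pk.k21) / (pk.Vc * (b - a))
    return HybridConstants(a=a, b=b, A=A, B=B)


@dataclass(frozen=True)
class DoseEvent:
    """A single infusion: start time t_D (day), dose D (mg), duration T (day)."""

    t_D: float
    D: float
    T: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"infusion duration T must be > 0 (got {self.T})")
        if self.D < 0:
            raise ValueError(f"dose D must be >= 0 (got {self.D})")


@dataclass(frozen=True)
class Regimen:
    """An ordered schedule of infusions at a common per-weight dose.

    `dosage` is in mg/kg, `weight` in kg; each event carries the absolute
    dose D = dosage * weight.
    """

    events: tuple[DoseEvent, ...]
    dosage: float
    weight: float

    def __post_init__(self) -> None:
        times = [e.t_D for e in self.events]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose events must be sorted by strictly increasing t_D")
        expected = self.dosage * self.weight
        for e in self.events:
            if not math.isclose(e.D, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    f"event at t={e.t_D} has D={e.D}, expected dosage*weight={expected}"
                )

    @property
    def n(self) -> int:
        return len(self.events)

    def scaled(self, dosage: float) -> "Regimen":
        """Same schedule at a different per-weight dose level."""
        events = tuple(
            DoseEvent(t_D=e.t_D, D=dosage * self.weight, T=e.T) for e in self.events
        )
        return Regimen(events=events, dosage=dosage, weight=self.weight)


def infusion_concentration(t, event: DoseEvent, consts: HybridConstants):
    """Plasma concentration (mg/ml) from a single infusion, vectorised over t.

    Zero before the dose starts; the during- and post-infusion branches are
    continuous at the switch ``t - t_D = T`` and decay to 0 as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    tau = t - event.t_D
    rate = event.D / event.T
    a, b, A, B = consts.a, consts.b, consts.A, consts.B

    # tau clipped into [0, T] keeps the during-branch exponentials finite
    # even where the other branch is selected by np.where.
    tau_in = np.clip(tau, 0.0, event.T)
    during = rate * (
        (A / a) * (1.0 - np.exp(-a * tau_in)) + (B / b) * (1.0 - np.exp(-b * tau_in))
    )
    elapsed_post = np.clip(tau - event.T, 0.0, None)
    post = rate * (
        (A / a) * (1.0 - math.exp(-a * event.T)) * np.exp(-a * elapsed_post)
        + (B / b) * (1.0 - math.exp(-b * event.T)) * np.exp(-b * elapsed_post)
    )
    out = np.where(tau < 0.0, 0.0, np.where(tau <= event.T, during, post))
    if out.ndim == 0:
        return float(out)
    return out


def regimen_concentration(t, regimen: Regimen, consts: HybridConstants):
    """Total plasma concentration (mg/ml): superposition over all started doses."""
    t = np.asarray(t, dtype=float)
    total = np.zeros_like(t)
    for event in regimen.events:
        total = total + infusion_concentration(t, event, consts)
    if total.ndim == 0:
        return float(total)
    return total


def to_growth_units(conc, plasma_density: float = PLASMA_DENSITY_KG_PER_ML):
    """Convert plasma concentration mg/ml -> mg/kg by the plasma density (kg/ml)."""
    if not plasma_density > 0:
        raise ValueError(f"plasma density must be > 0 (got {plasma_density})")
    return conc / plasma_density


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------


def read_pk_params(path: Union[str, Path]) -> PkParams:
    """Read PK micro-constants from a flat JSON object or key,value CSV
    with keys Vc, k12, k21, ke."""
    path = Path(path)
    keys = ("Vc", "k12", "k21", "ke")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        values = {k: float(data[k]) for k in keys if k in data}
    else:
        import pandas as pd

        raw = pd.read_csv(path, header=None)
        values = {}
        for _, row in raw.iterrows():
            key = str(row.iloc[0]).strip()
            if key in keys:
                values[key] = float(row.iloc[1])
    return PkParams(**values)


def read_regimen(path: Union[str, Path]) -> Regimen:
    """Read a dosing schedule from JSON with keys dosage (mg/kg), weight
    (kg), infusion_duration (day) and times (list of days)."""
    path = Path(path)
    data = json.loads(path.read_text())
    return build_regimen(
        dosage=float(data["dosage"]),
        weight=float(data["weight"]),
        days=[float(t) for t in data["times"]],
        duration=float(data["infusion_duration"]),
    )


def build_regimen(
    dosage: float, weight: float, days: Sequence[float], duration: float
) -> Regimen:
    """Construct a Regimen with D = dosage * weight at each administration day."""
    if dosage < 0 or not weight > 0 or not duration > 0:
        raise ValueError("dosage must be >= 0; weight and duration must be > 0")
    days = list(days)
    if len(set(days)) != len(days):
        raise ValueError("duplicate administration days in regimen")
    events = tuple(
        DoseEvent(t_D=float(t), D=dosage * weight, T=duration) for t in sorted(days)
    )
    return Regimen(events=events, dosage=dosage, weight=weight)
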