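"""Oral dosing: regimens, Weibull dissolution, gut-lumen absorption flux.

The gut is a single lumped lumen: solid drug dissolves following a Weibull
law (time to 50% dissolved is the tablet's dissolution time), the dissolved
concentration is capped by aqueous solubility, and dissolved drug permeates
the intestinal wall at a rate proportional to the luminal concentration and
an effective absorption surface. Absorbed drug enters the portal circulation
and passes through the liver before reaching the systemic blood (first pass).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "DoseEvent",
    "DoseRegimen",
    "fraction_dissolved",
    "dissolution_rate_constant",
    "gut_absorption_flux",
]


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time (h), amount (mg) and formulation.

    ``formulation`` 'tablet' enters the undissolved pool, 'solution' enters
    the dissolved pool directly, 'iv' is an intravenous-like bolus into
    venous blood (used for mass-balance checks).
    """

    time_h: float
    amount_mg: float
    formulation: str = "tablet"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be >= 0")
        if self.formulation not in ("tablet", "solution", "iv"):
            raise ValueError(f"unknown formulation {self.formulation!r}")


_SEGMENT = re.compile(
    r"^\s*(?P<amount>[\d.]+)\s*mg\s*"
    r"(?:qd\s*)?"
    r"(?:(?:x|×)\s*(?P<days>\d+)\s*d(?:ays?)?"
    r"|to\s+day\s+(?P<today>\d+)"
    r"|from\s+day\s+(?P<fromday>\d+)\s+to\s+(?:day\s+)?(?P<untilday>\d+))?\s*$",
    re.IGNORECASE,
)


@dataclass
class DoseRegimen:
    """An ordered, duplicate-free collection of dose events."""

    events: list[DoseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        # events at identical times and formulation merge (amounts add), so
        # the sorted event list has no duplicate times per formulation
        merged: dict[tuple[float, str], float] = {}
        for e in self.events:
            key = (e.time_h, e.formulation)
            merged[key] = merged.get(key, 0.0) + e.amount_mg
        self.events = [
            DoseEvent(t, amt, form)
            for (t, form), amt in sorted(merged.items())
        ]

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_dose_mg(self) -> float:
        return sum(e.amount_mg for e in self.events)

    @classmethod
    def single(cls, amount_mg: float, time_h: float = 0.0,
               formulation: str = "tablet") -> "DoseRegimen":
        return cls([DoseEvent(time_h, amount_mg, formulation)])

    @classmethod
    def daily(cls, amount_mg: float, days: int, start_day: int = 0,
              formulation: str = "tablet") -> "DoseRegimen":
        return cls([
            DoseEvent(24.0 * (start_day + d), amount_mg, formulation)
            for d in range(days)
        ])

    @classmethod
    def parse(cls, text: str) -> "DoseRegimen":
        """Parse shorthand like ``"2 mg QD x 21 d"`` or
        ``"0.35 mg QD x 7 d then 2 mg QD to day 21"``."""
        events: list[DoseEvent] = []
        day = 0
        for segment in re.split(r"\bthen\b", text, flags=re.IGNORECASE):
            m = _SEGMENT.match(segment)
            if m is None:
                raise ValueError(f"cannot parse regimen segment {segment!r}")
            amount = float(m.group("amount"))
            if m.group("fromday"):
                start = int(m.group("fromday")) - 1
                end = int(m.group("untilday"))
            else:
                start = day
                if m.group("days"):
                    end = start + int(m.group("days"))
                elif m.group("today"):
                    end = int(m.group("today"))
                else:
                    end = start + 1
            for d in range(start, end):
                events.append(DoseEvent(24.0 * d, amount))
            day = end
        return cls(events)


def fraction_dissolved(t_min: float, t50_min: float, shape: float) -> float:
    """Cumulative Weibull dissolution: F(t) = 1 - exp(-ln2 (t/t50)^shape).

    F(t50) = 1/2 for every shape parameter; shape 1 gives first-order
    dissolution with half-time t50.
    """
    if t_min < 0:
        raise ValueError("time must be >= 0")
    if t50_min <= 0 or shape <= 0:
        raise ValueError("t50 and shape must be positive")
    return 1.0 - math.exp(-math.log(2.0) * (t_min / t50_min) ** shape)


def dissolution_rate_constant(t50_min: float) -> float:
    """First-order dissolution rate (1/h) equivalent to shape-1 Weibull."""
    if t50_min <= 0:
        raise ValueError("t50 must be positive")
    return math.log(2.0) * 60.0 / t50_min


def gut_absorption_flux(
    dissolved_amount_mg: float,
    lumen_volume_l: float,
    permeability_cm_per_min: float,
    surface_area_cm2: float,
) -> float:
    """Absorptive flux (mg/min) out of the lumen.

    flux = P * S * C_lumen with C_lumen in mg/cm^3 (1 L = 1000 cm^3).
    """
    for v in (dissolved_amount_mg, lumen_volume_l,
              permeability_cm_per_min, surface_area_cm2):
        if v < 0:
            raise ValueError("arguments must be >= 0")
    if dissolved_amount_mg == 0.0:
        return 0.0
    if lumen_volume_l == 0.0:
        raise ValueError("zero lumen volume with nonzero dissolved amount")
    conc_mg_per_cm3 = dissolved_amount_mg / (lumen_volume_l * 1000.0)
    return permeability_cm_per_min * surface_area_cm2 * conc_mg_per_cm3
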