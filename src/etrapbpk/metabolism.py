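"""Hepatic metabolism: IVIVE scaling, fraction metabolized, DDI actions.

Per-enzyme specific intrinsic clearances (uL/min/pmol, measured with
recombinant enzymes) scale to whole-liver intrinsic clearance through the
individual's whole-liver enzyme amounts and activity multipliers.
Perpetrators act multiplicatively on each enzyme's effective clearance:
competitive inhibition divides by (1 + I_u/Ki); induction multiplies by
1 + Emax*C_u/(EC50 + C_u). Renal clearance is negligible for etrasimod and
is fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._resources import read_text
from .physiology import ReferenceIndividual

__all__ = [
    "EnzymeKinetics",
    "InhibitionSpec",
    "InductionSpec",
    "PerpetratorExposure",
    "Perpetrator",
    "load_perpetrator",
    "convert_clint_units",
    "whole_liver_intrinsic_clearance",
    "fraction_metabolized",
    "inhibited_clint",
    "induction_factor",
    "effective_enzyme_clearances",
]

#: uL/min -> L/h
_UL_PER_MIN_TO_L_PER_H = 60.0 * 1e-6
#: umol -> pmol
_UMOL_TO_PMOL = 1e6


class EnzymeKinetics(dict):
    """Mapping enzyme name -> specific intrinsic clearance (uL/min/pmol)."""

    def __init__(self, values: dict[str, float]):
        for enz, v in values.items():
            if v < 0:
                raise ValueError(f"{enz}: specific clearance must be >= 0")
        super().__init__(values)

    @classmethod
    def from_drug(cls, drug) -> "EnzymeKinetics":
        return cls(dict(drug.enzyme_clint_ul_per_min_per_pmol))


@dataclass(frozen=True)
class InhibitionSpec:
    enzyme: str
    ki_umol_per_l: float

    def __post_init__(self) -> None:
        if self.ki_umol_per_l <= 0:
            raise ValueError("Ki must be positive")


@dataclass(frozen=True)
class InductionSpec:
    enzyme: str
    ec50_umol_per_l: float
    emax: float

    def __post_init__(self) -> None:
        if self.ec50_umol_per_l <= 0:
            raise ValueError("EC50 must be positive")
        if self.emax < 0:
            raise ValueError("Emax must be >= 0")


@dataclass(frozen=True)
class PerpetratorExposure:
    """Unbound perpetrator concentration: constant or a time profile."""

    mode: str = "constant"  # 'constant' | 'profile'
    unbound_umol_per_l: float = 0.0
    profile: tuple[tuple[float, float], ...] = ()  # (time h, conc uM)

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "profile"):
            raise ValueError(f"unknown exposure mode {self.mode!r}")
        if self.unbound_umol_per_l < 0:
            raise ValueError("concentration must be >= 0")
        if any(c < 0 for _, c in self.profile):
            raise ValueError("profile concentrations must be >= 0")

    def concentration_at(self, t_h: float) -> float:
        if self.mode == "constant":
            return self.unbound_umol_per_l
        import numpy as np

        times = [p[0] for p in self.profile]
        concs = [p[1] for p in self.profile]
        return float(np.interp(t_h, times, concs))


@dataclass(frozen=True)
class Perpetrator:
    """A co-administered enzyme inhibitor or inducer and its exposure."""

    name: str
    inhibition: tuple[InhibitionSpec, ...] = ()
    induction: tuple[InductionSpec, ...] = ()
    exposure: PerpetratorExposure = field(default_factory=PerpetratorExposure)

    def activity_multiplier(self, enzyme: str, t_h: float = 0.0) -> float:
        """Net multiplicative action on one enzyme's effective clearance."""
        conc = self.exposure.concentration_at(t_h)
        mult = 1.0
        for spec in self.inhibition:
            if spec.enzyme == enzyme:
                mult /= 1.0 + conc / spec.ki_umol_per_l
        for spec in self.induction:
            if spec.enzyme == enzyme:
                mult *= induction_factor(conc, spec)
        return mult


def load_perpetrator(
    name_or_path: str, unbound_umol_per_l: float | None = None
) -> Perpetrator:
    """Load a packaged perpetrator config ('fluconazole', 'rifampicin')."""
    if name_or_path.endswith((".yaml", ".yml")):
        with open(name_or_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(read_text(f"{name_or_path}.yaml"))
    conc = (
        cfg.get("default_unbound_concentration_umol_per_l", 0.0)
        if unbound_umol_per_l is None
        else unbound_umol_per_l
    )
    inhibition = tuple(
        InhibitionSpec(enzyme=enz, ki_umol_per_l=ki)
        for enz, ki in cfg.get("ki_umol_per_l", {}).items()
    )
    induction = tuple(
        InductionSpec(enzyme=enz, ec50_umol_per_l=spec["ec50_umol_per_l"],
                      emax=spec["emax"])
        for enz, spec in cfg.get("induction", {}).items()
    )
    return Perpetrator(
        name=cfg["name"],
        inhibition=inhibition,
        induction=induction,
        exposure=PerpetratorExposure(mode="constant", unbound_umol_per_l=conc),
    )


def convert_clint_units(
    clint_ul_per_min_per_mg: float, abundance_pmol_per_mg: float
) -> float:
    """Mass-normalized intrinsic clearance to per-pmol-enzyme units.

    Clint[uL/min/pmol] = Clint[uL/min/mg] / abundance[pmol/mg].
    """
    if abundance_pmol_per_mg <= 0:
        raise ValueError("enzyme abundance must be positive")
    return clint_ul_per_min_per_mg / abundance_pmol_per_mg


def whole_liver_intrinsic_clearance(
    kinetics: EnzymeKinetics,
    individual: ReferenceIndividual,
    perpetrators: tuple[Perpetrator, ...] = (),
    t_h: float = 0.0,
) -> tuple[dict[str, float], float]:
    """Per-enzyme and total whole-liver unbound intrinsic clearance (L/h).

    CLint_e = specific clearance * whole-liver amount * activity multiplier
    (disease activity and any perpetrator action), converted to L/h.
    """
    unknown = set(kinetics) - set(individual.enzyme_abundance_umol)
    if unknown:
        raise ValueError(f"unknown enzyme(s) in kinetics: {sorted(unknown)}")
    per_enzyme: dict[str, float] = {}
    for enz, specific in kinetics.items():
        amount_pmol = individual.enzyme_abundance_umol[enz] * _UMOL_TO_PMOL
        activity = individual.enzyme_activity.get(enz, 1.0)
        for perp in perpetrators:
            activity *= perp.activity_multiplier(enz, t_h)
        per_enzyme[enz] = (
            specific * amount_pmol * activity * _UL_PER_MIN_TO_L_PER_H
        )
    return per_enzyme, sum(per_enzyme.values())


def fraction_metabolized(
    kinetics: EnzymeKinetics, individual: ReferenceIndividual
) -> dict[str, float]:
    """Share of total metabolic clearance carried by each enzyme."""
    per_enzyme, total = whole_liver_intrinsic_clearance(kinetics, individual)
    if total <= 0:
        raise ValueError("total intrinsic clearance is zero")
    return {enz: cl / total for enz, cl in per_enzyme.items()}


def inhibited_clint(
    clint: float, unbound_inhibitor_umol_per_l: float, ki_umol_per_l: float
) -> float:
    """Competitive inhibition: CLint / (1 + I_u/Ki)."""
    if clint < 0 or unbound_inhibitor_umol_per_l < 0:
        raise ValueError("clearance and inhibitor concentration must be >= 0")
    if ki_umol_per_l <= 0:
        raise ValueError("Ki must be positive")
    return clint / (1.0 + unbound_inhibitor_umol_per_l / ki_umol_per_l)


def induction_factor(
    unbound_inducer_umol_per_l: float, spec: InductionSpec
) -> float:
    """Steady-state induction multiplier: 1 + Emax*C/(EC50 + C), in [1, 1+Emax]."""
    if unbound_inducer_umol_per_l < 0:
        raise ValueError("inducer concentration must be >= 0")
    c = unbound_inducer_umol_per_l
    return 1.0 + spec.emax * c / (spec.ec50_umol_per_l + c)


def effective_enzyme_clearances(
    kinetics: EnzymeKinetics,
    individual: ReferenceIndividual,
    perpetrators: tuple[Perpetrator, ...] = (),
) -> tuple[dict[str, float], float]:
    """Convenience alias used by the simulation engine at assembly time."""
    return whole_liver_intrinsic_clearance(kinetics, individual, perpetrators)
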