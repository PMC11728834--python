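"""Virtual-individual physiology: the reference healthy adult, virtual
populations, and Child-Pugh chronic-liver-disease scaling.

The reference adult (73 kg, 30 y) is loaded from a packaged table of organ
volumes, regional blood flows and tissue compositions. Organ volumes scale
linearly with body weight and blood flows allometrically (exponent 0.75).
Hepatic impairment is applied as a set of multiplicative scalers on flows,
liver mass, binding proteins, hematocrit, GFR and per-CYP metabolic activity,
one grade (A/B/C) at a time, on an otherwise healthy individual.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ._resources import read_text, REFERENCE_WEIGHT_KG

__all__ = [
    "OrganSpec",
    "ReferenceIndividual",
    "ChildPughScalers",
    "VirtualPopulation",
    "build_reference_adult",
    "sample_population",
    "apply_child_pugh",
    "scale_fraction_unbound",
    "ORGAN_NAMES",
    "BLOOD_POOLS",
    "PORTAL_ORGANS",
    "ENZYMES",
]

ORGAN_NAMES = (
    "lung", "heart", "brain", "muscle", "adipose", "skin", "bone",
    "kidney", "gut", "spleen", "liver", "rest-of-body",
    "arterial blood", "venous blood",
)
BLOOD_POOLS = ("arterial blood", "venous blood")
#: organs whose venous effluent drains into the portal vein (first pass)
PORTAL_ORGANS = ("gut", "spleen")
#: organs whose arterial supply belongs to the "other organs" flow category
#: of the liver-disease scaler table
OTHER_FLOW_ORGANS = (
    "heart", "brain", "muscle", "adipose", "skin", "bone", "rest-of-body",
)
ENZYMES = ("CYP2C8", "CYP2C9", "CYP3A4", "CYP2C19", "CYP2J2")

_REFERENCE_HEMATOCRIT = 0.45


@dataclass(frozen=True)
class OrganSpec:
    """One perfused compartment: volume, regional blood flow, composition.

    Composition fractions are expressed per unit tissue volume; albumin and
    lipoprotein ratios are tissue-to-plasma concentration ratios. Blood pools
    carry zero regional flow and an all-zero composition.
    """

    name: str
    volume_l: float
    blood_flow_l_per_h: float
    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ap_mg_per_g: float
    albumin_ratio: float
    lipoprotein_ratio: float

    def __post_init__(self) -> None:
        if self.volume_l <= 0:
            raise ValueError(f"{self.name}: volume must be positive")
        if self.blood_flow_l_per_h < 0:
            raise ValueError(f"{self.name}: blood flow must be >= 0")
        for label in ("f_ew", "f_iw", "f_nl", "f_np"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {label}={v} outside [0, 1]")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-12:
            raise ValueError(f"{self.name}: water+lipid fractions exceed 1")

    @property
    def total_water(self) -> float:
        return self.f_ew + self.f_iw


@dataclass
class ReferenceIndividual:
    """A virtual subject: anthropometry, organs, binding proteins, enzymes."""

    weight_kg: float
    age_years: float
    organs: dict[str, OrganSpec]
    hematocrit: float
    albumin_ratio: float
    agp_ratio: float
    gfr_ratio: float
    enzyme_abundance_umol: dict[str, float]
    enzyme_activity: dict[str, float]
    child_pugh_grade: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")
        for label in ("albumin_ratio", "agp_ratio", "gfr_ratio"):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")
        for enz, amount in self.enzyme_abundance_umol.items():
            if amount < 0:
                raise ValueError(f"{enz}: abundance must be >= 0")

    @property
    def cardiac_output_l_per_h(self) -> float:
        """Cardiac output = sum of arterial-side regional flows."""
        return sum(
            o.blood_flow_l_per_h for n, o in self.organs.items()
            if n != "lung" and n not in BLOOD_POOLS
        )

    @property
    def portal_flow_l_per_h(self) -> float:
        return sum(self.organs[n].blood_flow_l_per_h for n in PORTAL_ORGANS)

    @property
    def liver_blood_flow_l_per_h(self) -> float:
        """Total hepatic inflow: hepatic artery plus portal vein."""
        return self.organs["liver"].blood_flow_l_per_h + self.portal_flow_l_per_h

    def copy(self) -> "ReferenceIndividual":
        return copy.deepcopy(self)

    def parameter_row(self) -> dict[str, float]:
        """Flat parameter dict (one CSV row) for population export."""
        row: dict[str, float] = {
            "weight_kg": self.weight_kg,
            "age_years": self.age_years,
            "hematocrit": self.hematocrit,
            "albumin_ratio": self.albumin_ratio,
            "agp_ratio": self.agp_ratio,
            "gfr_ratio": self.gfr_ratio,
            "cardiac_output_l_per_h": self.cardiac_output_l_per_h,
        }
        for name, organ in self.organs.items():
            key = name.replace(" ", "_").replace("-", "_")
            row[f"volume_{key}_l"] = organ.volume_l
            row[f"flow_{key}_l_per_h"] = organ.blood_flow_l_per_h
        for enz in ENZYMES:
            row[f"abundance_{enz}_umol"] = self.enzyme_abundance_umol[enz]
            row[f"activity_{enz}"] = self.enzyme_activity[enz]
        return row


def _load_organ_table() -> dict[str, OrganSpec]:
    text = read_text("reference_physiology.csv")
    organs: dict[str, OrganSpec] = {}
    for line in io.StringIO(text):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("organ,"):
            continue
        parts = line.split(",")
        organs[parts[0]] = OrganSpec(
            name=parts[0],
            volume_l=float(parts[1]),
            blood_flow_l_per_h=float(parts[2]),
            f_ew=float(parts[3]),
            f_iw=float(parts[4]),
            f_nl=float(parts[5]),
            f_np=float(parts[6]),
            ap_mg_per_g=float(parts[7]),
            albumin_ratio=float(parts[8]),
            lipoprotein_ratio=float(parts[9]),
        )
    missing = set(ORGAN_NAMES) - set(organs)
    if missing:
        raise RuntimeError(f"packaged physiology table is missing {missing}")
    return organs


def build_reference_adult(
    weight_kg: float = 73.0, age_years: float = 30.0
) -> ReferenceIndividual:
    """Construct a healthy adult scaled from the packaged 73 kg reference.

    Organ volumes scale as weight/73, blood flows as (weight/73)^0.75, and
    whole-liver enzyme amounts follow liver mass (linear in weight).
    """
    if not 30.0 <= weight_kg <= 200.0:
        raise ValueError(f"weight {weight_kg} kg outside supported range [30, 200]")
    if not 18.0 <= age_years <= 90.0:
        raise ValueError(f"age {age_years} y outside supported range [18, 90]")

    scalars = yaml.safe_load(read_text("reference_adult.yaml"))
    vol_scale = weight_kg / REFERENCE_WEIGHT_KG
    flow_scale = vol_scale ** 0.75

    organs = {
        name: replace(
            organ,
            volume_l=organ.volume_l * vol_scale,
            blood_flow_l_per_h=organ.blood_flow_l_per_h * flow_scale,
        )
        for name, organ in _load_organ_table().items()
    }
    abundance = {
        enz: amount * vol_scale
        for enz, amount in scalars["enzyme_abundance_umol"].items()
    }
    return ReferenceIndividual(
        weight_kg=weight_kg,
        age_years=age_years,
        organs=organs,
        hematocrit=scalars["hematocrit"],
        albumin_ratio=scalars["albumin_ratio"],
        agp_ratio=scalars["agp_ratio"],
        gfr_ratio=scalars["gfr_ratio"],
        enzyme_abundance_umol=abundance,
        enzyme_activity={enz: 1.0 for enz in ENZYMES},
    )


DEFAULT_VARIABILITY = {"volume": 0.16, "flow": 0.16, "enzyme": 0.35}


@dataclass
class VirtualPopulation:
    individuals: list[ReferenceIndividual]
    seed: int
    variability: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individuals)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([ind.parameter_row() for ind in self.individuals])


def _lognormal(rng: np.random.Generator, cv: float, size: int | None = None):
    """Mean-preserving log-normal multipliers with the given CV."""
    if cv == 0.0:
        return np.ones(size) if size else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def sample_population(
    ref: ReferenceIndividual,
    n: int,
    variability: dict[str, float] | None = None,
    seed: int = 0,
) -> VirtualPopulation:
    """Draw a virtual population around a reference individual.

    Organ volumes, regional flows, and whole-liver enzyme amounts receive
    independent mean-preserving log-normal multipliers with class-specific
    coefficients of variation (keys ``volume``, ``flow``, ``enzyme``).
    Cardiac output is re-derived from the perturbed flows so venous return
    stays exactly balanced.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    cvs = dict(DEFAULT_VARIABILITY)
    if variability is not None:
        cvs.update(variability)
    for key, cv in cvs.items():
        if cv < 0:
            raise ValueError(f"negative CV for {key!r}")

    rng = np.random.default_rng(seed)
    individuals = []
    for _ in range(n):
        ind = ref.copy()
        organs = {}
        for name, organ in ind.organs.items():
            v_mult = float(_lognormal(rng, cvs["volume"]))
            q_mult = float(_lognormal(rng, cvs["flow"]))
            organs[name] = replace(
                organ,
                volume_l=organ.volume_l * v_mult,
                blood_flow_l_per_h=organ.blood_flow_l_per_h
                * (q_mult if name not in BLOOD_POOLS else 1.0),
            )
        # lung carries the full cardiac output in series
        co = sum(
            o.blood_flow_l_per_h for nm, o in organs.items()
            if nm != "lung" and nm not in BLOOD_POOLS
        )
        organs["lung"] = replace(organs["lung"], blood_flow_l_per_h=co)
        ind.organs = organs
        ind.enzyme_abundance_umol = {
            enz: amount * float(_lognormal(rng, cvs["enzyme"]))
            for enz, amount in ind.enzyme_abundance_umol.items()
        }
        individuals.append(ind)
    return VirtualPopulation(individuals=individuals, seed=seed, variability=cvs)


@dataclass(frozen=True)
class ChildPughScalers:
    """Multiplicative pathophysiology of chronic liver disease (one grade).

    All fields are fractions of healthy-control values; hematocrit is carried
    as a fraction of the reference hematocrit (the packaged table stores the
    absolute value and the loader divides by the 0.45 reference).
    """

    grade: str
    portal_vein_flow: float
    hepatic_artery_flow: float
    renal_flow: float
    cardiac_index: float
    other_organ_flow: float
    albumin: float
    agp: float
    hematocrit: float
    functional_liver_mass: float
    gfr: float
    cyp_activity: dict[str, float]

    def __post_init__(self) -> None:
        for label in (
            "portal_vein_flow", "hepatic_artery_flow", "renal_flow",
            "cardiac_index", "other_organ_flow", "albumin", "agp",
            "hematocrit", "functional_liver_mass", "gfr",
        ):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")
        for enz, act in self.cyp_activity.items():
            if act <= 0:
                raise ValueError(f"{enz} activity must be positive")

    @classmethod
    def identity(cls, grade: str = "A") -> "ChildPughScalers":
        return cls(
            grade=grade, portal_vein_flow=1.0, hepatic_artery_flow=1.0,
            renal_flow=1.0, cardiac_index=1.0, other_organ_flow=1.0,
            albumin=1.0, agp=1.0, hematocrit=1.0, functional_liver_mass=1.0,
            gfr=1.0, cyp_activity={enz: 1.0 for enz in ENZYMES},
        )

    @classmethod
    def from_grade(cls, grade: str) -> "ChildPughScalers":
        """Load the packaged liver-disease scaler table for grade A, B or C."""
        grade = grade.upper()
        if grade not in ("A", "B", "C"):
            raise ValueError(f"unknown Child-Pugh grade {grade!r}")
        col = {"A": "cp_a", "B": "cp_b", "C": "cp_c"}[grade]
        from .datasets import packaged_tables

        table = packaged_tables()["table3"].set_index("parameter")[col]
        cyp = {
            enz: float(table[f"{enz.lower()}_activity"]) for enz in ENZYMES
        }
        return cls(
            grade=grade,
            portal_vein_flow=float(table["portal_vein_flow"]),
            hepatic_artery_flow=float(table["hepatic_artery_flow"]),
            renal_flow=float(table["renal_flow"]),
            cardiac_index=float(table["cardiac_index"]),
            other_organ_flow=float(table["other_organ_flow"]),
            albumin=float(table["albumin"]),
            agp=float(table["agp"]),
            hematocrit=float(table["hematocrit"]) / _REFERENCE_HEMATOCRIT,
            functional_liver_mass=float(table["functional_liver_mass"]),
            gfr=float(table["gfr"]),
            cyp_activity=cyp,
        )


def apply_child_pugh(
    ind: ReferenceIndividual, scalers: ChildPughScalers
) -> ReferenceIndividual:
    """Return a new individual with one grade of liver disease applied.

    Flows are scaled per category (portal organs, hepatic artery, kidney,
    everything else); cardiac output follows the cardiac-index scaler, with
    the residual between the scaled regional flows and the scaled cardiac
    output absorbed by a common re-normalisation of the "other organs" flow
    group so that venous return stays exactly balanced and every flow stays
    positive. Liver volume shrinks with functional mass; albumin, AGP,
    hematocrit and GFR follow their scalers; per-CYP activity multipliers are
    applied on top of healthy activity. The input individual is not modified.
    """
    if ind.child_pugh_grade is not None:
        raise ValueError(
            "individual already carries Child-Pugh scaling "
            f"(grade {ind.child_pugh_grade}); refusing to apply twice"
        )
    for enz, act in ind.enzyme_activity.items():
        if act != 1.0:
            raise ValueError(f"{enz}: expected healthy activity 1.0, got {act}")

    out = ind.copy()
    co_target = ind.cardiac_output_l_per_h * scalers.cardiac_index

    fixed: dict[str, float] = {}
    for name in PORTAL_ORGANS:
        fixed[name] = ind.organs[name].blood_flow_l_per_h * scalers.portal_vein_flow
    fixed["liver"] = ind.organs["liver"].blood_flow_l_per_h * scalers.hepatic_artery_flow
    fixed["kidney"] = ind.organs["kidney"].blood_flow_l_per_h * scalers.renal_flow

    other_base = sum(
        ind.organs[name].blood_flow_l_per_h for name in OTHER_FLOW_ORGANS
    )
    other_target = co_target - sum(fixed.values())
    if other_target <= 0:
        raise ValueError("scaled flows exceed scaled cardiac output")
    other_factor = other_target / other_base

    organs = {}
    for name, organ in ind.organs.items():
        if name in fixed:
            q = fixed[name]
        elif name in OTHER_FLOW_ORGANS:
            q = organ.blood_flow_l_per_h * other_factor
        elif name == "lung":
            q = co_target
        else:  # blood pools
            q = 0.0
        vol = organ.volume_l * (
            scalers.functional_liver_mass if name == "liver" else 1.0
        )
        organs[name] = replace(organ, volume_l=vol, blood_flow_l_per_h=q)

    out.organs = organs
    out.albumin_ratio = ind.albumin_ratio * scalers.albumin
    out.agp_ratio = ind.agp_ratio * scalers.agp
    out.hematocrit = ind.hematocrit * scalers.hematocrit
    out.gfr_ratio = ind.gfr_ratio * scalers.gfr
    out.enzyme_activity = {
        enz: ind.enzyme_activity[enz] * scalers.cyp_activity.get(enz, 1.0)
        for enz in ind.enzyme_activity
    }
    out.child_pugh_grade = scalers.grade
    return out


def scale_fraction_unbound(fu_ref: float, albumin_ratio: float) -> float:
    """Plasma fraction unbound under altered albumin (single binding protein).

    fu' = 1 / (1 + albumin_ratio * (1 - fu_ref) / fu_ref): lowering the
    binding-protein concentration raises the unbound fraction; at control
    albumin the value is unchanged.
    """
    if not 0.0 < fu_ref <= 1.0:
        raise ValueError("fu_ref must lie in (0, 1]")
    if albumin_ratio <= 0:
        raise ValueError("albumin_ratio must be positive")
    return 1.0 / (1.0 + albumin_ratio * (1.0 - fu_ref) / fu_ref)
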