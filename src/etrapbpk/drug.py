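"""Drug physicochemistry: ionization, tissue partitioning, permeability.

Tissue-to-plasma partition coefficients follow the Rodgers-Rowland
composition-based method for monoprotic acids and neutrals: the drug
distributes into tissue water (with a Henderson-Hasselbalch ionization
correction between plasma pH 7.4 and intracellular pH 7.0), into neutral
lipid and neutral phospholipid in proportion to the octanol-water partition
of the neutral species, and binds to tissue albumin in proportion to the
tissue-to-plasma albumin ratio and the residual plasma binding not explained
by plasma lipids. Adipose uses the vegetable-oil:water partition proxy
log P_vow = 1.115 log P - 1.35, as is conventional for that method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ._resources import read_text
from .physiology import OrganSpec, BLOOD_POOLS

__all__ = [
    "DrugParameters",
    "PartitionSet",
    "fraction_neutral",
    "tissue_partition_coefficient",
    "build_partition_set",
    "cellular_permeability",
    "load_drug",
    "PLASMA_PH",
    "INTRACELLULAR_PH",
]

PLASMA_PH = 7.4
INTRACELLULAR_PH = 7.0
#: plasma composition used by the partitioning method
PLASMA_F_NL = 0.00147
PLASMA_F_NP = 0.00083


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and binding parameters of one small-molecule drug."""

    name: str
    molecular_weight: float          # g/mol, for mass/mole conversion
    effective_molecular_weight: float  # g/mol, size term of permeability law
    log_lipophilicity: float         # log10 octanol-water partition
    pka: float
    acid_base_type: str              # 'acid' | 'base' | 'neutral'
    solubility_mg_per_ml: float
    fraction_unbound: float
    blood_to_plasma_ratio: float
    intestinal_permeability_cm_per_min: float
    dissolution_t50_min: float
    dissolution_shape: float = 1.0
    enzyme_clint_ul_per_min_per_pmol: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_unbound <= 1.0:
            raise ValueError("fraction_unbound must lie in (0, 1]")
        if not 0.0 < self.blood_to_plasma_ratio < 5.0:
            raise ValueError("blood_to_plasma_ratio must lie in (0, 5)")
        for label in (
            "molecular_weight", "effective_molecular_weight",
            "solubility_mg_per_ml", "intestinal_permeability_cm_per_min",
            "dissolution_t50_min", "dissolution_shape",
        ):
            if getattr(self, label) <= 0:
                raise ValueError(f"{label} must be positive")
        if self.acid_base_type not in ("acid", "base", "neutral"):
            raise ValueError(f"unknown acid/base type {self.acid_base_type!r}")

    @property
    def erythrocyte_partition(self) -> float:
        """Blood-cell-to-plasma partition implied by B:P at hematocrit 0.45."""
        hct = 0.45
        return (self.blood_to_plasma_ratio - (1.0 - hct)) / hct

    def blood_to_plasma_at(self, hematocrit: float) -> float:
        """B:P ratio recomposed at a different hematocrit."""
        return (1.0 - hematocrit) + self.erythrocyte_partition * hematocrit


class PartitionSet(dict):
    """Mapping organ name -> tissue:plasma partition coefficient Kp."""

    def __setitem__(self, key: str, value: float) -> None:
        if not value > 0 or value != value or value == float("inf"):
            raise ValueError(f"Kp for {key!r} must be finite and positive")
        super().__setitem__(key, value)


def load_drug(name_or_path: str = "etrasimod") -> DrugParameters:
    """Load a drug parameter config (packaged name or a YAML file path)."""
    if name_or_path.endswith((".yaml", ".yml")):
        with open(name_or_path) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(read_text(f"{name_or_path}.yaml"))
    return DrugParameters(
        name=cfg["name"],
        molecular_weight=cfg["molecular_weight_g_per_mol"],
        effective_molecular_weight=cfg["effective_molecular_weight_g_per_mol"],
        log_lipophilicity=cfg["log_lipophilicity"],
        pka=cfg["pka"],
        acid_base_type=cfg["acid_base_type"],
        solubility_mg_per_ml=cfg["solubility_mg_per_ml"],
        fraction_unbound=cfg["fraction_unbound"],
        blood_to_plasma_ratio=cfg["blood_to_plasma_ratio"],
        intestinal_permeability_cm_per_min=cfg["intestinal_permeability_cm_per_min"],
        dissolution_t50_min=cfg["dissolution_t50_min"],
        dissolution_shape=cfg.get("dissolution_shape", 1.0),
        enzyme_clint_ul_per_min_per_pmol=dict(
            cfg.get("enzyme_clint_ul_per_min_per_pmol", {})
        ),
    )


def fraction_neutral(ph: float, pka: float, acid_base_type: str) -> float:
    """Neutral (un-ionized) fraction of a monoprotic species at a given pH."""
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    if acid_base_type == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if acid_base_type == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if acid_base_type == "neutral":
        return 1.0
    raise ValueError(f"unknown acid/base type {acid_base_type!r}")


def _ionization_factor(ph: float, drug: DrugParameters) -> float:
    """(total species)/(neutral species) at pH: 1/fraction_neutral."""
    return 1.0 / fraction_neutral(ph, drug.pka, drug.acid_base_type)


def _lipid_affinity(p_octanol: float) -> tuple[float, float]:
    """Neutral-lipid and neutral-phospholipid affinities of the neutral form."""
    return p_octanol, 0.3 * p_octanol + 0.7


def tissue_partition_coefficient(
    drug: DrugParameters,
    organ: OrganSpec,
    plasma_ph: float = PLASMA_PH,
    intracellular_ph: float = INTRACELLULAR_PH,
    fraction_unbound: float | None = None,
) -> float:
    """Tissue:plasma partition coefficient (Rodgers-Rowland, acid/neutral).

    ``fraction_unbound`` overrides the drug's plasma fu (used when binding
    proteins are altered, e.g. in liver disease); the tissue binding term
    scales with the organ's tissue-to-plasma albumin ratio.
    """
    fu = drug.fraction_unbound if fraction_unbound is None else fraction_unbound
    if not 0.0 < fu <= 1.0:
        raise ValueError("fraction unbound must lie in (0, 1]")
    if drug.acid_base_type == "base" and drug.pka > 7.0:
        raise ValueError(
            "the acid/neutral partition branch does not apply to strong bases"
        )

    x = _ionization_factor(plasma_ph, drug)        # plasma total/neutral
    y = _ionization_factor(intracellular_ph, drug)  # cell-water total/neutral

    p = 10.0 ** drug.log_lipophilicity
    p_tissue = (
        10.0 ** (1.115 * drug.log_lipophilicity - 1.35)
        if organ.name == "adipose"
        else p
    )
    nl_aff, np_aff = _lipid_affinity(p_tissue)
    nl_aff_plasma, np_aff_plasma = _lipid_affinity(p)

    plasma_lipid = (nl_aff_plasma * PLASMA_F_NL + np_aff_plasma * PLASMA_F_NP) / x
    protein_binding = (1.0 / fu) - 1.0 - plasma_lipid
    if protein_binding < 0 and organ.albumin_ratio > 0:
        raise ValueError(
            f"{organ.name}: plasma lipid partitioning already exceeds total "
            "plasma binding; albumin binding term would be negative"
        )

    kpu = (
        organ.f_ew
        + (y / x) * organ.f_iw
        + (nl_aff * organ.f_nl + np_aff * organ.f_np) / x
        + protein_binding * organ.albumin_ratio
    )
    kp = kpu * fu
    if not kp > 0:
        raise ValueError(f"{organ.name}: non-positive Kp")
    return kp


def build_partition_set(
    drug: DrugParameters,
    organs: dict[str, OrganSpec],
    fraction_unbound: float | None = None,
) -> PartitionSet:
    """Kp for every perfused (non-blood) organ of an individual."""
    kps = PartitionSet()
    for name, organ in organs.items():
        if name in BLOOD_POOLS:
            continue
        kps[name] = tissue_partition_coefficient(
            drug, organ, fraction_unbound=fraction_unbound
        )
    return kps


def cellular_permeability(drug: DrugParameters) -> float:
    """Passive transcellular permeability (cm/min).

    P = a * 10^logP * MW_eff^(-b) with packaged constants; the prefactor is
    anchored so the law reproduces the reported intestinal permeability of
    etrasimod, making the two permeabilities mutually consistent.
    """
    from .config import calibration_constants

    cal = calibration_constants()
    return (
        cal["permeability_a"]
        * 10.0 ** drug.log_lipophilicity
        * drug.effective_molecular_weight ** (-cal["permeability_b"])
    )
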