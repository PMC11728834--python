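"""Packaged study tables and the synthetic concentration-profile generator.

The packaged tables carry the published anchors the model is verified
against: observed clinical PK by regimen, the drug-parameter inputs, the
liver-disease physiology scalers, the drug-interaction exposure table and
the hepatic-impairment exposure table. The synthetic generator produces
trial-like noisy concentration profiles (multiplicative log-normal residual
error around a known truth) so recovery of NCA parameters can be tested
without any digitized observations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml

from ._resources import read_text

__all__ = [
    "packaged_tables",
    "SyntheticProfileSpec",
    "generate_observed_like_profile",
]


def _read_csv(name: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(read_text(name)), comment="#")


def _table2() -> pd.DataFrame:
    """Drug-parameter input table assembled from the packaged drug configs."""
    drug = yaml.safe_load(read_text("etrasimod.yaml"))
    flu = yaml.safe_load(read_text("fluconazole.yaml"))
    rif = yaml.safe_load(read_text("rifampicin.yaml"))
    rows = [
        ("molecular_weight", "g/mol", drug["molecular_weight_g_per_mol"]),
        ("effective_molecular_weight", "g/mol",
         drug["effective_molecular_weight_g_per_mol"]),
        ("lipophilicity", "log units", drug["log_lipophilicity"]),
        ("pka", "", drug["pka"]),
        ("solubility", "mg/mL", drug["solubility_mg_per_ml"]),
        ("fraction_unbound", "%", drug["fraction_unbound"] * 100.0),
        ("blood_to_plasma_ratio", "", drug["blood_to_plasma_ratio"]),
        ("intestinal_permeability", "cm/min",
         drug["intestinal_permeability_cm_per_min"]),
        ("dissolution_t50", "min", drug["dissolution_t50_min"]),
    ]
    for enz, v in drug["enzyme_clint_ul_per_min_per_pmol"].items():
        rows.append((f"clint_{enz}", "uL/min/pmol", v))
    for enz, ki in flu["ki_umol_per_l"].items():
        rows.append((f"ki_fluconazole_{enz}", "umol/L", ki))
    for enz, spec in rif["induction"].items():
        rows.append((f"ec50_rifampicin_{enz}", "umol/L", spec["ec50_umol_per_l"]))
        rows.append((f"emax_rifampicin_{enz}", "", spec["emax"]))
    return pd.DataFrame(rows, columns=["parameter", "unit", "value"])


@lru_cache(maxsize=None)
def packaged_tables() -> dict[str, pd.DataFrame]:
    """All packaged study tables, keyed 'table1' .. 'table5'.

    Every resource is integrity-checked (SHA-256) at load; a corrupted file
    raises instead of silently parameterizing a simulation.
    """
    return {
        "table1": _read_csv("table1_clinical_pk.csv"),
        "table2": _table2(),
        "table3": _read_csv("table3_child_pugh.csv"),
        "table4": _read_csv("table4_ddi.csv"),
        "table5": _read_csv("table5_hepatic.csv"),
    }


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for a trial-like noisy concentration profile.

    Either supply one-compartment truth parameters (``ka_per_h``,
    ``volume_l``, ``clearance_l_per_h``, ``dose_mg``) or a reference
    simulation (``reference_time_h``, ``reference_conc``); the residual
    error is proportional log-normal with median 1 and the stated CV.
    """

    sampling_times_h: tuple[float, ...]
    residual_cv: float = 0.15
    seed: int = 0
    dose_mg: float | None = None
    ka_per_h: float | None = None
    volume_l: float | None = None
    clearance_l_per_h: float | None = None
    reference_time_h: tuple[float, ...] | None = None
    reference_conc: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.residual_cv < 0:
            raise ValueError("residual CV must be >= 0")
        times = np.asarray(self.sampling_times_h)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        analytic = all(
            v is not None for v in
            (self.dose_mg, self.ka_per_h, self.volume_l, self.clearance_l_per_h)
        )
        reference = (
            self.reference_time_h is not None and self.reference_conc is not None
        )
        if not (analytic or reference):
            raise ValueError(
                "supply one-compartment truth parameters or a reference profile"
            )

    def truth(self) -> np.ndarray:
        """Noiseless concentration (ng/mL) at the sampling times."""
        t = np.asarray(self.sampling_times_h, dtype=float)
        if self.reference_time_h is not None:
            return np.interp(
                t, np.asarray(self.reference_time_h),
                np.asarray(self.reference_conc),
            )
        ka = self.ka_per_h
        k = self.clearance_l_per_h / self.volume_l
        if abs(ka - k) < 1e-12:
            mg_per_l = self.dose_mg / self.volume_l * ka * t * np.exp(-ka * t)
        else:
            mg_per_l = (
                self.dose_mg * ka / (self.volume_l * (ka - k))
                * (np.exp(-k * t) - np.exp(-ka * t))
            )
        return mg_per_l * 1000.0  # mg/L -> ng/mL


def generate_observed_like_profile(
    spec: SyntheticProfileSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noisy profile plus its noiseless truth: (time_h, observed, truth).

    Residual error multiplies each sample by an independent log-normal
    deviate with median 1 and the spec's CV, the standard proportional
    error model for digitized PK observations.
    """
    t = np.asarray(spec.sampling_times_h, dtype=float)
    truth = spec.truth()
    if spec.residual_cv == 0:
        return t, truth.copy(), truth
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log(1.0 + spec.residual_cv ** 2))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=t.size)
    return t, truth * noise, truth
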