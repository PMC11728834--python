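"""Hepatic-impairment exposure simulation and dose-reduction selection.

A healthy virtual population is built once per scenario; the grade's
liver-disease scalers are applied to each member, a single oral dose is
simulated, and per-individual AUC_inf values are summarized. Dose selection
walks a candidate grid downward from the standard 2 mg dose and picks the
candidate whose population mean exposure is closest to the simulated healthy
2 mg reference, subject to the candidate's mean +/- SE interval lying inside
the healthy population band (mean +/- SD by default); ties break toward the
lower dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .absorption import DoseRegimen
from .drug import DrugParameters, load_drug
from .engine import SolverSettings, simulate_population
from .physiology import (
    ChildPughScalers,
    apply_child_pugh,
    build_reference_adult,
    sample_population,
)

__all__ = [
    "ExposureDistribution",
    "DoseRecommendation",
    "simulate_cp_exposure",
    "optimize_dose",
    "box_whisker_summary",
    "DEFAULT_CANDIDATE_DOSES",
]

DEFAULT_CANDIDATE_DOSES = (2.0, 1.75, 1.5, 1.25, 1.0)
STANDARD_DOSE_MG = 2.0


@dataclass
class ExposureDistribution:
    """Per-individual AUC_inf values for one grade and dose."""

    grade: str                 # 'healthy' | 'A' | 'B' | 'C'
    dose_mg: float
    auc_values: np.ndarray     # ng*h/mL, one per individual

    def __post_init__(self) -> None:
        self.auc_values = np.asarray(self.auc_values, dtype=float)
        if self.auc_values.size < 2:
            raise ValueError("need at least 2 individuals for a SE")

    @property
    def mean(self) -> float:
        return float(self.auc_values.mean())

    @property
    def sd(self) -> float:
        return float(self.auc_values.std(ddof=1))

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.auc_values.size)


@dataclass
class DoseRecommendation:
    grade: str
    selected_dose_mg: float | None
    candidates_mg: tuple[float, ...]
    deviations: dict[float, float]       # candidate -> |mean - healthy mean|
    overlap: dict[float, bool]           # candidate -> band criterion met
    exposures: dict[float, ExposureDistribution] = field(default_factory=dict)

    @property
    def recommended(self) -> bool:
        return self.selected_dose_mg is not None


def simulate_cp_exposure(
    grade: str,
    dose_mg: float,
    n: int = 100,
    seed: int = 0,
    drug: DrugParameters | None = None,
    variability: dict[str, float] | None = None,
    duration_h: float = 336.0,
    output_step_h: float = 1.0,
    settings: SolverSettings | None = None,
    scalers: ChildPughScalers | None = None,
) -> ExposureDistribution:
    """Population AUC_inf distribution for one Child-Pugh grade and dose.

    ``grade`` 'healthy' skips the disease scaling; otherwise the packaged
    grade scalers are applied to every member of the (seeded) healthy
    population, so healthy and impaired scenarios share their virtual
    subjects whenever the seed matches.
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if drug is None:
        drug = load_drug("etrasimod")
    ref = build_reference_adult()
    pop = sample_population(ref, n=n, variability=variability, seed=seed)
    if grade != "healthy":
        if scalers is None:
            scalers = ChildPughScalers.from_grade(grade)
        pop.individuals = [
            apply_child_pugh(ind, scalers) for ind in pop.individuals
        ]
    summary = simulate_population(
        pop, drug, regimen=DoseRegimen.single(dose_mg),
        duration_h=duration_h, output_step_h=output_step_h,
        settings=settings,
    )
    aucs = []
    for i, pk in enumerate(summary.individual_pk):
        if pk.auc_inf is None:
            raise RuntimeError(
                f"individual {i}: no reliable terminal phase for AUC_inf"
            )
        aucs.append(pk.auc_inf)
    return ExposureDistribution(grade=grade, dose_mg=dose_mg,
                                auc_values=np.array(aucs))


def optimize_dose(
    grade: str,
    healthy_reference: ExposureDistribution,
    candidates_mg=DEFAULT_CANDIDATE_DOSES,
    n: int | None = None,
    seed: int | None = None,
    band: str = "sd",
    **simulate_kwargs,
) -> DoseRecommendation:
    """Grid-search the dose matching impaired exposure to the healthy 2 mg.

    Each candidate is simulated for the grade's population; a candidate
    qualifies when its mean +/- SE interval overlaps the healthy band
    (``band`` 'sd': healthy mean +/- SD; 'se': healthy mean +/- SE;
    'range': healthy min-max). Among qualifying candidates the one with the
    smallest absolute deviation of the mean from the healthy mean wins,
    lower dose on ties. Without any qualifying candidate no dose is
    recommended and the full deviation table is still returned.
    """
    candidates = tuple(sorted(set(candidates_mg), reverse=True))
    if not candidates:
        raise ValueError("candidate list is empty")
    if healthy_reference.dose_mg != STANDARD_DOSE_MG:
        raise ValueError("healthy reference must be at the standard 2 mg dose")
    if band not in ("sd", "se", "range"):
        raise ValueError(f"unknown band {band!r}")

    if n is None:
        n = healthy_reference.auc_values.size
    if seed is None:
        seed = 0

    h_mean = healthy_reference.mean
    if band == "sd":
        lo, hi = h_mean - healthy_reference.sd, h_mean + healthy_reference.sd
    elif band == "se":
        lo, hi = h_mean - healthy_reference.se, h_mean + healthy_reference.se
    else:
        lo = float(healthy_reference.auc_values.min())
        hi = float(healthy_reference.auc_values.max())

    deviations: dict[float, float] = {}
    overlap: dict[float, bool] = {}
    exposures: dict[float, ExposureDistribution] = {}
    for dose in candidates:
        if grade == "healthy" and dose == healthy_reference.dose_mg:
            dist = healthy_reference
        else:
            dist = simulate_cp_exposure(
                grade, dose, n=n, seed=seed, **simulate_kwargs
            )
        exposures[dose] = dist
        deviations[dose] = abs(dist.mean - h_mean)
        overlap[dose] = (dist.mean - dist.se) <= hi and (dist.mean + dist.se) >= lo

    qualifying = [d for d in candidates if overlap[d]]
    selected = None
    if qualifying:
        # ties break toward the lower dose (sort by deviation, then dose)
        selected = min(qualifying, key=lambda d: (deviations[d], d))
    return DoseRecommendation(
        grade=grade, selected_dose_mg=selected, candidates_mg=candidates,
        deviations=deviations, overlap=overlap, exposures=exposures,
    )


def box_whisker_summary(values) -> dict[str, float]:
    """Order statistics for a box-whisker display (linear quantiles)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    return {
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.median(arr)),
        "q3": float(np.percentile(arr, 75)),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "se": float(arr.std(ddof=1) / math.sqrt(arr.size)),
    }
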