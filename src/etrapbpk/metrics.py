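"""Noncompartmental analysis and model-verification statistics.

NCA uses the linear-up/log-down trapezoid for AUC to the last measurable
concentration, a terminal log-linear regression for lambda_z (best adjusted
fit over the last 3-6 points, excluding the peak), and extrapolates
AUC_inf = AUC_last + C_last/lambda_z. Verification statistics mirror
standard practice: predicted/observed fold errors, their geometric mean
(average fold error), the two-fold acceptance band, drug-interaction
exposure ratios, and percent exposure increases over a reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "DDIRatios",
    "FoldError",
    "nca",
    "ddi_ratios",
    "fold_error",
    "average_fold_error",
    "two_fold_check",
    "exposure_increase_percent",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed PK tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class PKParameters:
    auc_inf: float | None      # ng*h/mL; None when no terminal decline
    auc_last: float            # ng*h/mL
    cmax: float                # ng/mL
    tmax: float                # h
    lambda_z: float | None     # 1/h
    t_half: float | None       # h
    extrapolated_fraction: float | None
    auc_inf_reliable: bool = True

    def __post_init__(self) -> None:
        if self.auc_inf is not None and self.auc_last > 0:
            if self.auc_inf < self.auc_last:
                raise ValueError("auc_inf must be >= auc_last")


@dataclass(frozen=True)
class DDIRatios:
    aucr: float
    cmaxr: float
    t_half_r: float

    def __post_init__(self) -> None:
        for v in (self.aucr, self.cmaxr, self.t_half_r):
            if not v > 0:
                raise ValueError("ratios must be positive")


@dataclass(frozen=True)
class FoldError:
    predicted: float
    observed: float

    def __post_init__(self) -> None:
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError("predicted and observed must be positive")

    @property
    def ratio(self) -> float:
        return self.predicted / self.observed

    @property
    def within_two_fold(self) -> bool:
        return 0.5 <= self.ratio <= 2.0


def _auc_linup_logdown(t: np.ndarray, c: np.ndarray) -> float:
    """Linear trapezoid while rising, log trapezoid while falling."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0 and c1 > 0:
            auc += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            auc += dt * 0.5 * (c1 + c2)
    return auc


def _terminal_fit(t: np.ndarray, c: np.ndarray, i_max: int,
                  min_points: int = 3, max_points: int = 6):
    """lambda_z by best adjusted-R^2 log-linear fit on the terminal points."""
    pos = c > 0
    candidates = []
    n = len(t)
    for k in range(min_points, max_points + 1):
        idx = np.arange(n - k, n)
        if idx[0] <= i_max:            # never include the peak
            continue
        if not pos[idx].all():
            continue
        x, y = t[idx], np.log(c[idx])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        candidates.append((r2_adj, -slope))
    if not candidates:
        return None
    return max(candidates)[1]


def nca(time_h, conc_ng_per_ml, min_points: int = 3,
        max_points: int = 6, rel_lloq: float = 1e-6) -> PKParameters:
    """Noncompartmental parameters of one concentration-time profile.

    Samples below ``rel_lloq`` times the peak concentration are treated as
    below the quantification limit and excluded, mirroring bioanalytical
    practice (and keeping the terminal fit away from solver round-off on
    very long simulated profiles). When no reliable terminal decline can be
    fit, ``auc_inf`` is withheld (None, ``auc_inf_reliable`` False) while
    ``auc_last`` is still returned.
    """
    t = np.asarray(time_h, dtype=float)
    c = np.asarray(conc_ng_per_ml, dtype=float)
    if t.ndim != 1 or t.size != c.size:
        raise ValueError("time and concentration must be 1-D of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if (c > 0).sum() < 3:
        raise ValueError("need at least 3 positive concentrations")

    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])

    # AUC to the last quantifiable concentration
    i_last = int(np.nonzero(c > cmax * rel_lloq)[0][-1])
    auc_last = _auc_linup_logdown(t[: i_last + 1], c[: i_last + 1])

    lam = _terminal_fit(t[: i_last + 1], c[: i_last + 1], i_max,
                        min_points, max_points)
    if lam is None:
        return PKParameters(
            auc_inf=None, auc_last=auc_last, cmax=cmax, tmax=tmax,
            lambda_z=None, t_half=None, extrapolated_fraction=None,
            auc_inf_reliable=False,
        )
    tail = float(c[i_last]) / lam
    auc_inf = auc_last + tail
    return PKParameters(
        auc_inf=auc_inf, auc_last=auc_last, cmax=cmax, tmax=tmax,
        lambda_z=lam, t_half=math.log(2.0) / lam,
        extrapolated_fraction=tail / auc_inf,
    )


def ddi_ratios(treated: PKParameters, control: PKParameters) -> DDIRatios:
    """Exposure ratios with/without a perpetrator (AUC, Cmax, T1/2)."""
    for label, v in (("auc_inf", control.auc_inf), ("cmax", control.cmax),
                     ("t_half", control.t_half)):
        if not v or v <= 0:
            raise ValueError(f"control {label} must be positive")
    if treated.auc_inf is None or treated.t_half is None:
        raise ValueError("treated profile lacks a reliable terminal phase")
    return DDIRatios(
        aucr=treated.auc_inf / control.auc_inf,
        cmaxr=treated.cmax / control.cmax,
        t_half_r=treated.t_half / control.t_half,
    )


def fold_error(predicted: float, observed: float) -> FoldError:
    """Predicted-to-observed ratio for one quantity."""
    return FoldError(predicted=predicted, observed=observed)


def average_fold_error(pairs) -> float:
    """Geometric mean of predicted/observed ratios (AFE)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (predicted, observed) pair")
    logs = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise ValueError("all values must be positive")
        logs.append(math.log10(pred / obs))
    return 10.0 ** (sum(logs) / len(logs))


def two_fold_check(pairs) -> tuple[float, list[bool]]:
    """Flag each predicted/observed pair against the [0.5, 2] band."""
    flags = [fold_error(p, o).within_two_fold for p, o in pairs]
    if not flags:
        raise ValueError("need at least one pair")
    return sum(flags) / len(flags), flags


def exposure_increase_percent(group_mean: float, reference_mean: float) -> float:
    """Percent increase of a group mean over the reference mean."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (group_mean / reference_mean - 1.0)
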