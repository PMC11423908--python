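"""Milk-penetration metrics.

The extent of drug passage into milk is the per-subject AUC ratio
AUC_milk / AUC_plasma (to the last quantifiable time and extrapolated to
infinity), plus time-matched milk/plasma concentration ratios at shared
nominal sampling times.  Ratios are formed per subject and summarized
geometrically, so the group ratio equals the ratio of geometric means
exactly.  Dose normalization is linear: value × ref_dose / dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import ConcProfile
from .exceptions import NotComputableError, PairingError
from .nca import NCAResults

__all__ = [
    "PenetrationResult", "penetration_ratios", "conc_ratio_at_time",
    "dose_normalize",
]


@dataclass(frozen=True)
class PenetrationResult:
    """Milk-over-plasma exposure ratios for one subject and dose."""

    subject_id: str
    dose: float
    auc_ratio_last: float
    auc_ratio_inf: float
    milk_cmax: float
    milk_tmax: float

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id, "dose": self.dose,
            "auc_ratio_last": self.auc_ratio_last,
            "auc_ratio_inf": self.auc_ratio_inf,
            "milk_cmax": self.milk_cmax, "milk_tmax": self.milk_tmax,
        }


def penetration_ratios(milk: NCAResults, plasma: NCAResults) -> PenetrationResult:
    """AUC_milk / AUC_plasma for one subject at one dose.

    Both results must come from the same subject and dose; the ratio to
    infinity is NaN when either λz fit failed.
    """
    if milk.subject_id != plasma.subject_id or milk.dose != plasma.dose:
        raise PairingError(
            f"milk ({milk.subject_id}, {milk.dose}) and plasma "
            f"({plasma.subject_id}, {plasma.dose}) do not match"
        )
    if milk.matrix != "milk" or plasma.matrix != "plasma":
        raise PairingError("arguments must be (milk, plasma) results")
    if not (plasma.auc_last > 0):
        raise PairingError("plasma AUC must be positive")
    ratio_inf = (
        milk.auc_inf / plasma.auc_inf
        if not (math.isnan(milk.auc_inf) or math.isnan(plasma.auc_inf))
        else math.nan
    )
    return PenetrationResult(
        subject_id=milk.subject_id,
        dose=milk.dose,
        auc_ratio_last=milk.auc_last / plasma.auc_last,
        auc_ratio_inf=ratio_inf,
        milk_cmax=milk.cmax,
        milk_tmax=milk.tmax,
    )


def conc_ratio_at_time(milk: ConcProfile, plasma: ConcProfile, t: float) -> float:
    """Milk/plasma concentration ratio at a shared sampled time.

    No interpolation: ``t`` must be a quantifiable sampling time in both
    matrices, otherwise :class:`NotComputableError` is raised.
    """

    def value_at(profile: ConcProfile, label: str) -> float:
        idx = np.flatnonzero(np.isclose(profile.times, t))
        if idx.size == 0:
            raise NotComputableError(f"t={t} h not sampled in {label}")
        i = int(idx[0])
        if profile.blq[i]:
            raise NotComputableError(f"{label} BLQ at t={t} h")
        return float(profile.concs[i])

    return value_at(milk, "milk") / value_at(plasma, "plasma")


def dose_normalize(value: float, dose: float, ref_dose: float) -> float:
    """Linearly rescale a dose-proportional parameter to a reference dose."""
    if not (dose > 0 and ref_dose > 0):
        raise ValueError("dose and ref_dose must be positive")
    return value * ref_dose / dose
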