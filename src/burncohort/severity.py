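"""Burn severity scores: Ryan, ABSI, Baux, and R-Baux.

Ryan counts risk factors (TBSA > 40%, age > 60 years, inhalation
injury; strict inequalities). ABSI sums points for sex, inhalation
injury, full-thickness burn, a 20-year age category, and a 10% TBSA
category. Baux is TBSA + age; R-Baux adds 17 points for inhalation
injury. APACHEII is a recorded clinical input and is never computed
here.

Fractional ages and TBSA are bucketed by value intervals matching the
integer category labels: age (0, 20] -> 1 point, (20, 40] -> 2, ...;
TBSA [1, 10] -> 1 point, (10, 20] -> 2, ... (TBSA < 1% scores 0 TBSA
points — a documented extension; the cohort minimum is 20%). The
intervals continue unbounded at the same step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SeverityScores",
    "ryan_score",
    "absi_score",
    "baux_score",
    "rbaux_score",
    "absi_category",
    "compute_scores",
    "RBAUX_INHALATION_POINTS",
]

RBAUX_INHALATION_POINTS = 17.0

# Reporting bands for ABSI; everything below 6 is grouped as "low".
ABSI_CATEGORIES = (
    (6, 7, "moderately severe"),
    (8, 9, "serious"),
    (10, 11, "severe"),
    (12, math.inf, "maximum"),
)


@dataclass
class SeverityScores:
    patient_id: str
    ryan: int
    absi: int
    baux: float
    rbaux: float
    apacheii: int  # pass-through input


def ryan_score(tbsa: float, age: float, inhalation: bool) -> int:
    """One point per risk factor: TBSA above 40%, age above 60, inhalation."""
    return int(tbsa > 40) + int(age > 60) + int(inhalation)


def _age_points(age: float) -> int:
    # (0, 20] -> 1, (20, 40] -> 2, ...; age 0 still scores 1
    return max(1, math.ceil(age / 20))


def _tbsa_points(tbsa: float) -> int:
    # [1, 10] -> 1, (10, 20] -> 2, ...; below 1% scores 0
    if tbsa < 1:
        return 0
    return math.ceil(tbsa / 10)


def absi_score(sex: str, inhalation: bool, third_degree: bool,
               age: float, tbsa: float) -> int:
    """Abbreviated Burn Severity Index point sum."""
    if sex not in ("male", "female"):
        raise ValueError(f"unrecognized sex {sex!r}")
    return (int(sex == "male") + int(inhalation) + int(third_degree)
            + _age_points(age) + _tbsa_points(tbsa))


def baux_score(tbsa: float, age: float) -> float:
    """Classic Baux: TBSA percent plus age in years."""
    return tbsa + age


def rbaux_score(tbsa: float, age: float, inhalation: bool) -> float:
    """Modified Baux: Baux plus 17 points with inhalation injury."""
    return baux_score(tbsa, age) + (RBAUX_INHALATION_POINTS if inhalation else 0.0)


def absi_category(absi: int) -> str:
    """Reporting band for an ABSI value ("moderately severe" ... "maximum")."""
    for lo, hi, label in ABSI_CATEGORIES:
        if lo <= absi <= hi:
            return label
    return "low"


def compute_scores(patient) -> SeverityScores:
    """All four scores for one :class:`~burncohort.cohort_io.PatientRecord`."""
    return SeverityScores(
        patient_id=patient.patient_id,
        ryan=ryan_score(patient.tbsa, patient.age, patient.inhalation),
        absi=absi_score(patient.sex, patient.inhalation, patient.third_degree,
                        patient.age, patient.tbsa),
        baux=baux_score(patient.tbsa, patient.age),
        rbaux=rbaux_score(patient.tbsa, patient.age, patient.inhalation),
        apacheii=patient.apacheii,
    )
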