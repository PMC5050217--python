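"""Patient and infection tables: parsing, validation, and the eligibility filter.

The cohort is adult patients with severe (>=20% TBSA) burns, an early
(<=48 h post-injury) plasma draw, and no infection recorded until at least
24 h after that draw. Two CSV inputs drive everything downstream:

``patients.csv``
    one row per enrolled subject — demographics, burn characteristics,
    timing relative to injury, plasma TNF-alpha and IL-10 (pg/mL), the
    recorded APACHEII score, and outcomes.

``infections.csv``
    one row per recorded infection — day since injury (day 0 = injury),
    infection type, infection mode, pathogen label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PatientRecord",
    "InfectionRecord",
    "EligibilityReport",
    "SchemaError",
    "ValidationError",
    "SEX_ALIASES",
    "ETIOLOGIES",
    "read_patient_table",
    "write_patient_table",
    "read_infection_table",
    "write_infection_table",
    "apply_eligibility",
]


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A row violates a field invariant."""


# Documented alias table for categorical normalization; parsing lowercases
# first, so only lowercase keys appear here.
SEX_ALIASES: Mapping[str, str] = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}

ETIOLOGIES = ("flame", "flash", "scald", "electrical", "other")


@dataclass
class PatientRecord:
    """One enrolled subject.

    Times are relative to injury: ``admission_delay_h`` and
    ``blood_draw_h`` in hours. Cytokine concentrations in pg/mL.
    ``apacheii`` is a recorded input, never computed here.
    """

    patient_id: str
    age: float
    sex: str
    bmi: float
    etiology: str
    tbsa: float
    second_degree: bool
    third_degree: bool
    inhalation: bool
    admission_delay_h: float
    blood_draw_h: float
    tnf_pg_ml: float
    il10_pg_ml: float
    apacheii: int
    icu_days: float
    died: bool
    hospital_days: float

    def validate(self) -> None:
        if not self.patient_id:
            raise ValidationError("empty patient_id")
        if not 0 <= self.tbsa <= 100:
            raise ValidationError(
                f"patient {self.patient_id}: tbsa {self.tbsa} outside [0, 100]"
            )
        if self.age < 0:
            raise ValidationError(f"patient {self.patient_id}: negative age")
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id}: unrecognized sex {self.sex!r}"
            )
        if self.etiology not in ETIOLOGIES:
            raise ValidationError(
                f"patient {self.patient_id}: unrecognized etiology {self.etiology!r}"
            )
        for name in ("admission_delay_h", "blood_draw_h", "tnf_pg_ml", "il10_pg_ml"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ValidationError(f"patient {self.patient_id}: negative {name}")


@dataclass
class InfectionRecord:
    """One recorded infection; ``day`` counts from injury (day 0)."""

    patient_id: str
    day: float
    itype: str
    mode: str
    pathogen: str = "unknown"

    def validate(self) -> None:
        if self.day < 0:
            raise ValidationError(
                f"infection for {self.patient_id}: negative day {self.day}"
            )
        if not self.itype or not self.mode:
            raise ValidationError(
                f"infection for {self.patient_id}: empty type or mode"
            )


@dataclass
class EligibilityReport:
    """Partition of the input patients into eligible and excluded.

    A patient may violate several criteria at once, so exclusion reasons
    are sets; ``eligible`` and ``exclusions`` keys never overlap and
    together cover every input patient.
    """

    eligible: list[str] = field(default_factory=list)
    exclusions: dict[str, set[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "eligible": self.eligible,
            "exclusions": {k: sorted(v) for k, v in self.exclusions.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


_PATIENT_COLUMNS = [f.name for f in dc_fields(PatientRecord)]
_INFECTION_COLUMNS = [f.name for f in dc_fields(InfectionRecord)]
_BOOL_COLUMNS = ("second_degree", "third_degree", "inhalation", "died")
_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def _parse_flag(value, column: str, pid: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"patient {pid}: cannot parse {column}={value!r} as flag")


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read and validate ``patients.csv``.

    Categorical fields are lowercased and mapped through the documented
    alias table; malformed numerics and invariant violations raise
    :class:`ValidationError`, a missing column raises :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s): {dupes}")

    records = []
    for row in df.to_dict("records"):
        pid = str(row["patient_id"])
        kwargs: dict = {"patient_id": pid}
        sex = str(row["sex"]).strip().lower()
        if sex not in SEX_ALIASES:
            raise ValidationError(f"patient {pid}: unrecognized sex {row['sex']!r}")
        kwargs["sex"] = SEX_ALIASES[sex]
        kwargs["etiology"] = str(row["etiology"]).strip().lower()
        for col in _BOOL_COLUMNS:
            kwargs[col] = _parse_flag(row[col], col, pid)
        for col in (
            "age", "bmi", "tbsa", "admission_delay_h", "blood_draw_h",
            "tnf_pg_ml", "il10_pg_ml", "icu_days", "hospital_days",
        ):
            try:
                kwargs[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"patient {pid}: malformed numeric {col}={row[col]!r}"
                ) from exc
        try:
            kwargs["apacheii"] = int(row["apacheii"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"patient {pid}: malformed apacheii={row['apacheii']!r}"
            ) from exc
        rec = PatientRecord(**kwargs)
        rec.validate()
        records.append(rec)
    return records


def write_patient_table(records: Iterable[PatientRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_PATIENT_COLUMNS)
    df.to_csv(path, index=False)


def read_infection_table(path: str | Path) -> list[InfectionRecord]:
    """Read ``infections.csv``; a missing/empty pathogen becomes "unknown"."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _INFECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for row in df.to_dict("records"):
        pathogen = row.get("pathogen")
        if pathogen is None or (isinstance(pathogen, float) and math.isnan(pathogen)) \
                or str(pathogen).strip() == "":
            pathogen = "unknown"
        rec = InfectionRecord(
            patient_id=str(row["patient_id"]),
            day=float(row["day"]),
            itype=str(row["itype"]).strip().lower(),
            mode=str(row["mode"]).strip().lower(),
            pathogen=str(pathogen).strip().lower(),
        )
        rec.validate()
        records.append(rec)
    return records


def write_infection_table(records: Iterable[InfectionRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_INFECTION_COLUMNS)
    df.to_csv(path, index=False)


def apply_eligibility(
    patients: list[PatientRecord],
    infections: list[InfectionRecord],
    *,
    max_draw_h: float = 48.0,
    min_age: float = 16.0,
    min_infection_lag_h: float = 24.0,
) -> EligibilityReport:
    """Apply the study eligibility filter and enumerate exclusion reasons.

    A patient is eligible iff ALL hold: age >= 16 years; etiology is not
    electrical; blood draw within 48 h of injury; first recorded
    infection (if any) no sooner than 24 h after the draw (boundary
    equality is eligible); at least one ICU day; all required fields
    present. Exclusion counts may overlap — reasons are reported per
    patient as a set.
    """
    first_day: dict[str, float] = {}
    for rec in infections:
        d = first_day.get(rec.patient_id)
        if d is None or rec.day < d:
            first_day[rec.patient_id] = rec.day

    from ._units import days_to_hours

    report = EligibilityReport()
    for p in patients:
        reasons: set[str] = set()
        missing = [
            f.name for f in dc_fields(PatientRecord)
            if isinstance(getattr(p, f.name), float) and math.isnan(getattr(p, f.name))
        ]
        if missing:
            reasons.add("missing:" + ",".join(missing))
        if p.age < min_age:
            reasons.add(f"age<{min_age:g}")
        if p.etiology == "electrical":
            reasons.add("electrical_burn")
        if p.blood_draw_h > max_draw_h:
            reasons.add(f"blood_draw>{max_draw_h:g}h")
        d = first_day.get(p.patient_id)
        if d is not None and days_to_hours(d) < p.blood_draw_h + min_infection_lag_h:
            reasons.add(f"infection_before_draw+{min_infection_lag_h:g}h")
        if p.icu_days < 1:
            reasons.add("icu<1day")
        if reasons:
            report.exclusions[p.patient_id] = reasons
        else:
            report.eligible.append(p.patient_id)
    return report
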