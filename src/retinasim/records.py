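"""Patient-level visit records for a hospital retinal service.

The core unit of observation is one booked appointment of one patient:
``(patient_id, condition, visit_date, visit_type, status)``.  Thirty-six
months of such rows are the raw input from which every pathway parameter
(count distributions, discharge probabilities, case mix, virtual-clinic
eligibility) is calibrated.

Conditions follow the medical-retina case mix convention: neovascular AMD,
diabetic retinopathy, and a pooled "medical retina" (MR) group that contains
retinal vein/artery occlusions and the remaining non-AMD/DR diagnoses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd


class Condition(str, enum.Enum):
    """Diagnostic group of a patient: exactly one per patient."""

    AMD = "AMD"
    DR = "DR"
    MR = "MR"  # pooled: RVO plus other non-AMD/DR medical retina


class VisitType(str, enum.Enum):
    new_referral = "new_referral"
    injection = "injection"
    injection_fu = "injection_fu"
    laser = "laser"
    laser_fu = "laser_fu"
    observation_fu = "observation_fu"
    virtual_fu = "virtual_fu"  # only under an active virtual-clinic scenario


class VisitStatus(str, enum.Enum):
    attended = "attended"
    dna = "dna"  # did not attend
    cancelled = "cancelled"


#: Activity-table row each visit type is tallied under.  Hospital and virtual
#: monitoring reviews both count as "observation" activity; new referrals are
#: tallied separately and are not part of the five-row activity breakdown.
ACTIVITY_CATEGORY = {
    VisitType.injection: "injection",
    VisitType.injection_fu: "injection_fu",
    VisitType.laser: "laser",
    VisitType.laser_fu: "laser_fu",
    VisitType.observation_fu: "observation",
    VisitType.virtual_fu: "observation",
    VisitType.new_referral: "new_referral",
}

#: The five categories of the attended-activity breakdown.
ACTIVITY_CATEGORIES = ("injection", "injection_fu", "laser", "laser_fu", "observation")

TREATMENT_TYPES = frozenset({VisitType.injection, VisitType.laser})

CSV_HEADER = ["patient_id", "condition", "visit_date", "visit_type", "status"]


@dataclass(frozen=True)
class Visit:
    date: pd.Timestamp
    vtype: VisitType
    status: VisitStatus


@dataclass
class PatientRecord:
    """One patient's dated visit history over the observation window.

    ``discharged_year`` is the care year (1-3) at the end of which the patient
    permanently left the service, or ``None`` if still under care.
    """

    patient_id: str
    condition: Condition
    visits: list[Visit] = field(default_factory=list)
    discharged_year: Optional[int] = None

    def __post_init__(self) -> None:
        dates = [v.date for v in self.visits]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visits must be sorted by date"
            )
        if self.discharged_year is not None and self.discharged_year not in (1, 2, 3):
            raise ValueError(
                f"patient {self.patient_id}: discharged_year must be 1, 2 or 3"
            )

    @property
    def treated(self) -> bool:
        """True if the patient ever had an injection or laser visit."""
        return any(v.vtype in TREATMENT_TYPES for v in self.visits)

    def attended_visits(self) -> list[Visit]:
        return [v for v in self.visits if v.status is VisitStatus.attended]

    def first_attended_date(self) -> Optional[pd.Timestamp]:
        for v in self.visits:
            if v.status is VisitStatus.attended:
                return v.date
        return None


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records to the canonical one-row-per-visit table."""
    rows = []
    for rec in records:
        dy = "" if rec.discharged_year is None else rec.discharged_year
        for v in rec.visits:
            rows.append(
                (rec.patient_id, rec.condition.value, v.date.date().isoformat(),
                 v.vtype.value, v.status.value, dy)
            )
    return pd.DataFrame(rows, columns=CSV_HEADER + ["discharged_year"])


def write_records(records: Sequence[PatientRecord], path) -> None:
    """Write records as CSV.

    Schema: ``patient_id,condition,visit_date,visit_type,status`` with
    ISO-8601 dates, plus a trailing ``discharged_year`` column (blank when the
    patient is still under care) so that a round trip preserves the record.
    """
    records_to_frame(records).to_csv(path, index=False)


def _reject(line_no: int, msg: str):
    raise ValueError(f"line {line_no}: {msg}")


def read_records(path) -> list[PatientRecord]:
    """Read and validate a patient-level record CSV.

    Malformed rows (unknown condition or visit-type labels, bad dates,
    out-of-order dates within a patient) are rejected with the offending
    1-based data line number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    has_dy = "discharged_year" in df.columns

    conditions = {c.value: c for c in Condition}
    vtypes = {t.value: t for t in VisitType}
    statuses = {s.value: s for s in VisitStatus}

    patients: dict[str, PatientRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = row.patient_id
        cond = conditions.get(row.condition)
        if cond is None:
            _reject(i, f"unknown condition label {row.condition!r}")
        vt = vtypes.get(row.visit_type)
        if vt is None:
            _reject(i, f"unknown visit type label {row.visit_type!r}")
        st = statuses.get(row.status)
        if st is None:
            _reject(i, f"unknown status label {row.status!r}")
        try:
            date = pd.Timestamp(row.visit_date)
        except ValueError:
            _reject(i, f"unparseable ISO date {row.visit_date!r}")
        dy: Optional[int] = None
        if has_dy and row.discharged_year != "":
            try:
                dy = int(float(row.discharged_year))
            except ValueError:
                _reject(i, f"bad discharged_year {row.discharged_year!r}")
        rec = patients.get(pid)
        if rec is None:
            patients[pid] = rec = PatientRecord(pid, cond, [], dy)
        else:
            if rec.condition is not cond:
                _reject(i, f"patient {pid} has conflicting condition labels")
            if rec.visits and date < rec.visits[-1].date:
                _reject(i, f"patient {pid} visit dates not sorted non-decreasing")
            if dy is not None:
                rec.discharged_year = dy
        rec.visits.append(Visit(date, vt, st))
    return list(patients.values())
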