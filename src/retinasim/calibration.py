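"""Calibration of pathway parameters from patient-level visit records.

Follows the usual modelling-package shape: ``RetinalServiceModel`` wraps a
set of patient records; ``fit()`` returns a ``CalibrationResult`` carrying
the case mix, the attended-activity breakdown, annual event-count
distributions per (condition, activity category, care year), the discharge
model, and the virtual-clinic-eligible patient set.  The result serialises
to a JSON parameter file which is the simulation engine's input contract.

Care years are patient-relative: year 1 starts at the patient's first
attended visit, and activity beyond year 3 is pooled into year 3 (year-3
parameters apply to all later years throughout the package).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import CountDistribution, fit_count_distribution
from .records import (
    ACTIVITY_CATEGORIES,
    ACTIVITY_CATEGORY,
    Condition,
    PatientRecord,
    TREATMENT_TYPES,
    VisitStatus,
    read_records,
)

CONDITIONS = (Condition.AMD, Condition.DR, Condition.MR)

#: Nominal length of a care year when bucketing visit dates.
DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CaseMix:
    """Proportion of patients in each condition group (sums to 1)."""

    proportions: dict[Condition, float]

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("case-mix proportions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return tuple(self.proportions.get(c, 0.0) for c in CONDITIONS)


@dataclass
class DischargeModel:
    """P(discharged at end of care year | condition, status, year).

    ``status`` is ``"treated"`` or ``"observation"``; the year-3 entry applies
    to every later year.  ``n_discharged``/``n_at_risk`` keep the counts the
    probabilities were estimated from.
    """

    prob: dict[tuple[Condition, str, int], float]
    n_discharged: dict[tuple[Condition, str, int], int] = field(default_factory=dict)
    n_at_risk: dict[tuple[Condition, str, int], int] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.prob.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"discharge probability out of [0,1] at {k}: {v}")

    def p(self, condition: Condition, status: str, year: int) -> float:
        return self.prob.get((condition, status, min(year, 3)), 0.0)

    @property
    def total_discharged(self) -> int:
        return sum(self.n_discharged.values())

    def cohort_share(self, status: str) -> float:
        """Discharged patients of a status as a share of the whole cohort
        (the convention the itemised discharge table's percentages use)."""
        total = sum(v for (c, s, y), v in self.n_at_risk.items() if y == 1)
        k = sum(v for (c, s, y), v in self.n_discharged.items() if s == status)
        return k / total if total else 0.0

    def status_share(self, status: str) -> float:
        """Discharged patients of a status as a share of that status group."""
        denom = sum(v for (c, s, y), v in self.n_at_risk.items()
                    if s == status and y == 1)
        k = sum(v for (c, s, y), v in self.n_discharged.items() if s == status)
        return k / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "prob": [[c.value, s, y, p] for (c, s, y), p in sorted(self.prob.items())],
            "n_discharged": [[c.value, s, y, n] for (c, s, y), n
                             in sorted(self.n_discharged.items())],
            "n_at_risk": [[c.value, s, y, n] for (c, s, y), n
                          in sorted(self.n_at_risk.items())],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DischargeModel":
        unpack = lambda rows: {(Condition(c), s, y): v for c, s, y, v in rows}
        return cls(unpack(d["prob"]), unpack(d.get("n_discharged", [])),
                   unpack(d.get("n_at_risk", [])))


class ActivityTable:
    """Attended appointments cross-tabulated by activity category and
    condition, with exact row/column totals."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame  # index: category, columns: condition values

    @property
    def condition_totals(self) -> dict[Condition, int]:
        return {c: int(self.frame[c.value].sum()) for c in CONDITIONS}

    @property
    def category_totals(self) -> dict[str, int]:
        return {cat: int(self.frame.loc[cat].sum()) for cat in self.frame.index}

    @property
    def grand_total(self) -> int:
        return int(self.frame.to_numpy().sum())

    def count(self, category: str, condition: Condition) -> int:
        return int(self.frame.loc[category, condition.value])

    def __repr__(self):
        return f"ActivityTable(total={self.grand_total})\n{self.frame}"


# ---------------------------------------------------------------------------
# operations

def _first_attended(rec: PatientRecord):
    return rec.first_attended_date()


def care_year(date: pd.Timestamp, first: pd.Timestamp, pool_at: int = 3) -> int:
    """1-based care year of a visit date, pooled at ``pool_at``."""
    y = int((date - first).days // DAYS_PER_YEAR) + 1
    return min(y, pool_at)


def count_events(records: Sequence[PatientRecord], category: str) -> pd.DataFrame:
    """Per-patient, per-care-year attended event counts for one category.

    Returns a frame with columns ``patient_id, condition, year, count``
    containing every (patient, year) cell with at least one event.  Patients
    with no attended visits at all are excluded (a warning reports how many).
    """
    if category not in set(ACTIVITY_CATEGORY.values()):
        raise ValueError(f"unknown activity category {category!r}")
    if not records:
        raise ValueError("count_events needs a non-empty record set")
    rows = []
    skipped = 0
    for rec in records:
        first = _first_attended(rec)
        if first is None:
            skipped += 1
            continue
        tally: dict[int, int] = {}
        for v in rec.attended_visits():
            if ACTIVITY_CATEGORY[v.vtype] == category:
                y = care_year(v.date, first)
                tally[y] = tally.get(y, 0) + 1
        for y in sorted(tally):
            rows.append((rec.patient_id, rec.condition.value, y, tally[y]))
    if skipped:
        warnings.warn(f"{skipped} record(s) with no attended visits excluded")
    return pd.DataFrame(rows, columns=["patient_id", "condition", "year", "count"])


def estimate_mix(records: Sequence[PatientRecord]) -> CaseMix:
    """Share of patients per condition."""
    if not records:
        raise ValueError("estimate_mix needs a non-empty record set")
    n = len(records)
    counts = {c: 0 for c in CONDITIONS}
    for rec in records:
        counts[rec.condition] += 1
    return CaseMix({c: counts[c] / n for c in CONDITIONS})


def activity_table(records: Iterable[PatientRecord]) -> ActivityTable:
    """Attended-appointment breakdown; DNA/cancelled rows are excluded."""
    data = {c.value: {cat: 0 for cat in ACTIVITY_CATEGORIES} for c in CONDITIONS}
    extra_cats: list[str] = []
    for rec in records:
        col = data[rec.condition.value]
        for v in rec.attended_visits():
            cat = ACTIVITY_CATEGORY[v.vtype]
            if cat not in col:
                for d in data.values():
                    d.setdefault(cat, 0)
                extra_cats.append(cat)
            col[cat] += 1
    index = list(ACTIVITY_CATEGORIES) + sorted(set(extra_cats))
    frame = pd.DataFrame(
        {c.value: [data[c.value].get(cat, 0) for cat in index] for c in CONDITIONS},
        index=index,
    )
    return ActivityTable(frame)


def estimate_discharge(
    records: Sequence[PatientRecord],
    window_end: Optional[pd.Timestamp] = None,
) -> DischargeModel:
    """Discharge probabilities per (condition, status, care year).

    ``prob = discharged(c,s,y) / at-risk(c,s,y)`` where a patient is at risk
    in year ``y`` if their observation span covers ``y`` care years and they
    were not discharged earlier.  A zero at-risk denominator yields
    probability 0 with a warning.
    """
    dated = [r for r in records if _first_attended(r) is not None]
    if window_end is None:
        window_end = max(v.date for r in dated for v in r.attended_visits()) \
            + pd.Timedelta(days=1)
    n_dis: dict[tuple[Condition, str, int], int] = {}
    n_risk: dict[tuple[Condition, str, int], int] = {}
    for c in CONDITIONS:
        for s in ("treated", "observation"):
            for y in (1, 2, 3):
                n_dis[(c, s, y)] = 0
                n_risk[(c, s, y)] = 0
    for rec in dated:
        s = "treated" if rec.treated else "observation"
        first = _first_attended(rec)
        observed_years = min(3, max(1, int(np.ceil(
            (window_end - first).days / DAYS_PER_YEAR))))
        dy = rec.discharged_year
        horizon = min(observed_years, dy) if dy is not None else observed_years
        for y in range(1, horizon + 1):
            n_risk[(rec.condition, s, y)] += 1
        if dy is not None and dy <= 3:
            n_dis[(rec.condition, s, dy)] += 1
    prob = {}
    for key, k in n_dis.items():
        denom = n_risk[key]
        if denom == 0:
            if k:
                warnings.warn(f"zero at-risk denominator for {key}; probability set to 0")
            prob[key] = 0.0
        else:
            prob[key] = k / denom
    return DischargeModel(prob, n_dis, n_risk)


def select_virtual_clinic_eligible(
    records: Sequence[PatientRecord], as_of: pd.Timestamp
) -> set[str]:
    """Patients suitable for diversion to a nurse-led virtual clinic.

    A patient qualifies when, as of ``as_of``: they attended at least once in
    the preceding 24 months, had no attended injection or laser visit in the
    preceding 6 months, and have not been discharged.  Both windows are
    half-open: exclusive at the old end, inclusive at ``as_of``.
    """
    as_of = pd.Timestamp(as_of)
    lo24 = as_of - pd.DateOffset(months=24)
    lo6 = as_of - pd.DateOffset(months=6)
    out = set()
    for rec in records:
        if rec.discharged_year is not None:
            continue
        attended_recent = False
        treated_recent = False
        for v in rec.attended_visits():
            if lo24 < v.date <= as_of:
                attended_recent = True
            if v.vtype in TREATMENT_TYPES and lo6 < v.date <= as_of:
                treated_recent = True
        if attended_recent and not treated_recent:
            out.add(rec.patient_id)
    return out


# ---------------------------------------------------------------------------
# model / results

#: Activity categories for which annual count distributions are fitted.
FITTED_CATEGORIES = ("injection", "injection_fu", "laser", "laser_fu", "observation")


class RetinalServiceModel:
    """Pathway-parameter model over a set of patient-level records.

    Parameters
    ----------
    records : sequence of PatientRecord
        Typically 36 months of visit history.

    ``fit()`` estimates every quantity the simulation engine needs.
    """

    def __init__(self, records: Sequence[PatientRecord]):
        if not records:
            raise ValueError("RetinalServiceModel needs a non-empty record set")
        self.records = list(records)

    @classmethod
    def from_csv(cls, path) -> "RetinalServiceModel":
        return cls(read_records(path))

    def fit(
        self,
        window_end: Optional[pd.Timestamp] = None,
        eligibility_as_of: Optional[pd.Timestamp] = None,
    ) -> "CalibrationResult":
        if window_end is None:
            window_end = max(
                (v.date for r in self.records for v in r.visits), default=None
            )
            if window_end is not None:
                window_end = window_end + pd.Timedelta(days=1)
        if eligibility_as_of is None:
            eligibility_as_of = window_end

        mix = estimate_mix(self.records)
        activity = activity_table(self.records)
        discharge = estimate_discharge(self.records, window_end=window_end)
        eligible = select_virtual_clinic_eligible(self.records, eligibility_as_of)

        dists: dict[tuple[Condition, str, int], CountDistribution] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for cat in FITTED_CATEGORIES:
                counts = count_events(self.records, cat)
                if counts.empty:
                    continue
                for (cond_label, year), grp in counts.groupby(["condition", "year"]):
                    dists[(Condition(cond_label), cat, int(year))] = \
                        fit_count_distribution(grp["count"].to_numpy())

        return CalibrationResult(
            model=self,
            case_mix=mix,
            activity=activity,
            discharge=discharge,
            count_distributions=dists,
            eligible_ids=eligible,
            window_end=window_end,
            eligibility_as_of=eligibility_as_of,
        )


@dataclass
class CalibrationResult:
    """Fitted pathway parameters; the simulation engine's input contract."""

    model: Optional[RetinalServiceModel]
    case_mix: CaseMix
    activity: ActivityTable
    discharge: DischargeModel
    count_distributions: dict[tuple[Condition, str, int], CountDistribution]
    eligible_ids: set[str]
    window_end: pd.Timestamp
    eligibility_as_of: pd.Timestamp

    @property
    def n_patients(self) -> int:
        return len(self.model.records) if self.model else 0

    def distribution(self, condition: Condition, category: str, year: int
                     ) -> Optional[CountDistribution]:
        return self.count_distributions.get((condition, category, min(year, 3)))

    def treated_share(self) -> float:
        recs = self.model.records
        return sum(r.treated for r in recs) / len(recs)

    def summary(self) -> str:
        lines = ["Retinal service calibration", "=" * 60]
        lines.append(f"Patients: {self.n_patients}   "
                     f"attended appointments: {self.activity.grand_total}")
        mix = ", ".join(f"{c.value} {p:.1%}" for c, p in
                        zip(CONDITIONS, self.case_mix.as_tuple()))
        lines.append(f"Case mix: {mix}")
        lines.append(f"Treated (ever injected/lasered): {self.treated_share():.1%}")
        lines.append(
            "Discharged: "
            f"{self.discharge.total_discharged} patients "
            f"(treated {self.discharge.cohort_share('treated'):.0%}, "
            f"observation {self.discharge.cohort_share('observation'):.0%} "
            "of cohort)")
        lines.append(f"Virtual-clinic eligible at "
                     f"{self.eligibility_as_of.date()}: {len(self.eligible_ids)}")
        lines.append("")
        lines.append("Activity (attended):")
        lines.append(self.activity.frame.to_string())
        lines.append("")
        lines.append("Fitted annual count distributions (condition, category, year):")
        for (c, cat, y), d in sorted(self.count_distributions.items(),
                                     key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])):
            lines.append(f"  {c.value:3s} {cat:13s} year {y}: {d.family:9s} "
                         f"mean {d.mean:5.2f} sd {d.sd:5.2f}")
        return "\n".join(lines)

    def to_json(self, path=None):
        doc = {
            "case_mix": {c.value: p for c, p in self.case_mix.proportions.items()},
            "activity": self.activity.frame.to_dict(),
            "discharge": self.discharge.to_dict(),
            "count_distributions": [
                [c.value, cat, y, d.to_dict()]
                for (c, cat, y), d in sorted(
                    self.count_distributions.items(),
                    key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2]))
            ],
            "eligible_ids": sorted(self.eligible_ids),
            "window_end": str(self.window_end.date()),
            "eligibility_as_of": str(self.eligibility_as_of.date()),
        }
        if path is None:
            return json.dumps(doc, indent=1)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return None

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            doc = json.load(fh)
        frame = pd.DataFrame(doc["activity"])
        return cls(
            model=None,
            case_mix=CaseMix({Condition(c): p for c, p in doc["case_mix"].items()}),
            activity=ActivityTable(frame),
            discharge=DischargeModel.from_dict(doc["discharge"]),
            count_distributions={
                (Condition(c), cat, y): CountDistribution.from_dict(d)
                for c, cat, y, d in doc["count_distributions"]
            },
            eligible_ids=set(doc["eligible_ids"]),
            window_end=pd.Timestamp(doc["window_end"]),
            eligibility_as_of=pd.Timestamp(doc["eligibility_as_of"]),
        )
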