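"""Money and KPIs: tariffs, monthly-average reports, scenario comparison.

A simulation trace becomes a ``KPIReport`` of monthly averages — activity
(new attendances, follow-ups, injections), resource utilisation, and
costing/revenue/surplus — over the post-warm-up reporting window.  Scenario
reports are compared as integer percentage changes against a baseline, and
``render_table4`` lays four canonical service-design scenarios side by side
with the percentage change between the first and the fourth.

The follow-up KPI counts every visit that delivers a follow-up assessment:
standalone hospital follow-up visits plus injection visits that carry the
assessment under a combined-assessment (treat-and-extend) regimen.  Virtual
clinic reviews are reported separately (``virtual_followups``), so the
headline follow-up figure is hospital workload.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import VisitType

#: KPI keys in canonical presentation order.
KPI_KEYS = (
    "new_attendances",
    "followups",
    "util_clinic_session",
    "util_nurse",
    "util_consultation_room",
    "util_injection_bed",
    "n_injections",
    "costing",
    "revenue",
    "surplus",
)

KPI_LABELS = {
    "new_attendances": "New attendances",
    "followups": "Follow-ups",
    "util_clinic_session": "Clinic session utilisation",
    "util_nurse": "Nurse utilisation",
    "util_consultation_room": "Consultation room utilisation",
    "util_injection_bed": "Injection bed utilisation",
    "n_injections": "Number of Anti-VEGF injections",
    "costing": "Costing",
    "revenue": "Revenue",
    "surplus": "Surplus",
}

_FU_TYPES = {VisitType.injection_fu.value, VisitType.laser_fu.value,
             VisitType.observation_fu.value}


@dataclass
class TariffTable:
    """Per-visit revenue and cost (GBP).

    ``cost_per_visit`` holds component breakdowns (staff/drug/facility);
    ``virtual_fu_cost`` is the all-in cost of a virtual-clinic review, within
    the £30-45 band quoted for community review services.
    """

    revenue_per_visit: dict[VisitType, float]
    cost_per_visit: dict[VisitType, dict[str, float]]
    virtual_fu_cost: float = 37.5

    def __post_init__(self):
        if not 30.0 <= self.virtual_fu_cost <= 45.0:
            raise ValueError("virtual_fu_cost must lie in the £30-45 band")
        for v in self.revenue_per_visit.values():
            if v < 0:
                raise ValueError("negative revenue entry")
        for comp in self.cost_per_visit.values():
            if any(x < 0 for x in comp.values()):
                raise ValueError("negative cost component")

    def revenue(self, vtype: VisitType) -> float:
        return float(self.revenue_per_visit.get(vtype, 0.0))

    def cost(self, vtype: VisitType) -> float:
        if vtype is VisitType.virtual_fu:
            return float(self.virtual_fu_cost)
        return float(sum(self.cost_per_visit.get(vtype, {}).values()))

    @classmethod
    def default(cls) -> "TariffTable":
        from .config import default_tariffs
        return default_tariffs()


@dataclass
class KPIReport:
    """Monthly-average KPIs of one scenario (pooled over replications)."""

    scenario: str
    new_attendances: float = 0.0
    followups: float = 0.0
    virtual_followups: float = 0.0
    n_injections: float = 0.0
    utilisation: dict[str, float] = field(default_factory=dict)
    costing: float = 0.0
    revenue: float = 0.0
    surplus: float = 0.0
    overflows: float = 0.0
    replications: int = 1
    horizon_months: int = 12

    def __post_init__(self):
        for pool, u in self.utilisation.items():
            if not -1e-9 <= u <= 1.0 + 1e-9:
                raise ValueError(f"utilisation of {pool} outside [0,1]: {u}")
        if abs(self.surplus - (self.revenue - self.costing)) > 1.0:
            raise ValueError(
                f"accounting identity violated: surplus {self.surplus} vs "
                f"revenue - costing {self.revenue - self.costing}")

    def kpis(self) -> dict[str, float]:
        out = {}
        for key in KPI_KEYS:
            if key.startswith("util_"):
                out[key] = float(self.utilisation.get(key[5:], 0.0))
            else:
                out[key] = float(getattr(self, key))
        return out

    @classmethod
    def from_kpis(cls, scenario: str, kpis: dict[str, float], **kw) -> "KPIReport":
        util = {k[5:]: v for k, v in kpis.items() if k.startswith("util_")}
        plain = {k: v for k, v in kpis.items() if not k.startswith("util_")}
        return cls(scenario=scenario, utilisation=util, **plain, **kw)


def kpi_from_trace(trace, tariffs: TariffTable) -> KPIReport:
    """Monthly-average KPIs of one replication's trace (warm-up excluded)."""
    months = trace.reported_months
    n_rep = len(months)
    v = trace.visits
    if len(v) == 0:
        util = {p: 0.0 for p in trace.busy}
        return KPIReport(scenario=trace.scenario, utilisation=util,
                         horizon_months=n_rep)
    in_window = v["month"].isin(set(months.tolist()))
    att = v[(v["outcome"] == "attended") & in_window]

    new_att = int((att["visit_type"] == VisitType.new_referral.value).sum())
    fus = int(att["visit_type"].isin(_FU_TYPES).sum()
              + ((att["visit_type"] == VisitType.injection.value)
                 & att["assessment"]).sum())
    virt = int((att["visit_type"] == VisitType.virtual_fu.value).sum())
    n_inj = int((att["visit_type"] == VisitType.injection.value).sum())
    over = int(((v["outcome"] == "overflow") & in_window).sum())

    revenue = float(sum(tariffs.revenue(VisitType(t)) for t in att["visit_type"]))
    costing = float(sum(tariffs.cost(VisitType(t)) for t in att["visit_type"]))

    util = {pool: trace.utilisation(pool) for pool in trace.busy}
    return KPIReport(
        scenario=trace.scenario,
        new_attendances=new_att / n_rep,
        followups=fus / n_rep,
        virtual_followups=virt / n_rep,
        n_injections=n_inj / n_rep,
        utilisation=util,
        costing=costing / n_rep,
        revenue=revenue / n_rep,
        surplus=(revenue - costing) / n_rep,
        overflows=over / n_rep,
        replications=1,
        horizon_months=n_rep,
    )


def pool_reports(reports: Sequence[KPIReport], name: Optional[str] = None) -> KPIReport:
    """Average KPI reports over replications (linearity of monthly means)."""
    if not reports:
        raise ValueError("no reports to pool")
    pools = sorted({p for r in reports for p in r.utilisation})
    mean = lambda attr: float(np.mean([getattr(r, attr) for r in reports]))
    return KPIReport(
        scenario=name or reports[0].scenario,
        new_attendances=mean("new_attendances"),
        followups=mean("followups"),
        virtual_followups=mean("virtual_followups"),
        n_injections=mean("n_injections"),
        utilisation={p: float(np.mean([r.utilisation.get(p, 0.0) for r in reports]))
                     for p in pools},
        costing=mean("costing"),
        revenue=mean("revenue"),
        surplus=mean("surplus"),
        overflows=mean("overflows"),
        replications=len(reports),
        horizon_months=reports[0].horizon_months,
    )


def round_half_away(x: float) -> int:
    """Integer rounding with halves away from zero (42.5 -> 43, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ComparisonTable:
    """Integer % change of an alternative scenario against a baseline;
    ``None`` marks a KPI whose baseline is zero (undefined change)."""

    baseline: str
    alternative: str
    changes: dict[str, Optional[int]]

    def __getitem__(self, key: str) -> Optional[int]:
        return self.changes[key]


def compare_scenarios(baseline: KPIReport, alternative: KPIReport) -> ComparisonTable:
    """Per-KPI percentage change, rounded half away from zero."""
    b, a = baseline.kpis(), alternative.kpis()
    if set(b) != set(a):
        raise ValueError("KPI schema mismatch between reports")
    changes: dict[str, Optional[int]] = {}
    for key in KPI_KEYS:
        if b[key] == 0:
            changes[key] = None if a[key] != 0 else 0
        else:
            changes[key] = round_half_away(100.0 * (a[key] - b[key]) / b[key])
    return ComparisonTable(baseline.scenario, alternative.scenario, changes)


class Table4:
    """Side-by-side monthly-average KPI table of the four canonical
    service-design scenarios, with % change of the combined redesign
    (virtual clinic + treat and extend) against the current service."""

    def __init__(self, frame: pd.DataFrame, comparison: ComparisonTable):
        self.frame = frame
        self.comparison = comparison

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    def to_text(self) -> str:
        return self.frame.to_string()

    def __repr__(self):
        return self.to_text()


def render_table4(reports) -> Table4:
    """Build the four-scenario comparison document.

    ``reports`` is a sequence or dict of exactly four ``KPIReport`` objects
    carrying the canonical scenario names; order does not matter (the table
    is name-keyed).  Missing or unknown names are rejected by name.
    """
    from .reference_data import SCENARIO_NAMES

    if isinstance(reports, dict):
        by_name = dict(reports)
    else:
        by_name = {r.scenario: r for r in reports}
    missing = [n for n in SCENARIO_NAMES if n not in by_name]
    if missing:
        raise ValueError(f"missing scenario report(s): {missing}")
    extra = [n for n in by_name if n not in SCENARIO_NAMES]
    if extra:
        raise ValueError(f"unknown scenario name(s): {extra}")

    comp = compare_scenarios(by_name[SCENARIO_NAMES[0]], by_name[SCENARIO_NAMES[3]])
    rows = {}
    for key in KPI_KEYS:
        label = KPI_LABELS[key]
        vals = []
        for name in SCENARIO_NAMES:
            x = by_name[name].kpis()[key]
            vals.append(f"{x:.0%}" if key.startswith("util_") else f"{x:,.0f}")
        ch = comp.changes[key]
        vals.append("n/a" if ch is None else f"{ch:d}%")
        rows[label] = vals
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SCENARIO_NAMES) + ["% change"])
    frame.index.name = "Monthly averages"
    return Table4(frame, comp)
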