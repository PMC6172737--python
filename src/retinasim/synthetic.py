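"""Synthetic patient-level visit record generator.

Generates 36-month cohorts with the exact statistical composition of the
reference service: attended-appointment counts per activity category and
condition are *allocated* cell-by-cell (not sampled), discharge counts are
hit exactly, and a requested number of patients is planted so as to satisfy
the virtual-clinic eligibility predicate (attended within the last 2 years,
no treatment visit in the last 6 months, not discharged) at window end.
Only visit dates and patient assignments are random; totals are invariant to
the seed.

Within a patient-year, events are spread at regular intervals with a +/-7
day uniform jitter, smoothing monthly workload without inventing
seasonality.  Patients whose visit history must not reach into the last 24
months (so that the planted eligible set is exact) are confined to the first
12 months of the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import reference_data as ref
from .records import (
    ACTIVITY_CATEGORIES,
    Condition,
    PatientRecord,
    Visit,
    VisitStatus,
    VisitType,
)

CONDITIONS = (Condition.AMD, Condition.DR, Condition.MR)

_CATEGORY_VISIT_TYPE = {
    "injection": VisitType.injection,
    "injection_fu": VisitType.injection_fu,
    "laser": VisitType.laser,
    "laser_fu": VisitType.laser_fu,
    "observation": VisitType.observation_fu,
}

#: Per patient-year cap on allocated events of any one category.
MAX_PER_PATIENT_YEAR = 14


def largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return [int(b) for b in base]


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``category_counts`` maps activity category -> condition -> attended
    appointment count; ``discharge_counts`` maps (condition, status, year) ->
    number of patients discharged; ``treated_counts`` fixes how many patients
    per condition ever receive an injection or laser.  ``eligible_planted``
    patients are constructed virtual-clinic-eligible at window end.
    """

    n_patients: int
    mix: dict[Condition, float]
    category_counts: dict[str, dict[Condition, int]]
    discharge_counts: dict[tuple[Condition, str, int], int] = field(default_factory=dict)
    treated_counts: Optional[dict[Condition, int]] = None
    eligible_planted: int = 0
    window_months: int = 36
    start_date: str = "2013-04-01"
    dna_rate: float = 0.05       # ASSUMED: no rate is given for the service
    cancel_rate: float = 0.03    # ASSUMED
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.n_patients and abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("mix must sum to 1")
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")
        for cat in self.category_counts:
            if cat not in ACTIVITY_CATEGORIES:
                raise ValueError(f"unknown activity category {cat!r}")

    def counts(self, cat: str, cond: Condition) -> int:
        return int(self.category_counts.get(cat, {}).get(cond, 0))


def reference_cohort_spec(seed: int = 0, eligible_planted: int | None = None) -> CohortSpec:
    """The cohort spec calibrated cell-by-cell to the reference service."""
    return CohortSpec(
        n_patients=ref.N_PATIENTS,
        mix=dict(ref.CASE_MIX),
        category_counts={k: dict(v) for k, v in ref.ACTIVITY_COUNTS.items()},
        discharge_counts=dict(ref.DISCHARGE_COUNTS),
        treated_counts=dict(ref.TREATED_COUNTS),
        eligible_planted=ref.N_VC_ELIGIBLE if eligible_planted is None else eligible_planted,
        seed=seed,
    )


class _Patient:
    __slots__ = ("idx", "cond", "treated", "discharged_year", "eligible",
                 "start_month", "years", "visits")

    def __init__(self, idx, cond):
        self.idx = idx
        self.cond = cond
        self.treated = False
        self.discharged_year = None
        self.eligible = False
        self.start_month = 0
        self.years = 1
        self.visits: list[tuple[int, VisitType, VisitStatus]] = []


def _allocate(total: int, caps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random allocation of ``total`` units over cells with caps."""
    if total == 0:
        return np.zeros(len(caps), dtype=int)
    if total > caps.sum():
        raise ValueError(
            f"infeasible spec: {total} events exceed capacity {int(caps.sum())} "
            f"({MAX_PER_PATIENT_YEAR} per patient-year)"
        )
    expanded = np.repeat(np.arange(len(caps)), caps)
    chosen = rng.choice(expanded, size=total, replace=False)
    return np.bincount(chosen, minlength=len(caps))


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a cohort of patient records matching ``spec`` exactly.

    Deterministic for a fixed seed.  Raises ``ValueError`` with a diagnostic
    when the spec is infeasible (e.g. more events than patient-year capacity,
    or discharge counts exceeding the patients available).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_patients == 0:
        if any(v for cat in spec.category_counts.values() for v in cat.values()):
            raise ValueError("infeasible spec: events requested but n_patients = 0")
        return []

    base = pd.Timestamp(spec.start_date)
    w = spec.window_months
    # day offsets of month boundaries 0 .. w (+3 years of slack for year spans)
    boundary = [(base + pd.DateOffset(months=k) - base).days for k in range(w + 37)]
    window_days = boundary[w]
    cutoff24 = boundary[w - 24] if w > 24 else 0
    last6 = boundary[w - 6] if w > 6 else 0

    n_by_cond = dict(zip(CONDITIONS, largest_remainder(
        spec.n_patients, [spec.mix.get(c, 0.0) for c in CONDITIONS])))

    treated_counts = spec.treated_counts
    if treated_counts is None:
        treated_counts = {}
        for c in CONDITIONS:
            treat_events = spec.counts("injection", c) + spec.counts("laser", c)
            t_dis = sum(spec.discharge_counts.get((c, "treated", y), 0) for y in (1, 2, 3))
            # enough patients for the events at the per-year cap, at least one
            # per discharge row, never more patients than events
            need = max(t_dis, -(-treat_events // (MAX_PER_PATIENT_YEAR * 3)))
            treated_counts[c] = min(max(need, min(treat_events, 1)), treat_events)

    patients: list[_Patient] = []
    per_cond: dict[Condition, dict] = {}
    next_idx = 0
    for c in CONDITIONS:
        n_c = n_by_cond[c]
        t_c = int(treated_counts.get(c, 0))
        treat_events = spec.counts("injection", c) + spec.counts("laser", c)
        if t_c > n_c:
            raise ValueError(f"infeasible spec: {t_c} treated > {n_c} patients for {c.value}")
        if t_c > treat_events:
            raise ValueError(
                f"infeasible spec: {t_c} treated patients for {c.value} but only "
                f"{treat_events} treatment events to give each at least one")
        if t_c == 0 and treat_events > 0:
            raise ValueError(f"infeasible spec: treatment events for {c.value} but no treated patients")
        group = [_Patient(next_idx + i, c) for i in range(n_c)]
        next_idx += n_c
        perm = rng.permutation(n_c)
        treated = [group[i] for i in perm[:t_c]]
        observ = [group[i] for i in perm[t_c:]]
        for p in treated:
            p.treated = True
        # discharge labels
        for status, pool in (("treated", treated), ("observation", observ)):
            free = list(pool)
            for y in (1, 2, 3):
                k = spec.discharge_counts.get((c, status, y), 0)
                if k > len(free):
                    raise ValueError(
                        f"infeasible spec: {k} year-{y} {status} discharges for "
                        f"{c.value} but only {len(free)} patients left")
                pick = rng.choice(len(free), size=k, replace=False) if k else []
                for i in sorted(pick, reverse=True):
                    free[i].discharged_year = y
                    del free[i]
        patients.extend(group)
        per_cond[c] = {"treated": treated, "observ": observ}

    # plant the virtual-clinic-eligible set among non-discharged observation
    # patients, apportioned across conditions by pool size
    pools = {c: [p for p in per_cond[c]["observ"] if p.discharged_year is None]
             for c in CONDITIONS}
    total_pool = sum(len(v) for v in pools.values())
    if spec.eligible_planted > total_pool:
        raise ValueError(
            f"infeasible spec: eligible_planted {spec.eligible_planted} exceeds "
            f"the {total_pool} non-discharged observation patients")
    if spec.eligible_planted and w <= 24:
        raise ValueError("infeasible spec: eligibility planting needs window_months > 24")
    if spec.eligible_planted:
        shares = largest_remainder(
            spec.eligible_planted, [len(pools[c]) for c in CONDITIONS])
        for c, k in zip(CONDITIONS, shares):
            pick = rng.choice(len(pools[c]), size=k, replace=False) if k else []
            for i in pick:
                pools[c][i].eligible = True

    # start months and active years
    for p in patients:
        if p.discharged_year is not None:
            hi = w - 12 * p.discharged_year
            p.start_month = int(rng.integers(0, hi + 1))
            p.years = p.discharged_year
        elif not p.treated and not p.eligible:
            # confined to the first year so the eligibility filter cannot see them
            p.start_month = int(rng.integers(0, min(12, w)))
            p.years = 1
        else:
            p.start_month = int(rng.integers(0, w))
            p.years = min(3, -(-(w - p.start_month) // 12))

    def year_span(p: _Patient, year: int) -> tuple[int, int]:
        lo = boundary[p.start_month + 12 * (year - 1)]
        hi = min(boundary[p.start_month + 12 * year], window_days)
        return lo, hi

    def add_events(p: _Patient, year: int, vtype: VisitType, k: int,
                   lo_clip: int | None = None, hi_clip: int | None = None):
        lo, hi = year_span(p, year)
        if lo_clip is not None:
            lo = max(lo, lo_clip)
        if hi_clip is not None:
            hi = min(hi, hi_clip)
        length = max(hi - lo, 1)
        for i in range(k):
            d = lo + int((i + 0.5) * length / k) + int(rng.integers(-7, 8))
            d = min(max(d, lo), hi - 1) if hi > lo else lo
            d = min(max(d, 0), window_days - 1)
            p.visits.append((d, vtype, VisitStatus.attended))

    def allocate_category(cond, cat, owners, extra_used=None, already=0):
        """Spread spec.counts(cat, cond) minus ``already`` placed minimums
        over the owners' patient-years."""
        total = spec.counts(cat, cond) - already
        vtype = _CATEGORY_VISIT_TYPE[cat]
        if total == 0:
            return {}
        if not owners:
            raise ValueError(
                f"infeasible spec: {total} {cat} events for {cond.value} "
                f"but no eligible patients to own them")
        cells = [(p, y) for p in owners for y in range(1, p.years + 1)]
        caps = np.full(len(cells), MAX_PER_PATIENT_YEAR)
        if extra_used:
            for j, cell in enumerate(cells):
                caps[j] -= extra_used.get((cell[0].idx, cell[1]), 0)
        counts = _allocate(total, caps, rng)
        out = {}
        for (p, y), k in zip(cells, counts):
            if k:
                hi_clip = cutoff24 if (not p.treated and p.discharged_year is None
                                       and not p.eligible) else None
                add_events(p, y, vtype, int(k), hi_clip=hi_clip)
                out[(p.idx, y)] = int(k)
        return out

    for c in CONDITIONS:
        treated = per_cond[c]["treated"]
        observ = per_cond[c]["observ"]
        n_inj = spec.counts("injection", c)
        n_las = spec.counts("laser", c)

        # minimum one treatment per treated patient; non-discharged patients
        # get it in their final year inside the last 6 months, which keeps
        # them out of the virtual-clinic-eligible set
        used: dict[tuple[int, int], int] = {}
        inj_owners, las_owners = set(), set()
        if treated:
            lo_bound = max(0, len(treated) - n_las)
            hi_bound = min(len(treated), n_inj)
            k_inj_min = min(max(int(round(len(treated) * n_inj / max(n_inj + n_las, 1))),
                                lo_bound), hi_bound)
            order = rng.permutation(len(treated))
            for rank, i in enumerate(order):
                p = treated[i]
                vtype = VisitType.injection if rank < k_inj_min else VisitType.laser
                if p.discharged_year is None:
                    add_events(p, p.years, vtype, 1, lo_clip=last6 + 1)
                    used[(p.idx, p.years)] = used.get((p.idx, p.years), 0) + 1
                else:
                    add_events(p, 1, vtype, 1)
                    used[(p.idx, 1)] = used.get((p.idx, 1), 0) + 1
                (inj_owners if vtype is VisitType.injection else las_owners).add(p.idx)
            n_inj -= k_inj_min
            n_las -= len(treated) - k_inj_min

        spec_like = {"injection": n_inj, "laser": n_las}
        for cat in ("injection", "laser"):
            total = spec_like[cat]
            if total == 0:
                continue
            if not treated:
                raise ValueError(
                    f"infeasible spec: {total} {cat} events for {c.value} with no treated patients")
            cells = [(p, y) for p in treated for y in range(1, p.years + 1)]
            caps = np.array([MAX_PER_PATIENT_YEAR - used.get((p.idx, y), 0)
                             for p, y in cells])
            counts = _allocate(total, caps, rng)
            vtype = _CATEGORY_VISIT_TYPE[cat]
            for (p, y), k in zip(cells, counts):
                if k:
                    add_events(p, y, vtype, int(k))
                    used[(p.idx, y)] = used.get((p.idx, y), 0) + int(k)
                    (inj_owners if cat == "injection" else las_owners).add(p.idx)

        allocate_category(c, "injection_fu", [p for p in treated if p.idx in inj_owners])
        allocate_category(c, "laser_fu", [p for p in treated if p.idx in las_owners])

        # observation reviews: minimum one per observation patient (planted
        # eligible patients get theirs inside the last 24 months)
        n_obs = spec.counts("observation", c)
        if observ:
            if n_obs < len(observ):
                raise ValueError(
                    f"infeasible spec: {n_obs} observation reviews for {c.value} "
                    f"cannot give each of {len(observ)} observation patients one")
            used_obs: dict[tuple[int, int], int] = {}
            for p in observ:
                if p.eligible:
                    add_events(p, p.years, VisitType.observation_fu, 1,
                               lo_clip=cutoff24 + 1)
                    used_obs[(p.idx, p.years)] = 1
                else:
                    hi_clip = cutoff24 if p.discharged_year is None else None
                    add_events(p, 1, VisitType.observation_fu, 1, hi_clip=hi_clip)
                    used_obs[(p.idx, 1)] = 1
            allocate_category(c, "observation", observ, extra_used=used_obs,
                              already=len(observ))
        elif n_obs:
            raise ValueError(
                f"infeasible spec: {n_obs} observation reviews for {c.value} "
                f"but no observation patients")

    # non-attendance noise: clone attended visits as DNA/cancelled rows a few
    # days earlier (rates are stated assumptions, they do not alter totals)
    all_attended = [(p, j) for p in patients for j, v in enumerate(p.visits)]
    for rate, status in ((spec.dna_rate, VisitStatus.dna),
                         (spec.cancel_rate, VisitStatus.cancelled)):
        k = int(round(rate * len(all_attended)))
        if k:
            pick = rng.choice(len(all_attended), size=min(k, len(all_attended)),
                              replace=False)
            for i in pick:
                p, j = all_attended[i]
                d, vtype, _ = p.visits[j]
                p.visits.append((max(d - int(rng.integers(1, 8)), 0), vtype, status))

    out: list[PatientRecord] = []
    for p in patients:
        p.visits.sort(key=lambda v: (v[0], v[1].value, v[2].value))
        visits = [Visit(base + pd.Timedelta(days=d), vt, st) for d, vt, st in p.visits]
        out.append(PatientRecord(
            patient_id=f"P{p.idx:06d}",
            condition=p.cond,
            visits=visits,
            discharged_year=p.discharged_year,
        ))
    return out


def window_end(spec: CohortSpec) -> pd.Timestamp:
    """First day after the observation window of a cohort spec."""
    return pd.Timestamp(spec.start_date) + pd.DateOffset(months=spec.window_months)
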