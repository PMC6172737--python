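"""Discrete event simulation of the retinal service care pathway.

Entities are patients; events are appointments competing for finite clinic
resources.  Each simulated patient arrives (or is present at time zero as
part of the prevalent caseload), is planned a care year under the scenario's
treatment regimen — an annual injection count and follow-up count drawn from
calibrated count distributions, spread evenly over the year — and each due
visit is booked into the earliest feasible clinic day.  Booked appointments
may be cancelled or not attended (DNA), in which case the slot is released
and exactly one rebooking attempt is made within the service's rebooking
window.  At each care-year boundary a discharge draw decides whether the
patient exits.  Under a virtual-clinic scenario, eligible monitoring-only
patients have their observation reviews diverted to a nurse-led virtual
clinic, consuming virtual capacity instead of hospital clinic resources.

Time is measured in integer days from the scenario start (day 0 is a
Monday); a month is 365/12 days.  Determinism: every stochastic mechanism
(arrivals, count draws, non-attendance, discharge) has its own named random
stream derived per replication and per patient from the scenario seed, so a
fixed seed reproduces the trace bit for bit and paired-seed scenario
comparisons isolate the effect of the scenario levers (common random
numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import CountDistribution
from .records import Condition, VisitType

CONDITIONS = (Condition.AMD, Condition.DR, Condition.MR)

DAYS_PER_MONTH = 365.0 / 12.0
DAYS_PER_YEAR = 365

#: Deterministic tie-break rank of simultaneous visits.
VISIT_RANK = {t: i for i, t in enumerate(VisitType)}

POOL_NAMES = ("clinic_session", "nurse", "consultation_room",
              "injection_bed", "virtual_capacity")


def month_of_day(day: int) -> int:
    return int(day // DAYS_PER_MONTH)


def days_in_horizon(months: int) -> int:
    return int(round(months * DAYS_PER_MONTH))


# ---------------------------------------------------------------------------
# configuration types

@dataclass
class RegimenSpec:
    """Treatment regimen as per-care-year count distributions.

    PRN (as needed): injections only when disease activity is seen, mean
    4/3/2.5 per year, with separate follow-up assessment visits.  Treat and
    extend: an injection at every visit with the interval stretched as the
    disease stays dry, mean 8/6/5 per year; the assessment is folded into
    the injection visit (``combined_assessment``) and only the surplus of the
    follow-up draw over the injection draw remains as pure follow-up visits.
    Year-3 distributions apply to all later years.
    """

    name: str
    injections_per_year: dict[int, CountDistribution]
    fus_per_year: dict[int, CountDistribution]
    combined_assessment: bool = False

    def injections(self, year: int) -> CountDistribution:
        return self.injections_per_year[min(year, 3)]

    def fus(self, year: int) -> CountDistribution:
        return self.fus_per_year[min(year, 3)]

    @classmethod
    def from_means(cls, name, injection_means, fu_means, combined_assessment=False):
        return cls(
            name=name,
            injections_per_year={y: CountDistribution.lognormal(m)
                                 for y, m in injection_means.items()},
            fus_per_year={y: CountDistribution.lognormal(m)
                          for y, m in fu_means.items()},
            combined_assessment=combined_assessment,
        )

    @classmethod
    def prn(cls) -> "RegimenSpec":
        from . import reference_data as ref
        return cls.from_means("PRN", ref.PRN_INJECTION_MEANS, ref.TREATED_FU_MEANS,
                              combined_assessment=False)

    @classmethod
    def te(cls) -> "RegimenSpec":
        from . import reference_data as ref
        return cls.from_means("TE", ref.TE_INJECTION_MEANS, ref.TREATED_FU_MEANS,
                              combined_assessment=True)


@dataclass
class ResourcePool:
    """A finite clinic resource with a weekly availability template.

    ``weekly_schedule`` maps weekday (0=Monday) to (units, minutes per unit);
    ``minutes_per_visit`` maps visit type to the minutes this pool is seized
    for (absent or zero: the visit does not need this pool).
    """

    name: str
    weekly_schedule: dict[int, tuple[int, float]]
    minutes_per_visit: dict[VisitType, float] = field(default_factory=dict)

    def __post_init__(self):
        for wd, (units, mins) in self.weekly_schedule.items():
            if units < 0 or mins < 0:
                raise ValueError(f"negative capacity on weekday {wd} of {self.name}")
        if any(m < 0 for m in self.minutes_per_visit.values()):
            raise ValueError(f"negative visit minutes on {self.name}")

    def daily_minutes(self, n_days: int) -> np.ndarray:
        out = np.zeros(n_days)
        for wd, (units, mins) in self.weekly_schedule.items():
            out[np.arange(n_days) % 7 == wd] = units * mins
        return out

    def requires(self, vtype: VisitType) -> float:
        return float(self.minutes_per_visit.get(vtype, 0.0))


class BookingSystem:
    """Appointment slot calendar with non-attendance and rebooking rules.

    A slot is held by at most one appointment.  ``dna_prob``/``cancel_prob``
    are per-appointment probabilities; a failed appointment releases its slot
    and triggers exactly one rebooking attempt within ``rebook_within_days``.
    The calendar itself (free slots per clinic day) is supplied explicitly or
    derived by the engine from the clinic-session resource and
    ``slot_minutes``.
    """

    def __init__(self, dna_prob=0.05, cancel_prob=0.03, rebook_within_days=14,
                 slot_minutes=20.0, slots: Optional[Sequence[int]] = None):
        if not (0 <= dna_prob <= 1 and 0 <= cancel_prob <= 1
                and dna_prob + cancel_prob <= 1):
            raise ValueError("dna/cancel probabilities must lie in [0,1] and sum <= 1")
        if rebook_within_days <= 0:
            raise ValueError("rebook_within_days must be positive")
        self.dna_prob = float(dna_prob)
        self.cancel_prob = float(cancel_prob)
        self.rebook_within_days = int(rebook_within_days)
        self.slot_minutes = float(slot_minutes)
        self.slots = None if slots is None else np.asarray(slots, dtype=int).copy()

    def clone(self) -> "BookingSystem":
        return BookingSystem(self.dna_prob, self.cancel_prob,
                             self.rebook_within_days, self.slot_minutes,
                             None if self.slots is None else self.slots.copy())

    # -- slot operations ----------------------------------------------------

    def find_slot(self, due_day: int, end_day: Optional[int] = None,
                  feasible=None) -> Optional[int]:
        """Earliest day with a free slot on or after ``due_day``."""
        if self.slots is None:
            raise ValueError("booking system has no slot calendar attached")
        end = len(self.slots) if end_day is None else min(end_day, len(self.slots))
        for d in range(max(due_day, 0), end):
            if self.slots[d] > 0 and (feasible is None or feasible(d)):
                return d
        return None

    def seize(self, day: int) -> None:
        if self.slots[day] <= 0:
            raise RuntimeError(f"no free slot on day {day}")
        self.slots[day] -= 1

    def release(self, day: int) -> None:
        self.slots[day] += 1


def book(due_day: int, booking: BookingSystem,
         end_day: Optional[int] = None) -> Optional[int]:
    """Book the earliest free slot on or after ``due_day``; ``None`` means
    the demand overflows the calendar (recorded, never dropped)."""
    d = booking.find_slot(due_day, end_day)
    if d is not None:
        booking.seize(d)
    return d


@dataclass
class SimPatient:
    """A simulated patient (engine entity)."""

    idx: int
    condition: Condition
    treated: bool
    arrival_day: int = 0
    start_year: int = 1
    eligible: bool = False
    venue: str = "hospital"
    is_new: bool = True


@dataclass(frozen=True)
class InitialPatient:
    """Prevalent-caseload member present at scenario start."""

    condition: Condition
    treated: bool
    year: int = 2
    eligible: bool = False


@dataclass
class ScenarioConfig:
    """Everything one simulation scenario needs."""

    name: str
    regimen: RegimenSpec
    virtual_clinic: bool
    arrivals: dict[Condition, Sequence[float]]      # monthly new-patient means
    discharge: "object"                              # DischargeModel-like .p()
    resources: dict[str, ResourcePool]
    booking: BookingSystem
    tariffs: "object"                                # TariffTable
    observation_fus: dict[int, CountDistribution]
    p_treated_new: float = 0.157
    initial_cohort: list[InitialPatient] = field(default_factory=list)
    horizon_months: int = 15
    warmup_months: int = 3
    replications: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.warmup_months < self.horizon_months:
            raise ValueError("need 0 <= warmup_months < horizon_months")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 <= self.p_treated_new <= 1.0:
            raise ValueError("p_treated_new must be a probability")
        for cond in CONDITIONS:
            means = self.arrivals.get(cond, [])
            if len(means) < self.horizon_months:
                raise ValueError(
                    f"arrival means for {cond.value} cover {len(means)} months; "
                    f"horizon is {self.horizon_months}")


@dataclass
class SimulationTrace:
    """Per-visit outcomes and monthly resource occupancy of one replication."""

    visits: pd.DataFrame
    busy: dict[str, np.ndarray]         # minutes per pool per month
    available: dict[str, np.ndarray]
    horizon_months: int
    warmup_months: int
    scenario: str
    replication: int

    @property
    def reported_months(self) -> np.ndarray:
        return np.arange(self.warmup_months, self.horizon_months)

    def utilisation(self, pool: str) -> float:
        m = self.reported_months
        avail = self.available[pool][m].sum()
        return float(self.busy[pool][m].sum() / avail) if avail > 0 else 0.0

    def to_csv(self, path) -> None:
        self.visits.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations

def plan_care_year(patient: SimPatient, regimen: RegimenSpec, year: int,
                   rng: np.random.Generator,
                   observation_fus: Optional[dict[int, CountDistribution]] = None,
                   ) -> list[tuple[int, VisitType, bool]]:
    """Due visits (day offset within the year, type, carries-assessment) for
    one care year.

    Treated patients draw an injection count and a follow-up count from the
    regimen's year distributions; observation-only patients draw monitoring
    reviews from ``observation_fus``.  Events are spread evenly over the
    year.  Under a combined-assessment regimen each injection visit includes
    the follow-up assessment and only the surplus of the follow-up draw
    remains as separate visits.
    """
    due: list[tuple[int, VisitType, bool]] = []
    if patient.treated:
        u_inj, u_fu = rng.random(2)
        n_inj = int(regimen.injections(year).ppf([u_inj])[0])
        n_fu = int(regimen.fus(year).ppf([u_fu])[0])
        if regimen.combined_assessment:
            n_pure = max(n_fu - n_inj, 0)
            assess = True
        else:
            n_pure = n_fu
            assess = False
        for i in range(n_inj):
            due.append((int((i + 0.5) * DAYS_PER_YEAR / n_inj),
                        VisitType.injection, assess))
        for i in range(n_pure):
            due.append((int((i + 0.7) * DAYS_PER_YEAR / n_pure),
                        VisitType.injection_fu, False))
    else:
        if observation_fus is None:
            raise ValueError("observation patients need observation_fus distributions")
        u_fu = rng.random()
        dist = observation_fus[min(year, 3)]
        n_fu = int(dist.ppf([u_fu])[0])
        vtype = VisitType.virtual_fu if patient.venue == "virtual" \
            else VisitType.observation_fu
        for i in range(n_fu):
            due.append((int((i + 0.5) * DAYS_PER_YEAR / n_fu), vtype, False))
    return due


def apply_discharge(patient: SimPatient, year: int, model,
                    rng: np.random.Generator) -> bool:
    """Bernoulli discharge decision at the end of a completed care year."""
    status = "treated" if patient.treated else "observation"
    p = model.p(patient.condition, status, min(year, 3))
    return bool(rng.random() < p)


def divert_to_virtual(patient: SimPatient, as_of: int = 0) -> SimPatient:
    """Move an eligible patient's monitoring reviews to the virtual clinic."""
    patient.venue = "virtual"
    return patient


# ---------------------------------------------------------------------------
# the simulator

_TRACE_COLUMNS = ["patient_id", "condition", "visit_type", "assessment",
                  "due", "booked", "attended", "outcome", "venue", "rebooked",
                  "month"] + [f"minutes_{p}" for p in POOL_NAMES]


def _patient_rngs(seed: int, rep: int, key: tuple[int, ...]):
    ss = np.random.SeedSequence((seed, rep) + key)
    path_ss, dna_ss = ss.spawn(2)
    return (np.random.Generator(np.random.PCG64(path_ss)),
            np.random.Generator(np.random.PCG64(dna_ss)))


def _simulate_one(config: ScenarioConfig, rep: int) -> SimulationTrace:
    n_days = days_in_horizon(config.horizon_months)
    n_months = config.horizon_months

    pools = {name: config.resources[name] for name in config.resources}
    avail_daily = {n: p.daily_minutes(n_days) for n, p in pools.items()}
    remaining = {n: a.copy() for n, a in avail_daily.items()}
    month_idx = np.array([month_of_day(d) for d in range(n_days)])
    avail_monthly = {n: np.bincount(month_idx, weights=a, minlength=n_months)
                     for n, a in avail_daily.items()}
    busy_monthly = {n: np.zeros(n_months) for n in pools}
    for extra in POOL_NAMES:
        avail_monthly.setdefault(extra, np.zeros(n_months))
        busy_monthly.setdefault(extra, np.zeros(n_months))

    booking = config.booking.clone()
    if booking.slots is None:
        clinic = pools.get("clinic_session")
        if clinic is None:
            raise ValueError("need a clinic_session pool or an explicit slot calendar")
        booking.slots = (avail_daily["clinic_session"] // booking.slot_minutes
                        ).astype(int)
    elif len(booking.slots) < n_days:
        raise ValueError("slot calendar shorter than the horizon")

    # ---- entity creation: prevalent caseload, then forecast-driven arrivals
    patients: list[tuple[SimPatient, np.random.Generator, np.random.Generator]] = []
    for i, ip in enumerate(config.initial_cohort):
        p = SimPatient(idx=len(patients), condition=ip.condition,
                       treated=ip.treated, arrival_day=0, start_year=ip.year,
                       eligible=ip.eligible, is_new=False)
        patients.append((p, *_patient_rngs(config.seed, rep, (0, i))))

    for m in range(n_months):
        d_lo = int(round(m * DAYS_PER_MONTH))
        d_hi = int(round((m + 1) * DAYS_PER_MONTH))
        for ci, cond in enumerate(CONDITIONS):
            mean = float(config.arrivals[cond][m])
            arr_rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence((config.seed, rep, 2, m, ci))))
            n_arr = int(stats.poisson.ppf(arr_rng.random(), mean)) if mean > 0 else 0
            for k in range(n_arr):
                day = d_lo + int(arr_rng.random() * (d_hi - d_lo))
                p = SimPatient(idx=len(patients), condition=cond, treated=False,
                               arrival_day=day, start_year=1, is_new=True)
                patients.append((p, *_patient_rngs(config.seed, rep, (1, m, ci, k))))

    # ---- planning: full trajectory per patient (arrival -> yearly plans ->
    # discharge), independent of the booking calendar
    due_visits = []  # (due_day, patient_idx, rank, seq, patient, vtype, assess)
    dna_rngs = {}
    seq = 0
    for p, path_rng, dna_rng in patients:
        dna_rngs[p.idx] = dna_rng
        status_u = path_rng.random()
        if p.is_new:
            p.treated = status_u < config.p_treated_new
            due_visits.append((p.arrival_day, p.idx,
                               VISIT_RANK[VisitType.new_referral], seq, p,
                               VisitType.new_referral, False))
            seq += 1
        if config.virtual_clinic and p.eligible:
            divert_to_virtual(p)
        year = p.start_year
        year_start = p.arrival_day
        while year_start < n_days:
            for off, vtype, assess in plan_care_year(
                    p, config.regimen, year, path_rng,
                    observation_fus=config.observation_fus):
                due = year_start + off
                if due < n_days:
                    due_visits.append((due, p.idx, VISIT_RANK[vtype], seq, p,
                                       vtype, assess))
                    seq += 1
            if apply_discharge(p, year, config.discharge, path_rng):
                break
            year += 1
            year_start += DAYS_PER_YEAR

    # ---- booking and service, in due-date order with deterministic ties
    due_visits.sort(key=lambda t: t[:4])
    rows = []
    for due, pidx, rank, _seq, p, vtype, assess in due_visits:
        hospital = vtype is not VisitType.virtual_fu
        req = [(name, pool.requires(vtype)) for name, pool in pools.items()
               if pool.requires(vtype) > 0]

        def feasible(d):
            return all(remaining[name][d] >= mins for name, mins in req)

        def seize(d):
            if hospital:
                booking.seize(d)
            for name, mins in req:
                remaining[name][d] -= mins

        def release(d):
            if hospital:
                booking.release(d)
            for name, mins in req:
                remaining[name][d] += mins

        if hospital:
            booked = booking.find_slot(due, n_days, feasible)
        else:
            booked = next((d for d in range(due, n_days) if feasible(d)), None)
        if booked is None:
            rows.append([f"S{pidx:06d}", p.condition.value, vtype.value, assess,
                         due, -1, -1, "overflow", p.venue, False,
                         month_of_day(due)] + [0.0] * len(POOL_NAMES))
            continue
        seize(booked)

        u = dna_rngs[pidx].random()
        attended_day = booked
        outcome = "attended"
        rebooked = False
        if u < booking.cancel_prob + booking.dna_prob:
            failed_as = "cancelled" if u < booking.cancel_prob else "dna"
            release(booked)
            d2 = None
            lim = min(booked + booking.rebook_within_days + 1, n_days)
            if hospital:
                d2 = booking.find_slot(booked + 1, lim, feasible)
            else:
                d2 = next((d for d in range(booked + 1, lim) if feasible(d)), None)
            if d2 is None:
                outcome = failed_as
                attended_day = -1
            else:
                seize(d2)
                attended_day = d2
                rebooked = True

        minutes = [0.0] * len(POOL_NAMES)
        month = month_of_day(attended_day if attended_day >= 0 else due)
        if outcome == "attended":
            for name, mins in req:
                busy_monthly[name][month] += mins
                minutes[POOL_NAMES.index(name)] = mins
        rows.append([f"S{pidx:06d}", p.condition.value, vtype.value, assess,
                     due, booked, attended_day, outcome, p.venue, rebooked,
                     month] + minutes)

    visits = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    return SimulationTrace(
        visits=visits,
        busy=busy_monthly,
        available=avail_monthly,
        horizon_months=config.horizon_months,
        warmup_months=config.warmup_months,
        scenario=config.name,
        replication=rep,
    )


def run(config: ScenarioConfig):
    """Run all replications of a scenario.

    Returns ``(traces, report)``: one ``SimulationTrace`` per replication and
    the pooled ``KPIReport`` of monthly averages over the post-warm-up
    reporting window.  A fixed seed yields an identical result; capacity
    shortfalls surface as overflow outcomes in the trace, never as errors.
    """
    from .accounting import kpi_from_trace, pool_reports

    traces = [_simulate_one(config, rep) for rep in range(config.replications)]
    reports = [kpi_from_trace(t, config.tariffs) for t in traces]
    return traces, pool_reports(reports, name=config.name)
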