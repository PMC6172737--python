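"""Scenario construction from the packaged defaults and user YAML files.

``defaults.yaml`` ships the ASSUMED resource, booking and tariff inputs (no
service-specific values were available); everything here is a thin builder
layer turning that document — optionally overlaid with a user configuration
file — into ``ScenarioConfig`` objects, including the four canonical
service-design scenarios.
"""

from __future__ import annotations

import copy
from importlib import resources as importlib_resources
from typing import Optional, Sequence

import yaml

from . import reference_data as ref
from .calibration import CalibrationResult, DischargeModel
from .distributions import CountDistribution
from .engine import (
    BookingSystem,
    InitialPatient,
    RegimenSpec,
    ResourcePool,
    ScenarioConfig,
)
from .records import Condition, VisitType
from .synthetic import largest_remainder

CONDITIONS = (Condition.AMD, Condition.DR, Condition.MR)


def load_defaults() -> dict:
    with importlib_resources.files("retinasim").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def default_booking(doc: Optional[dict] = None) -> BookingSystem:
    b = (doc or load_defaults())["booking"]
    return BookingSystem(dna_prob=b["dna_prob"], cancel_prob=b["cancel_prob"],
                         rebook_within_days=b["rebook_within_days"],
                         slot_minutes=b["slot_minutes"])


def default_resources(doc: Optional[dict] = None) -> dict[str, ResourcePool]:
    res = (doc or load_defaults())["resources"]
    out = {}
    for name, spec in res.items():
        out[name] = ResourcePool(
            name=name,
            weekly_schedule={int(wd): (int(u), float(m))
                             for wd, (u, m) in spec["weekly_schedule"].items()},
            minutes_per_visit={VisitType(t): float(m)
                               for t, m in spec.get("minutes_per_visit", {}).items()},
        )
    return out


def default_tariffs(doc: Optional[dict] = None):
    from .accounting import TariffTable
    t = (doc or load_defaults())["tariffs"]
    return TariffTable(
        revenue_per_visit={VisitType(k): float(v) for k, v in t["revenue"].items()},
        cost_per_visit={VisitType(k): {c: float(x) for c, x in comp.items()}
                        for k, comp in t["cost"].items()},
        virtual_fu_cost=float(t["virtual_fu_cost"]),
    )


def default_observation_fus() -> dict[int, CountDistribution]:
    return {y: CountDistribution.lognormal(m)
            for y, m in ref.OBSERVATION_FU_MEANS.items()}


def default_discharge_model() -> DischargeModel:
    """Discharge model from the reference discharge counts.

    At-risk denominators assume the whole group is observable for three care
    years (per-year denominators were not itemised in the source cohort).
    """
    prob, n_dis, n_risk = {}, {}, {}
    group = {("treated", c): ref.TREATED_COUNTS[c] for c in CONDITIONS}
    n_obs = {c: round(ref.N_PATIENTS * ref.CASE_MIX[c]) - ref.TREATED_COUNTS[c]
             for c in CONDITIONS}
    group.update({("observation", c): n_obs[c] for c in CONDITIONS})
    for c in CONDITIONS:
        for s in ("treated", "observation"):
            at_risk = group[(s, c)]
            for y in (1, 2, 3):
                k = ref.DISCHARGE_COUNTS.get((c, s, y), 0)
                n_dis[(c, s, y)] = k
                n_risk[(c, s, y)] = at_risk
                prob[(c, s, y)] = k / at_risk if at_risk else 0.0
                at_risk -= k
    return DischargeModel(prob, n_dis, n_risk)


def default_initial_cohort(doc: Optional[dict] = None) -> list[InitialPatient]:
    """Deterministic prevalent caseload at the documented desk scale."""
    ic = (doc or load_defaults())["initial_cohort"]
    n, years = int(ic["n"]), [int(y) for y in ic["years"]]
    n_treated = int(round(n * float(ic["treated_share"])))
    n_eligible = int(ic["eligible"])
    per_cond = largest_remainder(n, [ref.CASE_MIX[c] for c in CONDITIONS])
    out: list[InitialPatient] = []
    i = 0
    for c, n_c in zip(CONDITIONS, per_cond):
        t_c = int(round(n_c * n_treated / n)) if n else 0
        for j in range(n_c):
            treated = j < t_c
            out.append(InitialPatient(condition=c, treated=treated,
                                      year=years[i % len(years)], eligible=False))
            i += 1
    # mark the eligible among observation-only members, spread across conditions
    obs_idx = [k for k, p in enumerate(out) if not p.treated]
    for k in obs_idx[:n_eligible]:
        p = out[k]
        out[k] = InitialPatient(p.condition, p.treated, p.year, eligible=True)
    return out


def constant_arrivals(horizon_months: int,
                      monthly_total: float = ref.MONTHLY_NEW_ATTENDANCES,
                      mix: Optional[dict[Condition, float]] = None,
                      ) -> dict[Condition, list[float]]:
    mix = mix or ref.CASE_MIX
    return {c: [monthly_total * mix[c]] * horizon_months for c in CONDITIONS}


def build_scenario(
    name: str,
    regimen: Optional[RegimenSpec] = None,
    virtual_clinic: bool = False,
    seed: int = 0,
    replications: Optional[int] = None,
    horizon_months: Optional[int] = None,
    warmup_months: Optional[int] = None,
    arrivals: Optional[dict[Condition, Sequence[float]]] = None,
    calibration: Optional[CalibrationResult] = None,
    overrides: Optional[dict] = None,
) -> ScenarioConfig:
    """Assemble a ScenarioConfig from defaults, optional calibration output
    and optional YAML-style overrides."""
    doc = _merge(load_defaults(), overrides)
    sim = doc["simulation"]
    horizon = horizon_months if horizon_months is not None else int(sim["horizon_months"])
    warmup = warmup_months if warmup_months is not None else int(sim["warmup_months"])
    reps = replications if replications is not None else int(sim["replications"])

    if calibration is not None:
        discharge = calibration.discharge
        obs = {y: calibration.distribution(Condition.AMD, "observation", y)
               or default_observation_fus()[y] for y in (1, 2, 3)}
        p_treated = calibration.treated_share()
        mix = calibration.case_mix.proportions
    else:
        discharge = default_discharge_model()
        obs = default_observation_fus()
        p_treated = float(sim["p_treated_new"])
        mix = ref.CASE_MIX

    if arrivals is None:
        arrivals = constant_arrivals(horizon, float(sim["monthly_new_arrivals"]), mix)

    return ScenarioConfig(
        name=name,
        regimen=regimen or RegimenSpec.prn(),
        virtual_clinic=virtual_clinic,
        arrivals=arrivals,
        discharge=discharge,
        resources=default_resources(doc),
        booking=default_booking(doc),
        tariffs=default_tariffs(doc),
        observation_fus=obs,
        p_treated_new=p_treated,
        initial_cohort=default_initial_cohort(doc),
        horizon_months=horizon,
        warmup_months=warmup,
        replications=reps,
        seed=seed,
    )


def four_scenarios(seed: int = 0, replications: Optional[int] = None,
                   **kw) -> dict[str, ScenarioConfig]:
    """The canonical scenario set: current service (as-needed regimen),
    virtual clinic alone, treat-and-extend alone, and both combined.
    All four share the seed, so comparisons use common random numbers."""
    names = ref.SCENARIO_NAMES
    return {
        names[0]: build_scenario(names[0], RegimenSpec.prn(), False,
                                 seed=seed, replications=replications, **kw),
        names[1]: build_scenario(names[1], RegimenSpec.prn(), True,
                                 seed=seed, replications=replications, **kw),
        names[2]: build_scenario(names[2], RegimenSpec.te(), False,
                                 seed=seed, replications=replications, **kw),
        names[3]: build_scenario(names[3], RegimenSpec.te(), True,
                                 seed=seed, replications=replications, **kw),
    }
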