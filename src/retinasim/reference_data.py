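"""Reference inputs describing the motivating service.

These constants summarise 36 months (April 2013 - March 2016) of patient
level activity at a mid-size English NHS hospital retinal service serving a
population of over 500,000: the attended-appointment breakdown by condition,
the discharge counts by care year and treatment status, the case mix, the
virtual-clinic-eligible cohort size, the per-regimen annual injection means,
and the monthly-average KPI columns of the four service-design scenarios.

They serve two purposes: as the default calibration of the synthetic cohort
generator (so the whole pipeline is testable without any patient data), and
as the fixed points that calibration routines are checked against.
"""

from __future__ import annotations

from .records import Condition

AMD, DR, MR = Condition.AMD, Condition.DR, Condition.MR

#: Total attending patients over the 36-month window (itemised cohort table;
#: the running text rounds this to 6520).
N_PATIENTS = 6530

#: Share of patients by condition (nAMD / DR / pooled medical retina).
CASE_MIX = {AMD: 0.172, DR: 0.423, MR: 0.405}

#: Attended appointments by activity category and condition over 36 months.
#: Lasers were not part of the AMD pathway at this service.
ACTIVITY_COUNTS = {
    "injection":    {AMD: 3295, DR: 425,  MR: 743},
    "injection_fu": {AMD: 4851, DR: 599,  MR: 955},
    "laser":        {AMD: 0,    DR: 315,  MR: 63},
    "laser_fu":     {AMD: 0,    DR: 848,  MR: 191},
    "observation":  {AMD: 1208, DR: 4790, MR: 3846},
}

#: Per-condition attended totals and the grand total implied by the above.
ACTIVITY_TOTALS = {AMD: 9354, DR: 6977, MR: 5798}
TOTAL_ATTENDED = 22129

#: Discharged patients by (condition, treatment status, care year at exit).
DISCHARGE_COUNTS = {
    (AMD, "treated", 1): 12,  (AMD, "observation", 1): 147,
    (DR,  "treated", 1): 1,   (DR,  "observation", 1): 330,
    (MR,  "treated", 1): 13,  (MR,  "observation", 1): 611,
    (AMD, "treated", 2): 16,  (AMD, "observation", 2): 14,
    (DR,  "treated", 2): 5,   (DR,  "observation", 2): 32,
    (MR,  "treated", 2): 13,  (MR,  "observation", 2): 58,
    (AMD, "treated", 3): 10,  (AMD, "observation", 3): 10,
    (DR,  "treated", 3): 1,   (DR,  "observation", 3): 24,
    (MR,  "treated", 3): 4,   (MR,  "observation", 3): 23,
}

TOTAL_DISCHARGED_TREATED = 75
TOTAL_DISCHARGED_OBSERVATION = 1249
TOTAL_DISCHARGED = 1324

#: Treated (ever injected or lasered) vs observation-only patient totals.
N_TREATED = 1025
N_OBSERVATION = 5505

#: ASSUMED split of the 1025 treated patients by condition (not itemised in
#: the source material); chosen to be feasible against ACTIVITY_COUNTS at
#: 1-14 injections per patient-year.
TREATED_COUNTS = {AMD: 400, DR: 280, MR: 345}

#: Observation-only patients who attended in the last 2 years with no
#: treatment visit in the last 6 months: the virtual-clinic-eligible cohort.
N_VC_ELIGIBLE = 894

#: Mean annual intravitreal injections per treated patient by care year.
PRN_INJECTION_MEANS = {1: 4.0, 2: 3.0, 3: 2.5}        # as-needed regimen
TE_INJECTION_MEANS = {1: 8.0, 2: 6.0, 3: 5.0}         # treat-and-extend

#: Mean annual follow-up assessments per treated patient by care year (AMD
#: pathway values, used as the regimen follow-up defaults).
TREATED_FU_MEANS = {1: 4.8, 2: 4.0, 3: 3.6}

#: Mean annual monitoring reviews per observation-only patient by care year.
OBSERVATION_FU_MEANS = {1: 1.7, 2: 1.6, 3: 1.4}

#: The one fully specified count distribution: observation follow-ups,
#: log-normal with natural-scale mean 1.4 and SD 0.37 per patient-year.
OBSERVATION_FU_LOGNORMAL = (1.4, 0.37)

#: Per-visit cost of a hospital outpatient follow-up assessment (GBP) and the
#: cost band of the same review done through a virtual clinic.
HOSPITAL_FU_COST = 89.0
VIRTUAL_FU_COST_RANGE = (30.0, 45.0)

#: Canonical names of the four service-design scenarios.
SCENARIO_NAMES = (
    "Current Service",
    "Virtual Clinic + no change in current service",
    "Treat and Extend + no virtual clinic",
    "Virtual Clinic + Treat and Extend",
)

#: Monthly-average KPI columns of the four scenarios as reported for the
#: reference service (utilisations as proportions, money in GBP/month).
REFERENCE_KPI_COLUMNS = {
    "Current Service": {
        "new_attendances": 119, "followups": 726,
        "util_clinic_session": 0.71, "util_nurse": 0.71,
        "util_consultation_room": 0.53, "util_injection_bed": 0.29,
        "n_injections": 169, "costing": 151760, "revenue": 207494,
        "surplus": 55735,
    },
    "Virtual Clinic + no change in current service": {
        "new_attendances": 119, "followups": 642,
        "util_clinic_session": 0.64, "util_nurse": 0.65,
        "util_consultation_room": 0.48, "util_injection_bed": 0.30,
        "n_injections": 172, "costing": 153963, "revenue": 207494,
        "surplus": 53532,
    },
    "Treat and Extend + no virtual clinic": {
        "new_attendances": 119, "followups": 812,
        "util_clinic_session": 0.85, "util_nurse": 0.82,
        "util_consultation_room": 0.55, "util_injection_bed": 0.40,
        "n_injections": 218, "costing": 192902, "revenue": 260809,
        "surplus": 67906,
    },
    "Virtual Clinic + Treat and Extend": {
        "new_attendances": 119, "followups": 708,
        "util_clinic_session": 0.71, "util_nurse": 0.70,
        "util_consultation_room": 0.51, "util_injection_bed": 0.37,
        "n_injections": 215, "costing": 190200, "revenue": 251664,
        "surplus": 61464,
    },
}

#: Reported percentage change, current service vs virtual clinic + T&E.
REFERENCE_PCT_CHANGE = {
    "new_attendances": 0, "followups": -2,
    "util_clinic_session": 0, "util_nurse": -1,
    "util_consultation_room": -4, "util_injection_bed": 28,
    "n_injections": 27, "costing": 25, "revenue": 21, "surplus": 10,
}

#: Monthly new attendances at the reference service (forecast level).
MONTHLY_NEW_ATTENDANCES = 119
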