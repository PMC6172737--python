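# Default scenario inputs for the retinal service simulator.
#
# STATUS: every value in this file is ASSUMED.  Resource capacities, session
# templates, visit durations and tariffs for the motivating service were not
# available; these defaults are chosen to be operationally plausible for a
# mid-size English hospital retinal clinic and are calibrated only for
# plausibility.  Analyses of absolute utilisation or money levels must
# replace them with local values; relative scenario comparisons are the
# supported use.

booking:
  dna_prob: 0.05            # per-appointment did-not-attend probability
  cancel_prob: 0.03         # per-appointment cancellation probability
  rebook_within_days: 14    # one rebooking attempt within this many days
  slot_minutes: 20          # calendar slot granularity

resources:
  clinic_session:           # bookable clinic time (slot calendar source)
    weekly_schedule:        # weekday (0 = Monday): [units, minutes per unit]
      0: [6, 240]
      1: [6, 240]
      2: [6, 240]
      3: [6, 240]
      4: [6, 240]
    minutes_per_visit:
      new_referral: 30
      injection: 20
      injection_fu: 20
      laser: 30
      laser_fu: 20
      observation_fu: 20
  nurse:
    weekly_schedule:
      0: [4, 420]
      1: [4, 420]
      2: [4, 420]
      3: [4, 420]
      4: [4, 420]
    minutes_per_visit:
      new_referral: 15
      injection: 20
      injection_fu: 10
      laser: 15
      laser_fu: 10
      observation_fu: 10
      virtual_fu: 5         # nurse-led review of virtual-clinic images
  consultation_room:
    weekly_schedule:
      0: [3, 420]
      1: [3, 420]
      2: [3, 420]
      3: [3, 420]
      4: [3, 420]
    minutes_per_visit:
      new_referral: 30
      injection_fu: 15
      laser_fu: 15
      observation_fu: 15
  injection_bed:
    weekly_schedule:
      0: [1, 300]
      1: [1, 300]
      2: [1, 300]
      3: [1, 300]
      4: [1, 300]
    minutes_per_visit:
      injection: 15
  virtual_capacity:         # imaging/review sessions out of the main clinic
    weekly_schedule:
      0: [2, 240]
      1: [2, 240]
      2: [2, 240]
      3: [2, 240]
      4: [2, 240]
    minutes_per_visit:
      virtual_fu: 10

tariffs:
  revenue:                  # GBP billed per attended visit
    new_referral: 150
    injection: 740          # procedure plus anti-VEGF drug
    injection_fu: 89        # outpatient follow-up assessment tariff
    laser: 200
    laser_fu: 89
    observation_fu: 89
    virtual_fu: 89          # billed as a follow-up review (revenue-neutral shift)
  cost:                     # GBP cost components per attended visit
    new_referral: {staff: 80, facility: 40}
    injection: {staff: 60, drug: 550, facility: 30}
    injection_fu: {staff: 59, facility: 30}
    laser: {staff: 100, facility: 50}
    laser_fu: {staff: 59, facility: 30}
    observation_fu: {staff: 59, facility: 30}   # £89: hospital review cost
  virtual_fu_cost: 37.5     # midpoint of the £30-45 community review band

simulation:
  horizon_months: 15        # simulated; first warmup_months discarded
  warmup_months: 3
  replications: 100
  seed: 0
  p_treated_new: 0.157      # share of new patients entering the treated pathway
  monthly_new_arrivals: 119 # mean new patients per month (all conditions)
  growth_rate: 0.0          # annual population growth applied to arrivals

initial_cohort:             # prevalent caseload at scenario start (desk scale)
  n: 1000
  treated_share: 0.182      # 950 of 5206 active patients are in treatment
  eligible: 172             # 894 virtual-clinic-eligible, same scale (x 1000/5206)
  years: [2, 3]             # care years the prevalent patients are entering
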