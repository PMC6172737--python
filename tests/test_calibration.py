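"""Calibration operations against brute-force oracles and fixed points."""

import numpy as np
import pandas as pd
import pytest

import retinasim as rs
from retinasim.records import ACTIVITY_CATEGORY, Condition, VisitStatus, VisitType
from retinasim.synthetic import window_end

from conftest import make_record


class TestCountEvents:
    def test_quarterly_injections_counted_in_year_one(self):
        rec = make_record("p", Condition.AMD, [
            (f"2014-{m:02d}-15", VisitType.injection) for m in (1, 4, 7, 10)])
        out = rs.count_events([rec], "injection")
        assert out.loc[0, "year"] == 1 and out.loc[0, "count"] == 4

    def test_years_beyond_three_pooled(self):
        rec = make_record("p", Condition.DR, [
            ("2013-01-10", VisitType.observation_fu),
            ("2017-06-10", VisitType.observation_fu)])
        out = rs.count_events([rec], "observation")
        assert sorted(out["year"]) == [1, 3]

    def test_matches_brute_force_row_scan(self, small_records):
        for category in ("injection", "observation", "injection_fu"):
            out = rs.count_events(small_records, category)
            brute = sum(
                1 for rec in small_records for v in rec.visits
                if v.status is VisitStatus.attended
                and ACTIVITY_CATEGORY[v.vtype] == category)
            assert out["count"].sum() == brute

    def test_reference_injection_total(self, reference_records):
        out = rs.count_events(reference_records, "injection")
        assert out[out.condition == "AMD"]["count"].sum() == 3295

    def test_no_attended_visits_excluded_with_warning(self):
        recs = [
            make_record("a", Condition.AMD, [("2014-01-01", VisitType.injection)]),
            make_record("b", Condition.AMD,
                        [("2014-01-01", VisitType.injection, VisitStatus.dna)]),
        ]
        with pytest.warns(UserWarning, match="no attended"):
            out = rs.count_events(recs, "injection")
        assert set(out["patient_id"]) == {"a"}


class TestEstimateMix:
    def test_known_proportions(self):
        recs = (
            [make_record(f"a{i}", Condition.AMD, []) for i in range(172)]
            + [make_record(f"d{i}", Condition.DR, []) for i in range(423)]
            + [make_record(f"m{i}", Condition.MR, []) for i in range(405)]
        )
        mix = rs.estimate_mix(recs)
        assert mix.as_tuple() == pytest.approx((0.172, 0.423, 0.405))

    def test_single_patient(self):
        mix = rs.estimate_mix([make_record("a", Condition.AMD, [])])
        assert mix.as_tuple() == (1.0, 0.0, 0.0)

    def test_sums_to_one(self, small_records):
        assert sum(rs.estimate_mix(small_records).as_tuple()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rs.estimate_mix([])


class TestActivityTable:
    def test_reference_column_sums(self, reference_records):
        table = rs.activity_table(reference_records)
        assert table.condition_totals[Condition.AMD] == 3295 + 4851 + 1208
        assert table.condition_totals[Condition.DR] == 425 + 599 + 315 + 848 + 4790
        assert table.grand_total == 22129

    def test_invariant_to_order_and_non_attendance(self, small_records):
        base = rs.activity_table(small_records).frame
        reordered = rs.activity_table(list(reversed(small_records))).frame
        assert base.equals(reordered)
        # strip all DNA/cancelled rows: totals must not move
        stripped = [
            rs.PatientRecord(r.patient_id, r.condition, r.attended_visits(),
                             r.discharged_year)
            for r in small_records]
        assert base.equals(rs.activity_table(stripped).frame)

    def test_empty_is_all_zero(self):
        table = rs.activity_table([])
        assert table.grand_total == 0 and (table.frame == 0).all().all()


class TestEstimateDischarge:
    def test_reference_totals(self, reference_records):
        model = rs.estimate_discharge(reference_records)
        assert model.total_discharged == 1324
        treated = sum(v for (c, s, y), v in model.n_discharged.items()
                      if s == "treated")
        assert treated == 75

    def test_cohort_share_convention(self, reference_records):
        model = rs.estimate_discharge(reference_records)
        assert model.cohort_share("treated") == pytest.approx(75 / 6530, abs=1e-9)
        assert model.cohort_share("observation") == pytest.approx(1249 / 6530, abs=1e-9)

    def test_hand_counted_toy_probability(self):
        recs = []
        for i in range(10):
            dy = 1 if i < 3 else None
            recs.append(make_record(f"p{i}", Condition.DR,
                                    [("2014-01-05", VisitType.observation_fu)],
                                    discharged_year=dy))
        model = rs.estimate_discharge(
            recs, window_end=pd.Timestamp("2015-01-05"))
        assert model.p(Condition.DR, "observation", 1) == pytest.approx(0.3)

    def test_nobody_discharged_gives_zero_probs(self, small_spec):
        import dataclasses
        spec = dataclasses.replace(small_spec, discharge_counts={})
        model = rs.estimate_discharge(rs.generate_cohort(spec))
        assert model.total_discharged == 0
        assert all(p == 0.0 for p in model.prob.values())

    def test_sum_matches_flagged_records(self, small_records):
        model = rs.estimate_discharge(small_records)
        flagged = sum(1 for r in small_records if r.discharged_year is not None)
        assert model.total_discharged == flagged


class TestEligibility:
    def naive_filter(self, records, as_of):
        """Independent double-loop oracle for the eligibility predicate."""
        lo24 = as_of - pd.DateOffset(months=24)
        lo6 = as_of - pd.DateOffset(months=6)
        out = set()
        for rec in records:
            if rec.discharged_year is not None:
                continue
            attended, treated_recent = False, False
            for v in rec.visits:
                if v.status is not VisitStatus.attended:
                    continue
                if lo24 < v.date <= as_of:
                    attended = True
                if v.vtype in (VisitType.injection, VisitType.laser) \
                        and lo6 < v.date <= as_of:
                    treated_recent = True
            if attended and not treated_recent:
                out.add(rec.patient_id)
        return out

    def test_matches_naive_oracle_on_small_cohort(self, small_records, small_spec):
        as_of = window_end(small_spec)
        assert rs.select_virtual_clinic_eligible(small_records, as_of) == \
            self.naive_filter(small_records, as_of)

    def test_planted_count_recovered(self, small_records, small_spec):
        as_of = window_end(small_spec)
        got = rs.select_virtual_clinic_eligible(small_records, as_of)
        assert len(got) == small_spec.eligible_planted

    @pytest.mark.parametrize("visits,expected", [
        # injection 3 months before as_of: treatment too recent
        ([("2015-12-20", VisitType.injection),
          ("2016-01-10", VisitType.observation_fu)], False),
        # last attendance 25 months before as_of: fell out of follow-up
        ([("2014-02-20", VisitType.observation_fu)], False),
        # monitoring 4 months ago, last injection 8 months ago: eligible
        ([("2015-07-20", VisitType.injection),
          ("2015-11-25", VisitType.observation_fu)], True),
        # DNA'd recent visit does not count as attendance
        ([("2015-11-25", VisitType.observation_fu, VisitStatus.dna)], False),
    ])
    def test_boundary_cases(self, visits, expected):
        rec = make_record("p", Condition.MR, visits)
        got = rs.select_virtual_clinic_eligible([rec], pd.Timestamp("2016-03-31"))
        assert (rec.patient_id in got) is expected

    def test_empty_set(self):
        assert rs.select_virtual_clinic_eligible([], pd.Timestamp("2016-03-31")) \
            == set()


class TestModelResults:
    def test_fit_summary_and_json_round_trip(self, small_records, small_spec,
                                             tmp_path):
        res = rs.RetinalServiceModel(small_records).fit(
            eligibility_as_of=window_end(small_spec))
        text = res.summary()
        assert "Case mix" in text and "Activity" in text
        path = tmp_path / "params.json"
        res.to_json(path)
        back = rs.CalibrationResult.from_json(path)
        assert back.case_mix.proportions == res.case_mix.proportions
        assert back.eligible_ids == res.eligible_ids
        assert back.activity.frame.equals(res.activity.frame)
        assert back.discharge.prob == res.discharge.prob
        assert set(back.count_distributions) == set(res.count_distributions)
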