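"""Valuation rules: intervention, index stay, follow-up, death zeroing, tariffs."""

import numpy as np
import pandas as pd
import pytest

from prehabcea import (
    UnitCostTable,
    ValueSet,
    apply_valueset,
    default_unit_costs,
    load_unit_costs,
    load_valueset,
    toy_valueset,
    utilities_from_states,
    value_costs,
    value_followup_visit,
    value_index_stay,
    value_intervention,
    write_valueset,
)
from prehabcea.schema import FOLLOWUP_CATEGORIES, RESOURCE_ITEMS, VISIT_MONTHS, cost_col, ru_col
from prehabcea.valuation import apply_death_zeroing, value_followup_all


def _one_record(**overrides):
    base = {
        "id": "P0", "arm": "IG", "sessions": 0.0, "setting": None,
        "sdm": False, "sdm_physicians": np.nan, "sdm_therapists": np.nan,
        "sdm_family": False, "surgery_done": True, "index_bill": 5000.0,
        "los_days": 10.0, "death_day": np.nan,
    }
    base.update(overrides)
    for item in RESOURCE_ITEMS:
        for t in VISIT_MONTHS:
            base.setdefault(ru_col(item, t), 0.0)
    return pd.DataFrame([base])


class TestIntervention:
    def test_control_arm_is_exactly_zero(self, small_records, unit_costs):
        cost = value_intervention(small_records, unit_costs)
        assert (cost[small_records["arm"] == "CG"] == 0.0).all()

    def test_screening_only(self, unit_costs):
        rec = _one_record(sessions=0.0, sdm=False)
        assert value_intervention(rec, unit_costs).iloc[0] == 26.0

    def test_linear_composition(self, unit_costs):
        rec = _one_record(
            sessions=30.0, setting="outpatient", sdm=True,
            sdm_physicians=2.0, sdm_therapists=1.0,
        )
        expected = (
            unit_costs.screening
            + unit_costs.sdm_base + 2 * unit_costs.sdm_physician + unit_costs.sdm_therapist
            + 30 * unit_costs.session_costs["outpatient"]
        )
        assert value_intervention(rec, unit_costs).iloc[0] == pytest.approx(expected)

    def test_sessions_without_setting_rejected(self, unit_costs):
        rec = _one_record(sessions=10.0, setting=None)
        with pytest.raises(ValueError, match="setting"):
            value_intervention(rec, unit_costs)


class TestIndexStay:
    def test_no_surgery_is_zero(self, unit_costs):
        rec = _one_record(surgery_done=False, index_bill=np.nan, los_days=np.nan)
        assert value_index_stay(rec, unit_costs).iloc[0] == 0.0

    def test_copayment_rule(self):
        uc = UnitCostTable(investment_per_case=0.0)
        rec = _one_record(index_bill=5000.0, los_days=10.0)
        assert value_index_stay(rec, uc).iloc[0] == pytest.approx(5000 + 0.5 * 10 * 10)

    def test_copayment_cap_binds(self):
        uc = UnitCostTable(investment_per_case=0.0)
        rec = _one_record(index_bill=0.0, los_days=40.0)
        assert value_index_stay(rec, uc).iloc[0] == pytest.approx(0.5 * 10 * 28)

    def test_missing_bill_flags_for_imputation(self, unit_costs):
        rec = _one_record(index_bill=np.nan)
        assert np.isnan(value_index_stay(rec, unit_costs).iloc[0])


class TestFollowup:
    def test_all_zero_answers(self, unit_costs):
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        out = value_followup_visit(answers, unit_costs)
        assert set(out) == set(FOLLOWUP_CATEGORIES)
        assert all(v == 0.0 for v in out.values())

    def test_linearity_physician_visits(self, unit_costs):
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        answers["physician_visits"] = 2
        out = value_followup_visit(answers, unit_costs)
        assert out["visits_physician"] == 2 * unit_costs.item_costs["physician_visits"]

    def test_informal_care_substitution_wage(self, unit_costs):
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        answers["informal_care_hours"] = 10
        out = value_followup_visit(answers, unit_costs)
        assert out["informal_care"] == 10 * unit_costs.item_costs["informal_care_hours"]

    def test_missing_answers_propagate(self, unit_costs):
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        answers["hospital_days"] = np.nan
        out = value_followup_visit(answers, unit_costs)
        assert np.isnan(out["hospital_inpatient"])
        assert out["visits_physician"] == 0.0

    def test_negative_counts_rejected(self, unit_costs):
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        answers["hospital_days"] = -1
        with pytest.raises(ValueError, match="negative"):
            value_followup_visit(answers, unit_costs)

    def test_medication_never_valued(self):
        uc = default_unit_costs()
        answers = {item: 0.0 for item in RESOURCE_ITEMS}
        answers["medication_uses"] = 99
        out = value_followup_visit(answers, uc)
        assert all(v == 0.0 for v in out.values())


class TestDeathZeroing:
    def test_survivor_unchanged(self, unit_costs):
        rec = _one_record()
        comp = value_followup_all(rec, unit_costs)
        pd.testing.assert_frame_equal(apply_death_zeroing(comp, rec), comp)

    def test_death_before_surgery(self, unit_costs):
        rec = _one_record(
            surgery_done=False, index_bill=np.nan, los_days=np.nan, death_day=10.0,
            **{ru_col("hospital_days", 3): 5.0},
        )
        comp = value_costs(rec, unit_costs)
        assert comp["cost_index"].iloc[0] == 0.0
        assert comp[[cost_col(c, t) for c in FOLLOWUP_CATEGORIES for t in VISIT_MONTHS]].iloc[0].sum() == 0.0
        assert comp["cost_intervention"].iloc[0] == 26.0  # retained

    def test_death_mid_year_keeps_earlier_windows(self, unit_costs):
        rec = _one_record(death_day=213.0)  # month ~7
        for t in VISIT_MONTHS:
            rec[ru_col("physician_visits", t)] = 3.0
        comp = value_costs(rec, unit_costs)
        u = unit_costs.item_costs["physician_visits"]
        assert comp[cost_col("visits_physician", 3)].iloc[0] == 3 * u
        assert comp[cost_col("visits_physician", 6)].iloc[0] == 3 * u
        assert comp[cost_col("visits_physician", 9)].iloc[0] == 0.0
        assert comp[cost_col("visits_physician", 12)].iloc[0] == 0.0


class TestValueSet:
    def test_best_state_anchor(self, valueset):
        assert apply_valueset("11111", valueset) == 1.0

    def test_toy_closed_form(self, valueset):
        # mean of 1 - 0.25*(level-1) per dimension
        assert apply_valueset("12345", valueset) == pytest.approx(
            np.mean([1 - 0.25 * (l - 1) for l in (1, 2, 3, 4, 5)])
        )
        assert apply_valueset("55555", valueset) == 0.0

    def test_national_tariff_anchors_from_config(self, tmp_path):
        # synthetic stand-in for a national value set: affine rescaling of
        # the toy tariff to the anchors 1 (11111) and -0.661 (55555)
        toy = toy_valueset()
        values = {s: -0.661 + 1.661 * u for s, u in toy.values.items()}
        vs = ValueSet(values=values, anchor_best=1.0, anchor_worst=-0.661, name="synthetic-national")
        path = tmp_path / "vs.json"
        write_valueset(vs, path)
        back = load_valueset(path)
        assert back.utility("55555") == pytest.approx(-0.661)
        assert back.utility("11111") == pytest.approx(1.0)

    def test_anchor_mismatch_rejected(self):
        toy = toy_valueset()
        with pytest.raises(ValueError, match="anchor"):
            ValueSet(values=toy.values, anchor_best=1.0, anchor_worst=-0.661)

    def test_malformed_state_rejected(self, valueset):
        for bad in ("1111", "11116", "abcde"):
            with pytest.raises(ValueError):
                apply_valueset(bad, valueset)

    def test_death_zero_utility(self, valueset):
        rec = _one_record(death_day=200.0)
        rec["eq5d_baseline"] = "11111"
        for t in VISIT_MONTHS:
            rec[f"eq5d_{t}m"] = "11111" if t <= 6 else None
        utils = utilities_from_states(rec, valueset)
        assert utils["util_3m"].iloc[0] == 1.0
        assert utils["util_9m"].iloc[0] == 0.0
        assert utils["util_12m"].iloc[0] == 0.0


class TestInvariants:
    def test_homogeneity_in_unit_costs(self, small_records, unit_costs):
        # zero out the billing data: the bill is recorded expenditure, not a
        # unit cost, so homogeneity applies to everything valued *from* units
        rec = small_records.copy()
        rec["index_bill"] = np.where(rec["surgery_done"], 0.0, np.nan)
        base = value_costs(rec, unit_costs)
        scaled = value_costs(rec, unit_costs.scaled(2.5))
        pd.testing.assert_frame_equal(scaled, base * 2.5)

    def test_total_additivity(self, small_table):
        from prehabcea import assemble_totals
        from prehabcea.schema import followup_cost_columns

        total = assemble_totals(small_table, winsorised=False)
        manual = (
            small_table["cost_intervention"]
            + small_table["cost_index"]
            + small_table[followup_cost_columns()].sum(axis=1, skipna=False)
        )
        pd.testing.assert_series_equal(total, manual, check_names=False)

    def test_unit_cost_table_round_trip(self, tmp_path, unit_costs):
        path = tmp_path / "uc.json"
        unit_costs.to_json(path)
        assert load_unit_costs(path) == unit_costs

    def test_incomplete_unit_costs_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            UnitCostTable(item_costs={"physician_visits": 45.0})
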