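"""Analysis-matrix orchestration, population selection, reporting, CLI."""

import numpy as np
import pandas as pd
import pytest

from prehabcea import (
    AnalysisSpec,
    SimConfig,
    complete_case_mask,
    cost_overview_table,
    results_table,
    round_half_up,
    run_analysis,
    select_population,
    simulate_trial,
)
from prehabcea.study_runner import build_analysis_table, write_bundle


@pytest.fixture(scope="module")
def records():
    return simulate_trial(SimConfig(n_per_arm=(150, 140), seed=21))


def _complete(table):
    """Fill analysis NaN without touching structural sentinels."""
    out = table.copy()
    cols = [
        c
        for c in out.columns
        if pd.api.types.is_numeric_dtype(out[c]) and c not in ("death_day", "sessions")
    ]
    out[cols] = out[cols].fillna(0.0)
    return out


def _fast_spec(**kw):
    defaults = dict(seed=5, m=3, iterations=3, bootstrap_b=400)
    defaults.update(kw)
    return AnalysisSpec(**defaults)


class TestSelectPopulation:
    def test_itt_keeps_everyone(self, small_table):
        ig, cg, pairs = select_population(_complete(small_table), _fast_spec(variant="ITT"))
        assert len(ig) + len(cg) == len(small_table)
        assert pairs is None

    def test_pp15_matched_equal_arms(self, small_table):
        data = _complete(small_table)
        ig, cg, pairs = select_population(data, _fast_spec(variant="PP15"))
        assert len(ig) == len(cg) == len(pairs)
        assert (ig["sessions"].astype(float) >= 15).all()

    def test_pp15op_requires_surgery(self, small_table):
        data = _complete(small_table)
        ig, _, _ = select_population(data, _fast_spec(variant="PP15OP"))
        assert ig["surgery_done"].all()

    def test_sa_effects_removes_exactly_the_dead(self, small_table):
        data = _complete(small_table)
        ig, cg, _ = select_population(data, _fast_spec(variant="SA_EFFECTS", effect_kind="dcdl"))
        n_dead = small_table["death_day"].notna().sum()
        assert len(ig) + len(cg) == len(small_table) - n_dead
        assert ig["death_day"].isna().all() and cg["death_day"].isna().all()

    def test_complete_case_is_effect_specific(self, small_table):
        m_qaly = complete_case_mask(small_table, "qaly")
        m_dcdl = complete_case_mask(small_table, "dcdl")
        # the 3-month EQ-5D extra missingness makes the QALY-complete
        # population strictly smaller
        assert m_qaly.sum() < m_dcdl.sum()

    def test_partitioning_subgroups_partition_itt(self, small_table):
        data = _complete(small_table)
        for lo, hi in [
            ("age_below_median", "age_at_or_above_median"),
            ("sex_female", "sex_male"),
            ("frailty_prefrail", "frailty_frail"),
            ("care_level_0", "care_level_ge1"),
            ("cognition_normal", "cognition_impaired"),
        ]:
            a = select_population(data, _fast_spec(subgroup=lo))
            b = select_population(data, _fast_spec(subgroup=hi))
            n = sum(len(x) for x in (*a[:2], *b[:2]))
            assert n == len(data), (lo, hi)

    def test_empty_subgroup_raises(self, small_table):
        data = _complete(small_table).assign(moca=30)
        with pytest.raises(ValueError, match="empty arm"):
            select_population(data, _fast_spec(subgroup="cognition_impaired"))

    def test_setting_subgroup_triggers_matching(self, small_table):
        data = _complete(small_table)
        ig, cg, pairs = select_population(data, _fast_spec(subgroup="setting_outpatient"))
        assert pairs is not None and len(ig) == len(cg)
        assert ig["setting"].isin(
            ("mobile", "outpatient", "outpatient_transport", "part_inpatient")
        ).all()


class TestRunAnalysis:
    def test_end_to_end_determinism(self, records):
        spec = _fast_spec(variant="ITT", effect_kind="qaly")
        a = run_analysis(records, spec)
        b = run_analysis(records, spec)
        assert a["incremental"] == b["incremental"]
        assert a["manifest"] == b["manifest"]
        np.testing.assert_array_equal(a["cloud"].delta_cost, b["cloud"].delta_cost)
        np.testing.assert_array_equal(a["cloud"].delta_effect, b["cloud"].delta_effect)
        assert a["ceac"] == b["ceac"]

    def test_sa_costs_differs_only_by_winsorisation_switch(self, records):
        itt = run_analysis(records, _fast_spec(variant="ITT"))
        sa = run_analysis(records, _fast_spec(variant="SA_COSTS"))
        m_itt, m_sa = dict(itt["manifest"]), dict(sa["manifest"])
        assert m_itt.pop("winsorised") is True and m_sa.pop("winsorised") is False
        assert m_itt.pop("variant") == "ITT" and m_sa.pop("variant") == "SA_COSTS"
        assert m_itt == m_sa  # everything else identical
        # raw costs can only be >= winsorised costs
        assert sa["arms"]["IG"]["cost_mean"] >= itt["arms"]["IG"]["cost_mean"]

    def test_cc_skips_imputation_but_winsorises(self, records):
        b = run_analysis(records, _fast_spec(variant="CC", effect_kind="dcdl"))
        assert b["manifest"]["imputed"] is False
        assert b["manifest"]["winsorised"] is True
        assert b["manifest"]["n_ig"] < (records["arm"] == "IG").sum()

    def test_dominant_configuration_detected(self):
        # strong follow-up savings make the intervention cheaper overall
        # while still more effective: the SE quadrant verdict must emerge
        cfg = SimConfig(
            n_per_arm=(900, 900), seed=31, effect_utility=0.06,
            effect_cost_followup=5000.0, mortality_12m=0.0,
            missing_visit_prob=0.0, missing_3m_extra=0.0,
        )
        rec = simulate_trial(cfg)
        b = run_analysis(rec, _fast_spec(variant="ITT", effect_kind="qaly", bootstrap_b=500))
        assert b["incremental"]["verdict"] == "intervention_dominates"

    def test_sa_effects_rejected_for_qaly(self):
        with pytest.raises(ValueError):
            AnalysisSpec(variant="SA_EFFECTS", effect_kind="qaly")

    def test_rubin_mode_reports_pooled_intervals(self, records):
        b = run_analysis(records, _fast_spec(variant="ITT", pooling="rubin"))
        assert "rubin" in b
        lo, hi = b["rubin"]["delta_cost"]["ci"]
        assert lo < b["rubin"]["delta_cost"]["estimate"] < hi

    def test_bundle_written_to_disk(self, tmp_path, records):
        b = run_analysis(records, _fast_spec(variant="ITT"))
        out = write_bundle(b, tmp_path / "itt", plots=True)
        assert (out / "results.json").exists()
        assert (out / "cloud.csv").exists()
        assert (out / "ce_plane.png").exists()


class TestReporting:
    def test_round_half_up(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(2.5) == 3.0
        assert round_half_up(-0.5) == -1.0
        assert round_half_up(4.445, 2) == 4.45
        assert np.isnan(round_half_up(float("nan")))

    def test_results_table_rows_and_dominance_cell(self, records):
        b1 = run_analysis(records, _fast_spec(variant="ITT", effect_kind="dcdl"))
        b1["incremental"]["verdict"] = "intervention_dominates"
        tab = results_table([b1, {"error": "empty subgroup"}])
        assert len(tab) == 1  # failed bundle flagged, not emitted
        assert tab["ICER"].iloc[0] == "Intervention dominates"
        assert "events_IG" in tab.columns

    def test_icer_cell_rounded_half_up_from_raw(self, records):
        b = run_analysis(records, _fast_spec(variant="ITT", effect_kind="qaly"))
        inc = b["incremental"]
        inc["verdict"], inc["icer"], inc["quadrant"] = "icer", 45547.4, "NE"
        tab = results_table([b])
        assert tab["ICER"].iloc[0] == "45,547"

    def test_cost_overview_additivity(self):
        from prehabcea import build_analysis_table, default_unit_costs, generate_trial, toy_valueset

        rec = generate_trial(SimConfig(n_per_arm=(80, 80), seed=17, missing_visit_prob=0.0, missing_3m_extra=0.0))
        complete = build_analysis_table(rec, default_unit_costs(), toy_valueset(), winsorised=True)
        tab = cost_overview_table(complete)
        for arm in ("IG", "CG"):
            parts = (
                tab.loc["Intervention", f"{arm}_mean"]
                + tab.loc["Index hospital stay", f"{arm}_mean"]
                + tab.loc["12-month follow-up", f"{arm}_mean"]
            )
            assert tab.loc["Total costs", f"{arm}_mean"] == pytest.approx(parts, abs=2)


class TestCli:
    def test_simulate_run_report_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from prehabcea.cli import main

        runner = CliRunner()
        cfg = tmp_path / "cfg.json"
        cfg.write_text('{"n_per_arm": [60, 60], "missing_visit_prob": 0.1, "missing_3m_extra": 0.1}')
        r = runner.invoke(main, ["simulate", "--config", str(cfg), "--seed", "3", "--out", str(tmp_path / "sim")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            main,
            [
                "run", "--data", str(tmp_path / "sim" / "records.csv"),
                "--variant", "ITT", "--effect", "dcdl", "--seed", "3",
                "--m", "2", "--iterations", "2", "--bootstrap-b", "200",
                "--out", str(tmp_path / "out"),
            ],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["report", "--in", str(tmp_path / "out")])
        assert r.exit_code == 0, r.output
        assert "ITT" in r.output
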