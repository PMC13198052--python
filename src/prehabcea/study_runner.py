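"""Orchestration of the analysis matrix.

Runs any of the analysis variants over a patient-record table and
produces a self-describing results bundle:

* ``ITT`` - intention to treat, winsorised + imputed (the main analysis);
* ``CC`` - complete cases only (winsorised, no imputation; completeness
  is judged relative to the chosen effect measure, so the complete-case
  population differs between the QALY and DCDL analyses);
* ``PP15`` - per-protocol, intervention patients with >= 15 supervised
  sessions plus a propensity-matched control group;
* ``PP15OP`` - PP15 patients who additionally underwent the index
  surgery, again with a matched control group;
* ``SA_COSTS`` - sensitivity analysis without winsorisation;
* ``SA_EFFECTS`` - sensitivity analysis excluding patients who died
  (DCDL/WHODAS only; probes the worst-score-at-death assumption).

Pipeline order: valuation -> death rules -> winsorisation (skipped for
SA_COSTS) -> chained-equation imputation + individual-level combination
(skipped for CC) -> population selection / matching -> effect panels ->
incremental statistics + bootstrap + CEAC + plane.  Every run carries a
manifest with seeds and config hashes; identical config + seed yields
identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance_match import MATCHED_LABEL, MatchSpec, propensity_match
from .cea_engine import (
    BootstrapCloud,
    attach_cis,
    bootstrap_cloud,
    ce_plane,
    ceac,
    incremental,
)
from .cost_processing import WinsorSpec, assemble_totals, winsorise_costs
from .impute import ImputeSpec, combine_individual, impute_dataset, rubin_pool
from .outcomes import build_effect_panel
from .schema import VISIT_MONTHS, followup_cost_columns, util_col
from .valuation import (
    UnitCostTable,
    ValueSet,
    default_unit_costs,
    toy_valueset,
    utilities_from_states,
    value_costs,
)

logger = logging.getLogger(__name__)

VARIANTS = ("ITT", "CC", "PP15", "PP15OP", "SA_COSTS", "SA_EFFECTS")

#: Propensity-model covariates for matched analyses; the baseline care
#: level is dropped when the outcome is DCDL (it defines the outcome's
#: baseline).
MATCH_COVARIATES = [
    "age",
    "sex",
    "bmi",
    "cci",
    "frailty",
    "care_level_baseline",
    "util_baseline",
    "moca",
    "whodas_baseline",
    "specialty",
]

SUBGROUPS = (
    "age_below_median",
    "age_at_or_above_median",
    "sex_female",
    "sex_male",
    "surgery_orthopaedic",
    "surgery_cardiac",
    "surgery_tumour",
    "surgery_other",
    "frailty_prefrail",
    "frailty_frail",
    "setting_outpatient",
    "setting_inpatient",
    "care_level_0",
    "care_level_ge1",
    "cognition_normal",
    "cognition_impaired",
)

#: Settings pooled into the "outpatient" subgroup (everything that is
#: not an overnight inpatient stay).
OUTPATIENT_SETTINGS = ("mobile", "outpatient", "outpatient_transport", "part_inpatient")


@dataclass
class AnalysisSpec:
    """One cell of the analysis matrix."""

    variant: str = "ITT"
    effect_kind: str = "qaly"
    subgroup: str | None = None
    seed: int = 0
    m: int = 20
    iterations: int = 10
    bootstrap_b: int = 10_000
    pooling: str = "individual"  # or "rubin" (comparison mode)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.effect_kind not in ("qaly", "dcdl", "whodas"):
            raise ValueError("effect_kind must be qaly, dcdl or whodas")
        if self.variant == "SA_EFFECTS" and self.effect_kind == "qaly":
            raise ValueError(
                "SA_EFFECTS applies to the cost-effectiveness outcomes (dcdl, whodas); "
                "the QALY already handles death through zero utilities"
            )
        if self.subgroup is not None and self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.pooling not in ("individual", "rubin"):
            raise ValueError("pooling must be 'individual' or 'rubin'")


def _child_seed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


# --------------------------------------------------------------------------
# analysis table
# --------------------------------------------------------------------------


def build_analysis_table(
    records: pd.DataFrame,
    unit_costs: UnitCostTable,
    valueset: ValueSet,
    winsorised: bool = True,
    winsor_spec: WinsorSpec | None = None,
) -> pd.DataFrame:
    """Valued, death-ruled, (optionally) winsorised per-patient table.

    Index: patient id.  Death-rule values (post-death zero costs and
    utilities, care level 5 and WHODAS 60 at death) are filled here so
    that imputation treats them as observed.
    """
    rec = records.set_index("id")
    comp = value_costs(records, unit_costs).set_axis(rec.index)
    if winsorised:
        comp = winsorise_costs(comp, winsor_spec)
    utils = utilities_from_states(records, valueset).set_axis(rec.index)

    died = rec["death_day"].notna()
    care12 = rec["care_level_12m"].astype(float).where(~died, 5.0)
    item_cols = [f"whodas_item{j + 1}_12m" for j in range(12)]
    whodas12 = rec[item_cols].astype(float).sum(axis=1, skipna=False).where(~died, 60.0)

    out = pd.DataFrame(index=rec.index)
    for c in (
        "arm",
        "age",
        "sex",
        "bmi",
        "cci",
        "frailty",
        "care_level_baseline",
        "moca",
        "whodas_baseline",
        "specialty",
        "sessions",
        "setting",
        "surgery_done",
        "death_day",
    ):
        out[c] = rec[c]
    out["care_level_12m"] = care12
    out["whodas_12m"] = whodas12
    # numeric encodings so the chained-equations model can condition on
    # arm (essential: imputing without it would shrink arm differences)
    # and the categorical baseline covariates
    out["arm_ig"] = (rec["arm"] == "IG").astype(float)
    out["sex_f"] = (rec["sex"] == "F").astype(float)
    out["frail"] = (rec["frailty"] == "frail").astype(float)
    for s in ("orthopaedic", "cardiac", "tumour"):
        out[f"specialty_{s}"] = (rec["specialty"] == s).astype(float)
    out = pd.concat([out, utils, comp], axis=1)
    return out


def complete_case_mask(table: pd.DataFrame, effect_kind: str) -> pd.Series:
    """Rows with complete cost data and complete data for the chosen effect."""
    cost_cols = ["cost_index"] + [c for c in followup_cost_columns() if c in table.columns]
    cost_ok = table[cost_cols].notna().all(axis=1)
    if effect_kind == "qaly":
        eff_ok = table[[util_col(t) for t in VISIT_MONTHS]].notna().all(axis=1)
    elif effect_kind == "dcdl":
        eff_ok = table["care_level_12m"].notna()
    else:
        eff_ok = table["whodas_12m"].notna()
    return cost_ok & eff_ok


# --------------------------------------------------------------------------
# population selection
# --------------------------------------------------------------------------


def _subgroup_mask(table: pd.DataFrame, subgroup: str) -> pd.Series:
    age_median = table["age"].median()
    masks = {
        "age_below_median": table["age"] < age_median,
        "age_at_or_above_median": table["age"] >= age_median,
        "sex_female": table["sex"] == "F",
        "sex_male": table["sex"] == "M",
        "surgery_orthopaedic": table["specialty"] == "orthopaedic",
        "surgery_cardiac": table["specialty"] == "cardiac",
        "surgery_tumour": table["specialty"] == "tumour",
        "surgery_other": table["specialty"] == "other",
        "frailty_prefrail": table["frailty"] == "pre-frail",
        "frailty_frail": table["frailty"] == "frail",
        "care_level_0": table["care_level_baseline"] == 0,
        "care_level_ge1": table["care_level_baseline"] >= 1,
        "cognition_normal": table["moca"] >= 26,
        "cognition_impaired": table["moca"] < 26,
    }
    return masks[subgroup]


def select_population(
    table: pd.DataFrame, spec: AnalysisSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """(intervention table, control table, matched pairs or None).

    Applies the variant's population rule and, for per-protocol and
    setting-subgroup analyses, 1:1 propensity matching of controls.
    Subgroup filters are applied before matching.
    """
    df = table
    if spec.variant == "SA_EFFECTS":
        df = df[df["death_day"].isna()]
    if spec.variant == "CC":
        df = df[complete_case_mask(df, spec.effect_kind)]

    needs_match = spec.variant in ("PP15", "PP15OP") or spec.subgroup in (
        "setting_outpatient",
        "setting_inpatient",
    )
    if spec.subgroup is not None and spec.subgroup not in (
        "setting_outpatient",
        "setting_inpatient",
    ):
        df = df[_subgroup_mask(df, spec.subgroup)]

    ig = df[df["arm"] == "IG"]
    cg = df[df["arm"] == "CG"]

    if spec.variant in ("PP15", "PP15OP"):
        ig = ig[ig["sessions"].astype(float) >= 15]
        if spec.variant == "PP15OP":
            ig = ig[ig["surgery_done"].astype(bool)]
    if spec.subgroup == "setting_outpatient":
        ig = ig[ig["setting"].isin(OUTPATIENT_SETTINGS)]
    elif spec.subgroup == "setting_inpatient":
        ig = ig[ig["setting"] == "inpatient"]

    if len(ig) == 0 or len(cg) == 0:
        raise ValueError(
            f"empty arm after filtering (variant={spec.variant}, subgroup={spec.subgroup})"
        )

    pairs = None
    if needs_match:
        covs = [
            c
            for c in MATCH_COVARIATES
            if not (c == "care_level_baseline" and spec.effect_kind == "dcdl")
        ]
        match_spec = MatchSpec(covariates=covs, seed=_child_seed(spec.seed, 2))
        pairs = propensity_match(ig, cg, match_spec)
        cg = cg.loc[pairs["donor_id"].to_numpy()]
    return ig, cg, pairs


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def _arm_summary(costs: np.ndarray, effects: np.ndarray, effect_kind: str) -> dict:
    out = {
        "n": int(len(costs)),
        "cost_mean": float(np.mean(costs)),
        "cost_sd": float(np.std(costs, ddof=1)) if len(costs) > 1 else 0.0,
        "effect_mean": float(np.mean(effects)),
        "effect_sd": float(np.std(effects, ddof=1)) if len(effects) > 1 else 0.0,
    }
    if effect_kind == "dcdl":
        out["n_events"] = int(np.sum(effects))
        out["pct_events"] = float(np.mean(effects) * 100.0)
    return out


def run_analysis(
    records: pd.DataFrame,
    spec: AnalysisSpec,
    unit_costs: UnitCostTable | None = None,
    valueset: ValueSet | None = None,
    winsor_spec: WinsorSpec | None = None,
    keep_cloud: bool = True,
) -> dict:
    """Execute one analysis end to end and return a results bundle."""
    uc = unit_costs or default_unit_costs()
    vs = valueset or toy_valueset()
    winsorised = spec.variant != "SA_COSTS"

    table = build_analysis_table(records, uc, vs, winsorised=winsorised, winsor_spec=winsor_spec)

    structural = [c for c in ("death_day", "sessions", "setting") if c in table.columns]
    imputed = spec.variant != "CC" and bool(
        table.drop(columns=structural).isna().any().any()
    )
    rubin = None
    if imputed:
        imp_spec = ImputeSpec(
            m=spec.m,
            iterations=spec.iterations,
            seed=_child_seed(spec.seed, 1),
            exclude=("death_day", "sessions"),
        )
        completed = impute_dataset(table, imp_spec)
        data = combine_individual(completed, mode_cols=("care_level_12m",))
        if spec.pooling == "rubin":
            rubin = _rubin_comparison(completed, spec, uc)
    else:
        data = table

    ig, cg, pairs = select_population(data, spec)

    eff_ig = build_effect_panel(ig)[spec.effect_kind].to_numpy(float)
    eff_cg = build_effect_panel(cg)[spec.effect_kind].to_numpy(float)
    # components are already winsorised (or deliberately raw): plain sums
    cost_ig = assemble_totals(ig, winsorised=False).to_numpy(float)
    cost_cg = assemble_totals(cg, winsorised=False).to_numpy(float)

    cloud = bootstrap_cloud(
        cost_ig,
        cost_cg,
        eff_ig,
        eff_cg,
        spec.effect_kind,
        B=spec.bootstrap_b,
        seed=_child_seed(spec.seed, 3),
    )
    result = attach_cis(cloud)
    curve = ceac(cloud)
    plane = ce_plane(cloud)

    manifest = {
        "package_version": __version__,
        "variant": spec.variant,
        "effect_kind": spec.effect_kind,
        "subgroup": spec.subgroup,
        "seed": spec.seed,
        "seeds": {
            "impute": _child_seed(spec.seed, 1),
            "match": _child_seed(spec.seed, 2),
            "bootstrap": _child_seed(spec.seed, 3),
        },
        "m": spec.m,
        "iterations": spec.iterations,
        "bootstrap_b": spec.bootstrap_b,
        "winsorised": winsorised,
        "imputed": imputed,
        "matched": pairs is not None,
        "label": MATCHED_LABEL if pairs is not None else "randomised comparison",
        "n_ig": int(len(ig)),
        "n_cg": int(len(cg)),
        "unit_costs_hash": _config_hash(dataclasses.asdict(uc)),
        "valueset": vs.name,
    }

    bundle = {
        "spec": dataclasses.asdict(spec),
        "manifest": manifest,
        "arms": {
            "IG": _arm_summary(cost_ig, eff_ig, spec.effect_kind),
            "CG": _arm_summary(cost_cg, eff_cg, spec.effect_kind),
        },
        "incremental": result.to_dict(),
        "ceac": {"wtp": curve.wtp.tolist(), "probability": curve.probability.tolist()},
        "plane": {
            "mean": plane.mean.tolist(),
            "cov": plane.cov.tolist(),
            "confidence": plane.confidence,
            "axis_half_widths": plane.axis_half_widths.tolist(),
            "crosses_effect_axis": plane.crosses_effect_axis,
            "crosses_cost_axis": plane.crosses_cost_axis,
            "quadrant_shares": plane.quadrant_shares,
            "degenerate": plane.degenerate,
        },
    }
    if rubin is not None:
        bundle["rubin"] = rubin
    if pairs is not None:
        bundle["pairs"] = pairs
    if keep_cloud:
        bundle["cloud"] = cloud
    return bundle


def _rubin_comparison(completed: list[pd.DataFrame], spec: AnalysisSpec, uc) -> dict:
    """Rubin's-rules pooled MDs across imputations (comparison mode).

    Per completed dataset the incremental cost and effect are computed
    with a small within-dataset bootstrap for the within variance, then
    pooled.  Reported alongside the individual-level combination.
    """
    dcs, des, vcs, ves = [], [], [], []
    b_small = max(200, spec.bootstrap_b // max(spec.m, 1))
    for k, dfk in enumerate(completed):
        ig_k, cg_k, _ = select_population(dfk, spec)
        eff_i = build_effect_panel(ig_k)[spec.effect_kind].to_numpy(float)
        eff_c = build_effect_panel(cg_k)[spec.effect_kind].to_numpy(float)
        cost_i = assemble_totals(ig_k, winsorised=False).to_numpy(float)
        cost_c = assemble_totals(cg_k, winsorised=False).to_numpy(float)
        cl = bootstrap_cloud(
            cost_i, cost_c, eff_i, eff_c, spec.effect_kind,
            B=b_small, seed=_child_seed(spec.seed, 100 + k),
        )
        dcs.append(cl.point.delta_cost)
        des.append(cl.point.delta_effect)
        vcs.append(float(np.var(cl.delta_cost, ddof=1)))
        ves.append(float(np.var(cl.delta_effect, ddof=1)))
    return {
        "delta_cost": rubin_pool(dcs, vcs),
        "delta_effect": rubin_pool(des, ves),
    }


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (report rendering only; statistics stay raw)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_eur(x: float) -> str:
    return f"{int(round_half_up(x, 0)):,}"


def cost_overview_table(table: pd.DataFrame) -> pd.DataFrame:
    """Cost-overview report: mean/SD/median/Q1/Q3 per block per arm (EUR).

    Expects an analysis-ready (valued, winsorised/imputed as desired)
    table with an ``arm`` column.
    """
    from .schema import FOLLOWUP_CATEGORIES, cost_col

    blocks: dict[str, pd.Series] = {"Intervention": table["cost_intervention"]}
    blocks["Index hospital stay"] = table["cost_index"]
    follow_cols = [c for c in followup_cost_columns() if c in table.columns]
    blocks["12-month follow-up"] = table[follow_cols].sum(axis=1, skipna=False)
    for cat in FOLLOWUP_CATEGORIES:
        cols = [cost_col(cat, t) for t in VISIT_MONTHS if cost_col(cat, t) in table.columns]
        blocks[f"  {cat}"] = table[cols].sum(axis=1, skipna=False)
    blocks["Total costs"] = (
        table["cost_intervention"] + table["cost_index"] + blocks["12-month follow-up"]
    )

    rows = []
    for name, series in blocks.items():
        row: dict[str, object] = {"block": name}
        for arm in ("IG", "CG"):
            v = series[table["arm"] == arm].dropna().to_numpy(float)
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            row.update(
                {
                    f"{arm}_mean": round_half_up(v.mean()),
                    f"{arm}_sd": round_half_up(v.std(ddof=1)) if v.size > 1 else 0.0,
                    f"{arm}_median": round_half_up(med),
                    f"{arm}_q1": round_half_up(q1),
                    f"{arm}_q3": round_half_up(q3),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("block")


def _verdict_cell(inc: dict) -> str:
    if inc["verdict"] == "intervention_dominates":
        return "Intervention dominates"
    if inc["verdict"] == "control_dominates":
        return "Control dominates"
    if inc["verdict"] == "undefined_icer":
        return "ICER undefined (zero incremental effect)"
    cell = _fmt_eur(inc["icer"])
    if inc["quadrant"] == "SW":
        cell += " (SW quadrant: less effective, less costly)"
    return cell


def results_table(bundles: list[dict]) -> pd.DataFrame:
    """Cost-utility / cost-effectiveness report, one row per analysis.

    EUR rounded to integers, utilities and percentages to two decimals
    (half-up); ICERs computed from raw values and rounded only here.
    Bundles carrying an ``error`` key (e.g. empty subgroups) are
    flagged and skipped.
    """
    rows = []
    for b in bundles:
        if "error" in b:
            logger.warning("skipping failed analysis: %s", b["error"])
            continue
        man, inc, arms = b["manifest"], b["incremental"], b["arms"]
        kind = man["effect_kind"]
        nd = 2
        row = {
            "analysis": man["variant"] + (f"/{man['subgroup']}" if man["subgroup"] else ""),
            "effect": kind,
            "N_IG": man["n_ig"],
            "N_CG": man["n_cg"],
            "cost_IG_mean": round_half_up(arms["IG"]["cost_mean"]),
            "cost_IG_sd": round_half_up(arms["IG"]["cost_sd"]),
            "cost_CG_mean": round_half_up(arms["CG"]["cost_mean"]),
            "cost_CG_sd": round_half_up(arms["CG"]["cost_sd"]),
            "incr_cost": round_half_up(inc["delta_cost"]),
            "incr_cost_ci": f"{_fmt_eur(inc['ci_cost'][0])}; {_fmt_eur(inc['ci_cost'][1])}",
        }
        if kind == "dcdl":
            row.update(
                {
                    "events_IG": f"{arms['IG']['n_events']} ({round_half_up(arms['IG']['pct_events'], nd)}%)",
                    "events_CG": f"{arms['CG']['n_events']} ({round_half_up(arms['CG']['pct_events'], nd)}%)",
                }
            )
        else:
            row.update(
                {
                    "effect_IG_mean": round_half_up(arms["IG"]["effect_mean"], nd),
                    "effect_CG_mean": round_half_up(arms["CG"]["effect_mean"], nd),
                }
            )
        row["incr_effect"] = round_half_up(inc["delta_effect"], nd)
        row["incr_effect_ci"] = (
            f"{round_half_up(inc['ci_effect'][0], nd)}; {round_half_up(inc['ci_effect'][1], nd)}"
        )
        row["ICER"] = _verdict_cell(inc)
        row["population"] = man["label"]
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# bundle I/O
# --------------------------------------------------------------------------


def write_bundle(bundle: dict, out_dir: str | Path, plots: bool = True) -> Path:
    """Persist a results bundle: JSON, bootstrap-cloud CSV, plot files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serialisable = {k: v for k, v in bundle.items() if k not in ("cloud", "pairs")}
    (out / "results.json").write_text(json.dumps(serialisable, indent=2, default=float))
    cloud: BootstrapCloud | None = bundle.get("cloud")
    if cloud is not None:
        pd.DataFrame(
            {"delta_cost": cloud.delta_cost, "delta_effect": cloud.delta_effect}
        ).to_csv(out / "cloud.csv", index=False)
    if "pairs" in bundle:
        bundle["pairs"].to_csv(out / "matched_pairs.csv", index=False)
    if plots and cloud is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .cea_engine import CEAC, plot_ce_plane, plot_ceac

        ax = plot_ce_plane(cloud)
        ax.figure.savefig(out / "ce_plane.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        curve = CEAC(
            wtp=np.asarray(bundle["ceac"]["wtp"]),
            probability=np.asarray(bundle["ceac"]["probability"]),
        )
        label = f"{bundle['manifest']['variant']} ({bundle['manifest']['effect_kind']})"
        ax = plot_ceac({label: curve})
        ax.figure.savefig(out / "ceac.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return out


def read_bundle(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "results.json").read_text())
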