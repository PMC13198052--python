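"""Cost valuation and EQ-5D-5L utility valuation.

Turns raw trial records (intervention delivery, index-stay billing,
quarterly resource-use answers) into the three EUR cost blocks of the
societal-perspective analysis:

1. intervention costs - frailty screening, shared decision-making (SDM)
   conference by attendee composition, and supervised prehabilitation
   sessions priced per setting (with transportation where the setting
   includes it); identically zero in the control arm, where the
   screening conferred no clinical benefit and was not standard care;
2. index hospital stay - the hospital bill plus an investment-cost
   reference per case and expected statutory co-payments (10 EUR/day,
   capped at 28 days, with an assumed 50% exemption share applied as a
   deterministic expected-value multiplier); zero for patients without
   the index surgery;
3. 12-month follow-up resource use - questionnaire counts multiplied by
   standardised unit costs; informal care valued by the substitution
   cost approach (professional-caregiver wage); medication carried in
   the schema but never valued (no standardised unit costs exist).

When a patient died, every cost window on or after the death date is
set to zero.  Utilities are read off a pluggable EQ-5D-5L value set;
a closed-form toy tariff is bundled for self-contained runs, while a
country-specific tariff (e.g. the German set with anchors 1 and
-0.661) can be supplied as a config file.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CATEGORY_ITEMS,
    FOLLOWUP_CATEGORIES,
    RESOURCE_ITEMS,
    SETTINGS,
    VISIT_DAYS,
    VISIT_MONTHS,
    cost_col,
    eq5d_col,
    ru_col,
    util_col,
)

#: Hard utility bounds of the supported value sets (German tariff).
U_MIN, U_MAX = -0.661, 1.0


# --------------------------------------------------------------------------
# unit costs
# --------------------------------------------------------------------------


@dataclass
class UnitCostTable:
    """Societal-perspective unit costs (EUR, price year ~2020).

    ``item_costs`` maps every valued resource-use item to EUR per
    reported unit.  The bundled defaults are illustrative round figures
    in the range of published German standardised unit costs; the exact
    tariffs are a user-supplied config input.
    """

    item_costs: dict[str, float] = field(
        default_factory=lambda: {
            "physician_visits": 45.0,
            "therapist_visits": 35.0,
            "mobile_nursing_hours": 42.0,
            "household_assistance_hours": 25.0,
            "informal_care_hours": 23.5,  # substitution wage
            "neighbour_help_hours": 23.5,  # substitution wage
            "day_care_days": 80.0,
            "short_term_care_days": 110.0,
            "nursing_home_days": 120.0,
            "rehabilitation_days": 160.0,
            "day_clinic_days": 320.0,
            "hospital_days": 780.0,
            "psychiatric_days": 450.0,
            "auxiliary_aids_count": 150.0,
            "housing_adaptation_count": 1500.0,
        }
    )
    screening: float = 26.0
    sdm_base: float = 60.0
    sdm_physician: float = 100.0
    sdm_therapist: float = 46.0
    session_costs: dict[str, float] = field(
        default_factory=lambda: {
            "mobile": 30.0,
            "outpatient": 22.0,
            "outpatient_transport": 49.0,  # session + shared transport
            "part_inpatient": 68.0,
            "inpatient": 320.0,  # includes overnight stay
        }
    )
    investment_per_case: float = 540.0
    copay_rate: float = 10.0
    copay_cap_days: int = 28
    copay_exempt_share: float = 0.5

    def __post_init__(self) -> None:
        valued = {i for i, (cat, _) in RESOURCE_ITEMS.items() if cat is not None}
        missing = valued - set(self.item_costs)
        if missing:
            raise ValueError(f"unit costs missing for items: {sorted(missing)}")
        allvals = list(self.item_costs.values()) + list(self.session_costs.values())
        allvals += [
            self.screening,
            self.sdm_base,
            self.sdm_physician,
            self.sdm_therapist,
            self.investment_per_case,
            self.copay_rate,
        ]
        if any(v < 0 for v in allvals):
            raise ValueError("unit costs must be nonnegative")
        if not 0.0 <= self.copay_exempt_share <= 1.0:
            raise ValueError("copay_exempt_share must be in [0, 1]")
        if set(self.session_costs) != set(SETTINGS):
            raise ValueError("session_costs must cover every setting")

    def scaled(self, k: float) -> "UnitCostTable":
        """Every monetary unit cost multiplied by ``k`` (homogeneity)."""
        return UnitCostTable(
            item_costs={i: k * c for i, c in self.item_costs.items()},
            screening=k * self.screening,
            sdm_base=k * self.sdm_base,
            sdm_physician=k * self.sdm_physician,
            sdm_therapist=k * self.sdm_therapist,
            session_costs={s: k * c for s, c in self.session_costs.items()},
            investment_per_case=k * self.investment_per_case,
            copay_rate=k * self.copay_rate,
            copay_cap_days=self.copay_cap_days,
            copay_exempt_share=self.copay_exempt_share,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def default_unit_costs() -> UnitCostTable:
    return UnitCostTable()


def load_unit_costs(path: str | Path) -> UnitCostTable:
    return UnitCostTable(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# value set
# --------------------------------------------------------------------------


@dataclass
class ValueSet:
    """EQ-5D-5L tariff: 5-digit state -> population-preference utility.

    The file format declares its anchors (utilities of the best state
    11111 and worst state 55555); the loader validates the tabulated
    extremes against them.
    """

    values: dict[str, float]
    anchor_best: float = 1.0
    anchor_worst: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.values) != 3125:
            raise ValueError("value set must cover all 3125 EQ-5D-5L states")
        vmax = max(self.values.values())
        vmin = min(self.values.values())
        if not (np.isclose(self.values["11111"], self.anchor_best) and np.isclose(vmax, self.anchor_best)):
            raise ValueError("best-state utility does not match declared anchor")
        if not (np.isclose(self.values["55555"], self.anchor_worst) and np.isclose(vmin, self.anchor_worst)):
            raise ValueError("worst-state utility does not match declared anchor")

    def utility(self, state: str) -> float:
        return apply_valueset(state, self)


def apply_valueset(eq5d_state: str, valueset: ValueSet) -> float:
    """Tabulated utility of a 5-digit EQ-5D-5L state."""
    s = str(eq5d_state)
    if len(s) != 5 or any(c not in "12345" for c in s):
        raise ValueError(f"malformed EQ-5D-5L state {eq5d_state!r}")
    try:
        return valueset.values[s]
    except KeyError:
        raise ValueError(f"state {s} absent from value set") from None


def toy_valueset() -> ValueSet:
    """Bundled illustrative tariff: mean of 1 - 0.25*(level-1) per dimension.

    Equivalently 1 - 0.05 * sum(level - 1); anchors 1 (11111) and 0 (55555).
    """
    values = {
        "".join(map(str, levels)): 1.0 - 0.05 * (sum(levels) - 5)
        for levels in itertools.product(range(1, 6), repeat=5)
    }
    return ValueSet(values=values, anchor_best=1.0, anchor_worst=0.0, name="toy")


def load_valueset(path: str | Path) -> ValueSet:
    d = json.loads(Path(path).read_text())
    return ValueSet(
        values={str(k): float(v) for k, v in d["values"].items()},
        anchor_best=float(d["anchors"]["best"]),
        anchor_worst=float(d["anchors"]["worst"]),
        name=d.get("name", "custom"),
    )


def write_valueset(vs: ValueSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "name": vs.name,
                "anchors": {"best": vs.anchor_best, "worst": vs.anchor_worst},
                "values": vs.values,
            }
        )
    )


# --------------------------------------------------------------------------
# intervention costs
# --------------------------------------------------------------------------


def value_intervention(records: pd.DataFrame, unit_costs: UnitCostTable) -> pd.Series:
    """Per-patient intervention cost (EUR).

    Control arm: exactly 0.  Intervention arm: frailty screening for
    every patient, SDM conference priced by attendee composition where
    one took place, and supervised sessions priced per setting.  Staff
    and centre training costs are excluded (scale-dependent
    implementation costs, not delivery costs).
    """
    is_ig = (records["arm"] == "IG").to_numpy()
    sessions = records["sessions"].to_numpy(float)
    setting = records["setting"].to_numpy(object)

    bad = is_ig & (np.nan_to_num(sessions) > 0) & pd.isna(setting)
    if bad.any():
        raise ValueError(
            f"{bad.sum()} intervention-arm records have sessions > 0 but no setting"
        )

    cost = np.zeros(len(records))
    cost[is_ig] += unit_costs.screening

    sdm = records["sdm"].to_numpy(bool) & is_ig
    n_phys = np.nan_to_num(records["sdm_physicians"].to_numpy(float))
    n_ther = np.nan_to_num(records["sdm_therapists"].to_numpy(float))
    cost += sdm * (
        unit_costs.sdm_base
        + n_phys * unit_costs.sdm_physician
        + n_ther * unit_costs.sdm_therapist
    )

    per_session = np.array(
        [unit_costs.session_costs.get(s, 0.0) if isinstance(s, str) else 0.0 for s in setting]
    )
    cost += is_ig * np.nan_to_num(sessions) * per_session
    return pd.Series(cost, index=records.index, name="cost_intervention")


# --------------------------------------------------------------------------
# index hospital stay
# --------------------------------------------------------------------------


def value_index_stay(records: pd.DataFrame, unit_costs: UnitCostTable) -> pd.Series:
    """Per-patient index-stay cost (EUR).

    Patients without the index surgery have no index hospitalisation:
    cost 0.  Otherwise bill + investment reference per case + expected
    co-payment ``(1 - exempt_share) * rate * min(days, cap)``.  A
    missing bill despite surgery yields NaN - flagged for imputation,
    not an exception.
    """
    surgery = records["surgery_done"].to_numpy(bool)
    bill = records["index_bill"].to_numpy(float)
    los = records["los_days"].to_numpy(float)
    copay = (
        (1.0 - unit_costs.copay_exempt_share)
        * unit_costs.copay_rate
        * np.minimum(los, unit_costs.copay_cap_days)
    )
    cost = np.where(surgery, bill + unit_costs.investment_per_case + copay, 0.0)
    return pd.Series(cost, index=records.index, name="cost_index")


# --------------------------------------------------------------------------
# follow-up resource use
# --------------------------------------------------------------------------


def value_followup_visit(answers: dict | pd.Series, unit_costs: UnitCostTable) -> dict[str, float]:
    """Value the resource-use answers of one 3-month recall window.

    Returns EUR per follow-up category.  Missing answers propagate as
    NaN for their category; medication is never valued.
    """
    out: dict[str, float] = {}
    for cat in FOLLOWUP_CATEGORIES:
        total = 0.0
        for item in CATEGORY_ITEMS[cat]:
            v = answers.get(item, np.nan)
            v = np.nan if v is None else float(v)
            if not np.isnan(v) and v < 0:
                raise ValueError(f"negative count for {item!r}: {v}")
            total += v * unit_costs.item_costs[item]
        out[cat] = total
    return out


def value_followup_all(records: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Valued follow-up components, one column per category x visit."""
    out = pd.DataFrame(index=records.index)
    for cat in FOLLOWUP_CATEGORIES:
        for t in VISIT_MONTHS:
            total = np.zeros(len(records))
            for item in CATEGORY_ITEMS[cat]:
                v = records[ru_col(item, t)].to_numpy(float)
                if np.nanmin(v, initial=0.0) < 0:
                    raise ValueError(f"negative count in {ru_col(item, t)}")
                total = total + v * unit_costs.item_costs[item]
            out[cost_col(cat, t)] = total
    return out


# --------------------------------------------------------------------------
# death zeroing and assembly
# --------------------------------------------------------------------------


def apply_death_zeroing(profile: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Zero every cost window on/after the patient's death date.

    Follow-up components of visits whose assessment day is on or after
    the death day are set to 0 (overriding death-truncated missing
    values).  The index stay of a patient who died before undergoing
    surgery is already 0 through the no-surgery rule; intervention
    costs (incurred preoperatively) are always retained.
    """
    out = profile.copy()
    death_day = records["death_day"].to_numpy(float)
    for t in VISIT_MONTHS:
        dead = death_day <= VISIT_DAYS[t]  # NaN -> False
        if dead.any():
            for cat in FOLLOWUP_CATEGORIES:
                col = cost_col(cat, t)
                if col in out.columns:
                    out.loc[dead, col] = 0.0
    return out


def value_costs(records: pd.DataFrame, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Full per-patient cost profile: intervention, index, follow-up components.

    Death zeroing is applied; missing (masked) visit windows remain NaN
    for downstream imputation.
    """
    comp = pd.DataFrame(index=records.index)
    comp["cost_intervention"] = value_intervention(records, unit_costs)
    comp["cost_index"] = value_index_stay(records, unit_costs)
    comp = pd.concat([comp, value_followup_all(records, unit_costs)], axis=1)
    return apply_death_zeroing(comp, records)


# --------------------------------------------------------------------------
# utilities
# --------------------------------------------------------------------------


def utilities_from_states(records: pd.DataFrame, valueset: ValueSet) -> pd.DataFrame:
    """Per-patient utilities at baseline and each visit.

    Assessments on/after the death date are 0 regardless of state;
    masked states yield NaN (for imputation).
    """
    lut = valueset.values
    out = pd.DataFrame(index=records.index)

    def _map(states: np.ndarray) -> np.ndarray:
        return np.array(
            [lut[str(s)] if isinstance(s, str) and s in lut else np.nan for s in states]
        )

    out["util_baseline"] = _map(records["eq5d_baseline"].to_numpy(object))
    death_day = records["death_day"].to_numpy(float)
    for t in VISIT_MONTHS:
        u = _map(records[eq5d_col(t)].to_numpy(object))
        dead = death_day <= VISIT_DAYS[t]
        u[dead] = 0.0
        out[util_col(t)] = u
    return out
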