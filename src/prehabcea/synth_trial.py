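"""Synthetic two-arm prehabilitation trial generator.

Emulates the data structure of a multicentre randomised trial of
multimodal prehabilitation versus standard preoperative care in elderly
(pre-)frail elective-surgery patients: baseline covariates, intervention
delivery (shared decision-making conference, supervised sessions by
setting), the index hospital stay, quarterly resource-use questionnaire
answers, quarterly EQ-5D-5L states, 12-month care-dependency level and
WHODAS 2.0 items, deaths, and missing-at-random dropout.

The generator's defaults are the study conditions of the emulated trial:
arm sizes 616/583 after withdrawals, ~37% frail, median age 78, ~90%
undergoing the index surgery, delivery-setting mix dominated by
outpatient prehabilitation with transportation, adherence with median
~29 of 30 supervised sessions, and 12-month mortality of 7.5% (the
survivor counts imply 7-8% per arm).  Arm effects (utility shift,
deterioration-probability shift, follow-up cost shift) are injected
quantities the analysis pipeline should recover.

Health states are produced by thresholding a latent per-patient health
trajectory (a shared patient-level component plus visit-level noise), so
utilities are correlated across visits and with the baseline state -
the structure chained-equation imputation exploits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    RESOURCE_ITEMS,
    SETTINGS,
    VISIT_DAYS,
    VISIT_MONTHS,
    eq5d_col,
    ru_col,
)

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def _default_cost_block_params() -> dict[str, tuple[float, float, float]]:
    """Per-item zero-inflated gamma parameters for one 3-month window.

    item -> (probability of any use, gamma shape, gamma mean given use).
    Chosen so that, under the bundled unit costs, annual category means
    echo the skewed medians-of-zero pattern typical of elderly surgical
    cohorts (hospital stays, informal care and rehabilitation dominate).
    """
    return {
        "physician_visits": (0.85, 2.0, 4.4),
        "therapist_visits": (0.50, 1.2, 10.0),
        "mobile_nursing_hours": (0.12, 0.8, 35.0),
        "household_assistance_hours": (0.18, 1.0, 6.0),
        "informal_care_hours": (0.15, 0.5, 200.0),
        "neighbour_help_hours": (0.10, 0.7, 40.0),
        "day_care_days": (0.01, 1.0, 10.0),
        "short_term_care_days": (0.01, 1.0, 8.0),
        "nursing_home_days": (0.015, 1.0, 25.0),
        "medication_uses": (0.70, 1.5, 3.0),
        "rehabilitation_days": (0.30, 1.5, 8.8),
        "day_clinic_days": (0.05, 1.0, 2.2),
        "hospital_days": (0.22, 1.2, 8.0),
        "psychiatric_days": (0.002, 1.0, 12.0),
        "auxiliary_aids_count": (0.35, 1.2, 1.1),
        "housing_adaptation_count": (0.01, 1.0, 1.0),
    }


def _default_setting_mix() -> dict[str, float]:
    # Delivered-setting shares among patients with >=1 session
    # (4 / 69 / 343 / 23 / 80 of 519 in the emulated trial).
    return {
        "mobile": 0.008,
        "outpatient": 0.133,
        "outpatient_transport": 0.661,
        "part_inpatient": 0.044,
        "inpatient": 0.154,
    }


def _default_adherence_pmf() -> np.ndarray:
    """Distribution of supervised session counts 0-30.

    ~16% never start, ~3% stop before 15 sessions, and 81% reach the
    per-protocol threshold of 15 sessions with a count of
    ``30 - floor(Exponential(scale=2.2))`` (median ~29, Q1 ~26).
    """
    pmf = np.zeros(31)
    pmf[0] = 0.157
    pmf[1:15] = 0.033 / 14.0
    scale = 2.2
    j = np.arange(16)
    tail = np.exp(-j / scale) - np.exp(-(j + 1) / scale)
    tail[-1] += np.exp(-16 / scale)  # lump the remaining mass
    for jj, p in enumerate(tail):
        pmf[30 - jj] += 0.81 * p
    return pmf / pmf.sum()


@dataclass
class SimConfig:
    """Design quantities of the synthetic trial.

    ``n_per_arm`` may be a single count (equal arms) or a pair
    ``(n_ig, n_cg)``.  Effects use the reporting conventions of the
    analysis: ``effect_utility`` shifts the mean EQ-5D-5L utility of the
    intervention group upward (IG - CG, utility units);
    ``effect_dcdl`` is the reduction in the overall 12-month
    care-dependency deterioration probability (CG - IG, includes the
    death-counts-as-deterioration rule); ``effect_cost_followup`` is the
    mean 12-month follow-up cost saving of the intervention group
    (CG - IG, EUR under the bundled unit costs), injected through the
    hospital-days item.
    """

    n_per_arm: int | tuple[int, int] = (616, 583)
    seed: int = 0
    effect_utility: float = 0.03
    effect_dcdl: float = 0.044
    effect_cost_followup: float = 900.0
    mortality_12m: float = 0.075
    missing_visit_prob: float = 0.25
    missing_3m_extra: float = 0.50
    cost_block_params: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_cost_block_params
    )
    setting_mix: dict[str, float] = field(default_factory=_default_setting_mix)
    adherence_pmf: np.ndarray = field(default_factory=_default_adherence_pmf)
    surgery_prob: float = 0.89
    sdm_prob: float = 0.90
    #: deterioration probability among control-group survivors
    base_deterioration_prob: float = 0.148
    #: EUR per hospital day under the bundled unit-cost table; converts
    #: the configured follow-up cost effect into a quantity shift.
    followup_effect_unit_cost_ref: float = 780.0

    def __post_init__(self) -> None:
        n_ig, n_cg = self.arm_sizes()
        if n_ig < 2 or n_cg < 2:
            raise ValueError("n_per_arm must be >= 2 in each arm")
        for name in (
            "mortality_12m",
            "missing_visit_prob",
            "missing_3m_extra",
            "surgery_prob",
            "sdm_prob",
            "base_deterioration_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        mix = np.array([self.setting_mix.get(s, 0.0) for s in SETTINGS], float)
        if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("setting_mix must be nonnegative and sum to 1")
        pmf = np.asarray(self.adherence_pmf, float)
        if pmf.shape != (31,) or (pmf < 0).any() or not np.isclose(pmf.sum(), 1.0):
            raise ValueError("adherence_pmf must be a length-31 probability vector")
        for item, (p_nz, shape, mean) in self.cost_block_params.items():
            if item not in RESOURCE_ITEMS:
                raise ValueError(f"unknown resource item {item!r}")
            if not 0.0 <= p_nz <= 1.0 or shape <= 0 or mean < 0:
                raise ValueError(f"bad cost_block_params for {item!r}")

    def arm_sizes(self) -> tuple[int, int]:
        if isinstance(self.n_per_arm, (tuple, list)):
            n_ig, n_cg = self.n_per_arm
        else:
            n_ig = n_cg = self.n_per_arm
        return int(n_ig), int(n_cg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adherence_pmf"] = list(np.asarray(self.adherence_pmf, float))
        if isinstance(d["n_per_arm"], tuple):
            d["n_per_arm"] = list(d["n_per_arm"])
        d["cost_block_params"] = {k: list(v) for k, v in d["cost_block_params"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "n_per_arm" in d and isinstance(d["n_per_arm"], list):
            d["n_per_arm"] = tuple(d["n_per_arm"])
        if "adherence_pmf" in d:
            d["adherence_pmf"] = np.asarray(d["adherence_pmf"], float)
        if "cost_block_params" in d:
            d["cost_block_params"] = {
                k: tuple(v) for k, v in d["cost_block_params"].items()
            }
        return cls(**d)


# --------------------------------------------------------------------------
# latent health states
# --------------------------------------------------------------------------

# Severity scale X in [0, 1]: toy-tariff utility is exactly 1 - X, so a
# mean shift on X maps one-to-one onto a mean utility shift.
_MU_SEVERITY = 0.30  # control-arm mean severity -> mean utility 0.70
_KAPPA = 4.0  # beta concentration of both latent components
_W_PATIENT = 0.6  # weight of the shared patient-level component


def _beta(rng: np.random.Generator, mu: float, n: int) -> np.ndarray:
    return rng.beta(mu * _KAPPA, (1.0 - mu) * _KAPPA, n)


def _states_from_severity(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map severities in [0, 1] to EQ-5D-5L state strings.

    The total excess level count S = sum(level - 1) over the five
    dimensions is the randomised rounding of 20x, so the toy-tariff
    utility 1 - 0.05 S is unbiased for 1 - x.  Excess levels are spread
    over a random subset of dimensions.
    """
    n = len(x)
    s_cont = 20.0 * np.clip(x, 0.0, 1.0)
    s = np.floor(s_cont).astype(int)
    s += (rng.random(n) < (s_cont - s)).astype(int)
    s = np.clip(s, 0, 20)
    base, rem = np.divmod(s, 5)
    order = rng.random((n, 5)).argsort(axis=1)
    levels = 1 + base[:, None] + (order < rem[:, None])
    digits = levels.astype("U1")
    return np.array(["".join(row) for row in digits])


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate_trial(config: SimConfig) -> pd.DataFrame:
    """Generate a complete (pre-dropout) synthetic trial table.

    One row per patient, visit fields wide.  Deterministic given the
    config (including its seed).  Baseline covariates are drawn
    independently of arm (randomisation); the configured arm effects are
    injected into utilities, the deterioration probability, and
    follow-up hospital days.  Deaths occur with ``mortality_12m`` at a
    uniform day within the 12-month window and truncate every later
    visit field (left as missing sentinels, never sampled values).
    """
    rng = np.random.default_rng(config.seed)
    n_ig, n_cg = config.arm_sizes()
    n = n_ig + n_cg
    is_ig = np.zeros(n, bool)
    is_ig[:n_ig] = True

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["id"] = [f"P{i:05d}" for i in range(n)]
    df["arm"] = np.where(is_ig, "IG", "CG")

    # ---- baseline covariates (arm-independent) ----
    df["age"] = np.minimum(np.round(70.0 + rng.gamma(2.2, 4.0, n)), 99).astype(int)
    df["sex"] = np.where(rng.random(n) < 0.545, "F", "M")
    df["bmi"] = np.round(np.clip(rng.normal(27.1, 4.9, n), 15, 55), 1)
    df["cci"] = np.clip(np.round(rng.normal(5.0, 1.6, n)), 0, 16).astype(int)
    df["frailty"] = np.where(rng.random(n) < 0.37, "frail", "pre-frail")
    df["care_level_baseline"] = rng.choice(
        6, n, p=[0.742, 0.154, 0.067, 0.0325, 0.0035, 0.001]
    )
    df["moca"] = np.clip(np.round(rng.normal(24.0, 3.4, n)), 0, 30).astype(int)
    df["specialty"] = rng.choice(
        ["orthopaedic", "cardiac", "tumour", "other"], n, p=[0.53, 0.09, 0.07, 0.31]
    )

    # latent severity: shared patient component + baseline visit noise
    pat = _beta(rng, _MU_SEVERITY, n)
    x0 = _W_PATIENT * pat + (1 - _W_PATIENT) * _beta(rng, _MU_SEVERITY, n)
    df["eq5d_baseline"] = _states_from_severity(x0, rng)
    q_b = np.clip(0.8 * x0 + 0.04 + rng.normal(0, 0.06, n), 0.01, 0.99)
    df["whodas_baseline"] = 12 + rng.binomial(48, q_b)

    # ---- intervention delivery (IG only) ----
    sessions = np.where(is_ig, rng.choice(31, n, p=config.adherence_pmf), 0).astype(
        float
    )
    sessions[~is_ig] = np.nan
    setting = np.array(
        rng.choice(SETTINGS, n, p=[config.setting_mix.get(s, 0.0) for s in SETTINGS]),
        object,
    )
    setting[~is_ig | (np.nan_to_num(sessions) == 0)] = None
    sdm = is_ig & (rng.random(n) < config.sdm_prob)
    sdm_phys = np.where(sdm, 1 + rng.binomial(2, 0.4, n), np.nan)
    sdm_family = np.where(sdm, rng.random(n) < 0.4, False)
    df["sessions"] = sessions
    df["setting"] = setting
    df["sdm"] = sdm
    df["sdm_physicians"] = sdm_phys
    df["sdm_therapists"] = np.where(sdm, 1.0, np.nan)
    df["sdm_family"] = sdm_family.astype(bool)

    # ---- index surgery and hospital stay ----
    surgery = rng.random(n) < config.surgery_prob
    bill = rng.gamma(1.55, 11200.0 / 1.55, n)
    los = np.maximum(np.round(rng.gamma(2.0, 5.75, n)), 1)
    df["surgery_done"] = surgery
    df["index_bill"] = np.where(surgery, np.round(bill, 2), np.nan)
    df["los_days"] = np.where(surgery, los, np.nan)

    # ---- mortality ----
    died = rng.random(n) < config.mortality_12m
    death_day = np.where(died, rng.integers(1, 366, n), np.nan)
    df["death_day"] = death_day

    # ---- follow-up visits ----
    eff_u = np.where(is_ig, config.effect_utility, 0.0)
    # quantity shift on IG hospital days implementing the follow-up cost
    # saving: EUR effect / (4 windows * P(use) * EUR per day)
    p_nz_hosp = config.cost_block_params["hospital_days"][0]
    if config.effect_cost_followup != 0.0 and p_nz_hosp <= 0:
        raise ValueError(
            "effect_cost_followup requires a positive hospital-days use probability"
        )
    day_shift = (
        config.effect_cost_followup
        / (4.0 * p_nz_hosp * config.followup_effect_unit_cost_ref)
        if config.effect_cost_followup != 0.0
        else 0.0
    )

    x12 = np.full(n, np.nan)
    visit_cols: dict[str, np.ndarray] = {}
    for t in VISIT_MONTHS:
        alive = ~died | (death_day > VISIT_DAYS[t])
        x_t = np.clip(
            _W_PATIENT * pat + (1 - _W_PATIENT) * _beta(rng, _MU_SEVERITY, n) - eff_u,
            0.0,
            1.0,
        )
        states = _states_from_severity(x_t, rng)
        visit_cols[eq5d_col(t)] = np.where(alive, states, None)
        if t == 12:
            x12 = np.where(alive, x_t, np.nan)
        for item, (p_nz, shape, mean) in config.cost_block_params.items():
            mean_row = np.full(n, mean)
            if item == "hospital_days":
                mean_row = np.maximum(mean_row - day_shift * is_ig, 0.01)
            q = rng.gamma(shape, mean_row / shape) * (rng.random(n) < p_nz)
            if RESOURCE_ITEMS[item][1]:
                q = np.round(q)
            else:
                q = np.round(q, 1)
            visit_cols[ru_col(item, t)] = np.where(alive, q, np.nan)

    # ---- 12-month care dependency ----
    alive_12 = ~died
    base_logit = np.log(
        config.base_deterioration_prob / (1 - config.base_deterioration_prob)
    )
    lin = (
        base_logit
        + 0.35 * (df["frailty"] == "frail").to_numpy()
        + 0.03 * (df["age"].to_numpy() - 78)
    )
    p_det = 1.0 / (1.0 + np.exp(-lin))
    if config.mortality_12m < 1.0:
        p_det = p_det - is_ig * config.effect_dcdl / (1.0 - config.mortality_12m)
    p_det = np.clip(p_det, 0.0, 1.0)
    det = rng.random(n) < p_det
    lvl_b = df["care_level_baseline"].to_numpy()
    jump = 1 + (rng.random(n) < 0.15)
    lvl12 = np.where(det, np.minimum(lvl_b + jump, 5), lvl_b)
    improve = ~det & (lvl_b >= 1) & (rng.random(n) < 0.15)
    lvl12 = np.where(improve, lvl_b - 1, lvl12)
    # a baseline-5 patient cannot worsen further while alive
    lvl12 = np.minimum(lvl12, 5)
    visit_cols["care_level_12m"] = np.where(alive_12, lvl12, np.nan)

    # ---- 12-month WHODAS items ----
    q12 = np.clip(
        0.75 * (0.5 * (df["whodas_baseline"].to_numpy() - 12) / 48.0 + 0.5 * np.nan_to_num(x12))
        + 0.03
        + rng.normal(0, 0.08, n),
        0.01,
        0.99,
    )
    items = 1 + rng.binomial(4, q12[:, None], (n, 12))
    for j in range(12):
        visit_cols[f"whodas_item{j + 1}_12m"] = np.where(alive_12, items[:, j], np.nan)

    return pd.concat([df, pd.DataFrame(visit_cols, index=df.index)], axis=1)


# --------------------------------------------------------------------------
# missingness
# --------------------------------------------------------------------------


def apply_missingness(records: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Mask visit fields under a missing-at-random mechanism.

    The per-visit masking probability is logistic in age and baseline
    WHODAS (observed covariates only, never the masked value itself),
    centred so the marginal rate is approximately
    ``missing_visit_prob``.  A masked visit loses its EQ-5D state and
    all resource-use answers; a masked 12-month visit additionally loses
    the care-dependency level and WHODAS items.  The 3-month EQ-5D state
    is masked with the extra probability ``missing_3m_extra``
    independently of covariates.  Fields already truncated by death are
    left untouched.
    """
    df = records.copy()
    rng = np.random.default_rng([int(config.seed) % (2**31), 104729])
    n = len(df)
    death_day = df["death_day"].to_numpy(float)

    base = config.missing_visit_prob
    if base <= 0.0:
        p_visit = np.zeros(n)
    elif base >= 1.0:
        p_visit = np.ones(n)
    else:
        z_age = (df["age"].to_numpy(float) - 78.0) / 6.0
        z_who = (df["whodas_baseline"].to_numpy(float) - 25.0) / 8.0
        lin = np.log(base / (1 - base)) + 0.35 * z_age + 0.35 * z_who
        p_visit = 1.0 / (1.0 + np.exp(-lin))

    for t in VISIT_MONTHS:
        alive = ~(death_day <= VISIT_DAYS[t])  # NaN compares False -> alive
        mask = (rng.random(n) < p_visit) & alive
        cols = [eq5d_col(t)] + [ru_col(i, t) for i in RESOURCE_ITEMS]
        if t == 12:
            cols += ["care_level_12m"] + [f"whodas_item{j + 1}_12m" for j in range(12)]
        for c in cols:
            if df[c].dtype == object:
                df.loc[mask, c] = None
            else:
                df.loc[mask, c] = np.nan

    if config.missing_3m_extra > 0.0:
        alive3 = ~(death_day <= VISIT_DAYS[3])
        extra = (rng.random(n) < config.missing_3m_extra) & alive3
        df.loc[extra, eq5d_col(3)] = None

    return df


def simulate_trial(config: SimConfig) -> pd.DataFrame:
    """Generate a trial and apply the configured dropout in one step."""
    return apply_missingness(generate_trial(config), config)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def write_records(records: pd.DataFrame, out_dir: str | Path, config: SimConfig | None = None) -> Path:
    """Write the canonical patient-record CSV (plus a config sidecar)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "records.csv"
    records.to_csv(path, index=False)
    if config is not None:
        (out / "simconfig.json").write_text(json.dumps(config.to_dict(), indent=2))
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a patient-record CSV written by :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={"eq5d_baseline": "string"} | {eq5d_col(t): "string" for t in VISIT_MONTHS},
    )
    for col in ("eq5d_baseline", *(eq5d_col(t) for t in VISIT_MONTHS)):
        df[col] = df[col].astype(object).where(df[col].notna(), None)
    df["sdm"] = df["sdm"].astype(bool)
    df["sdm_family"] = df["sdm_family"].astype(bool)
    df["surgery_done"] = df["surgery_done"].astype(bool)
    df["setting"] = df["setting"].astype(object).where(df["setting"].notna(), None)
    return df
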