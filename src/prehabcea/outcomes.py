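"""Per-patient effect measures.

Three effect measures are constructed for every participant:

* QALY - the arithmetic mean of the four quarterly EQ-5D-5L utilities
  over the postoperative year (so a value of 1 is one year of full
  quality of life).  Utilities at assessment points on/after the death
  date are 0; there is no partial-quarter proration because the measure
  averages four discrete assessments, not an area under a curve.
* DCDL - deterioration in care-dependency level: the indicator that the
  care grade (0-5) at 12 months exceeds its baseline value.  A death
  sets the 12-month level to 5 and automatically counts as a
  deterioration regardless of the baseline level (including a baseline
  level of 5, a deliberate consequence of the worst-score-at-death
  rule that is logged when it occurs).
* WHODAS 2.0 at 12 months - 12-item simple scoring, the plain sum of
  item scores 1-5, ranging 12 (best) to 60 (worst); death scores 60.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .schema import VISIT_DAYS, VISIT_MONTHS, util_col
from .valuation import U_MAX, U_MIN

logger = logging.getLogger(__name__)

DETERIORATED = 1.0
NOT_DETERIORATED = 0.0


def compute_qaly(utilities, death_day=None) -> float:
    """Mean of the four quarterly utilities with the death rule applied.

    ``utilities`` holds the 3/6/9/12-month slots (NaN = missing).
    Slots at assessments on/after ``death_day`` are set to 0.  If any
    non-death slot is missing the QALY is missing (NaN) - resolved
    upstream by imputation.
    """
    u = np.asarray(utilities, float).copy()
    if u.shape != (len(VISIT_MONTHS),):
        raise ValueError(f"expected {len(VISIT_MONTHS)} utility slots, got {u.shape}")
    obs = ~np.isnan(u)
    if ((u[obs] < U_MIN - 1e-9) | (u[obs] > U_MAX + 1e-9)).any():
        raise ValueError(f"utility outside [{U_MIN}, {U_MAX}]: {u}")
    if death_day is not None and not np.isnan(death_day):
        for k, t in enumerate(VISIT_MONTHS):
            if death_day <= VISIT_DAYS[t]:
                u[k] = 0.0
    if np.isnan(u).any():
        return float("nan")
    return float(u.mean())


def compute_dcdl(level_baseline, level_12m, died: bool) -> float:
    """Deterioration indicator (1 deteriorated / 0 not / NaN missing)."""
    lb = float(level_baseline)
    if np.isnan(lb) or not 0 <= lb <= 5:
        raise ValueError(f"baseline care level outside 0-5: {level_baseline}")
    if died:
        if lb == 5:
            logger.info(
                "patient with baseline care level 5 died: counted as deterioration "
                "per the worst-score-at-death rule despite no strict increase"
            )
        return DETERIORATED
    l12 = float(level_12m) if level_12m is not None else float("nan")
    if np.isnan(l12):
        return float("nan")
    if not 0 <= l12 <= 5:
        raise ValueError(f"12-month care level outside 0-5: {level_12m}")
    return DETERIORATED if l12 > lb else NOT_DETERIORATED


def compute_whodas(items, died: bool) -> float:
    """12-item simple-scoring WHODAS 2.0 total (12-60; death -> 60)."""
    if died:
        return 60.0
    v = np.asarray(items, float)
    if v.shape != (12,):
        raise ValueError(f"expected 12 WHODAS items, got shape {v.shape}")
    if np.isnan(v).any():
        return float("nan")
    if ((v < 1) | (v > 5)).any():
        raise ValueError(f"WHODAS item outside 1-5: {v}")
    return float(v.sum())


def build_effect_panel(analysis: pd.DataFrame) -> pd.DataFrame:
    """Vectorised effect panel from an analysis-ready table.

    Expects the utility columns (death rule already applied at
    valuation), ``care_level_baseline``, ``care_level_12m``,
    ``whodas_12m`` and ``death_day``.  Death-rule values (care level 5,
    WHODAS 60) are enforced here as well, so the panel is correct
    whether or not the inputs were pre-filled.
    """
    died = analysis["death_day"].notna().to_numpy()
    utils = analysis[[util_col(t) for t in VISIT_MONTHS]].to_numpy(float)
    qaly = np.where(np.isnan(utils).any(axis=1), np.nan, utils.mean(axis=1))

    lb = analysis["care_level_baseline"].to_numpy(float)
    l12 = analysis["care_level_12m"].to_numpy(float)
    dcdl = np.where(died, DETERIORATED, np.where(np.isnan(l12), np.nan, (l12 > lb).astype(float)))

    who = analysis["whodas_12m"].to_numpy(float)
    whodas = np.where(died, 60.0, who)

    return pd.DataFrame(
        {"qaly": qaly, "dcdl": dcdl, "whodas": whodas}, index=analysis.index
    )
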