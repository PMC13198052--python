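"""Winsorisation of skewed cost blocks and totals assembly.

Healthcare cost data are heavily right-skewed; to limit the influence
of extreme outliers on arm means, every cost block except the
intervention block is winsorised at its pooled (both arms together)
97.5th empirical percentile: values above the threshold are replaced by
the threshold, everything at or below is untouched.  The quantile uses
the linear-interpolation convention between order statistics
(numpy's default), documented here because software conventions differ.

Winsorisation happens before imputation-model fitting, so imputation
operates on winsorised observables; the raw components are retained for
the no-winsorisation sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import followup_cost_columns


@dataclass
class WinsorSpec:
    """Winsorisation settings.

    ``blocks`` lists the component columns subject to capping; the
    default covers the index stay and every follow-up category x visit
    component.  Intervention costs are never winsorised.  Thresholds
    are always computed pooled across both arms.
    """

    percentile: float = 0.975
    blocks: list[str] = field(default_factory=lambda: ["cost_index"] + followup_cost_columns())
    pooling: str = "pooled-across-arms"

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 1.0:
            raise ValueError(f"percentile must be in (0, 1), got {self.percentile}")
        if self.pooling != "pooled-across-arms":
            raise ValueError("only pooled-across-arms thresholds are supported")
        if any(b == "cost_intervention" for b in self.blocks):
            raise ValueError("intervention costs are never winsorised")


def winsorise_block(values, spec: WinsorSpec | float = 0.975) -> np.ndarray:
    """Cap one cost block at its empirical percentile.

    Missing entries are ignored when computing the threshold and pass
    through untouched.  Values at or below the threshold are unchanged.
    """
    p = spec.percentile if isinstance(spec, WinsorSpec) else float(spec)
    v = np.asarray(values, float).copy()
    obs = v[~np.isnan(v)]
    if obs.size == 0:
        raise ValueError("cannot winsorise an empty (all-missing) block")
    thr = np.quantile(obs, p, method="linear")
    v[v > thr] = thr
    return v


def winsorise_costs(profiles: pd.DataFrame, spec: WinsorSpec | None = None) -> pd.DataFrame:
    """Winsorise every configured block of a cost-profile table."""
    spec = spec or WinsorSpec()
    out = profiles.copy()
    for col in spec.blocks:
        if col in out.columns:
            out[col] = winsorise_block(out[col].to_numpy(float), spec)
    return out


def assemble_totals(profiles: pd.DataFrame, winsorised: bool = True, spec: WinsorSpec | None = None) -> pd.Series:
    """Per-patient total = intervention + index + sum of follow-up components.

    ``winsorised=True`` caps the subject blocks first; ``False``
    reproduces the raw sums exactly (the costs sensitivity analysis).
    NaN components propagate to the total (resolved by imputation).
    """
    df = winsorise_costs(profiles, spec) if winsorised else profiles
    cols = ["cost_intervention", "cost_index"] + [
        c for c in followup_cost_columns() if c in df.columns
    ]
    return df[cols].sum(axis=1, skipna=False).rename("cost_total")
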