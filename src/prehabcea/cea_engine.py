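"""Incremental cost-effectiveness inference.

Point estimates (mean differences), ICER / dominance classification,
non-parametric bootstrap clouds, cost-effectiveness planes with
confidence ellipses, and cost-effectiveness acceptability curves
(CEAC).

Conventions
-----------
* Incremental cost is always mean(IG) - mean(CG).
* Incremental effect is oriented so that positive = intervention
  better: QALY as IG - CG; deterioration of care-dependency level
  (DCDL) and WHODAS 2.0 are *inverted* (CG - IG) because lower values
  are preferable; DCDL is expressed in percentage points (the absolute
  risk reduction).
* Dominance: the intervention dominates when more effective and less
  costly; is dominated when less effective and more costly; otherwise
  an ICER = incremental cost / incremental effect is computed from the
  raw (unrounded) values.  A south-west result (less effective, less
  costly) reports the ratio with an explicit quadrant label.  An
  incremental effect of exactly 0 yields an undefined-ICER verdict
  (reported, never raised).
* Bootstrap: patients resampled with replacement within arm (arm sizes
  preserved), the full incremental statistic recomputed per replicate.
  Confidence intervals are percentile intervals whose endpoints are
  order statistics of the cloud (inverted-CDF quantile convention).
* CEAC: P(lambda * dE - dC > 0) over replicates - the net-monetary-
  benefit rule with strict inequality; DCDL effects are converted from
  percentage points to proportions first, so lambda is EUR per whole
  prevented deterioration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

EFFECT_KINDS = ("qaly", "dcdl", "whodas")

VERDICT_ICER = "icer"
VERDICT_INTERVENTION_DOMINATES = "intervention_dominates"
VERDICT_CONTROL_DOMINATES = "control_dominates"
VERDICT_UNDEFINED = "undefined_icer"


def delta_effect(effects_ig, effects_cg, effect_kind: str) -> float:
    """Incremental effect under the positive-is-better orientation."""
    if effect_kind not in EFFECT_KINDS:
        raise ValueError(f"effect_kind must be one of {EFFECT_KINDS}")
    mi = float(np.mean(effects_ig))
    mc = float(np.mean(effects_cg))
    if effect_kind == "qaly":
        return mi - mc
    if effect_kind == "dcdl":
        return (mc - mi) * 100.0  # percentage points prevented
    return mc - mi  # whodas points gained


@dataclass
class IncrementalResult:
    """Incremental costs/effects with verdict; CIs attach after bootstrap."""

    delta_cost: float
    delta_effect: float
    effect_kind: str
    verdict: str
    icer: float | None
    quadrant: str
    ci_cost: tuple[float, float] | None = None
    ci_effect: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "effect_kind": self.effect_kind,
            "verdict": self.verdict,
            "icer": self.icer,
            "quadrant": self.quadrant,
            "ci_cost": list(self.ci_cost) if self.ci_cost else None,
            "ci_effect": list(self.ci_effect) if self.ci_effect else None,
        }


def _classify(dc: float, de_units: float, de_reported: float, effect_kind: str) -> IncrementalResult:
    """Verdict from the signs of the incremental pair.

    ``de_units`` is the effect on its natural (ratio) scale - for DCDL
    a proportion, so the ICER is EUR per whole prevented case.
    """
    if de_units == 0.0:
        verdict, icer, quadrant = VERDICT_UNDEFINED, None, "boundary"
    elif de_units > 0 and dc >= 0:
        verdict, icer, quadrant = VERDICT_ICER, dc / de_units, "NE"
    elif de_units > 0 and dc < 0:
        verdict, icer, quadrant = VERDICT_INTERVENTION_DOMINATES, None, "SE"
    elif de_units < 0 and dc >= 0:
        verdict, icer, quadrant = VERDICT_CONTROL_DOMINATES, None, "NW"
    else:  # both negative: less effective, less costly
        verdict, icer, quadrant = VERDICT_ICER, dc / de_units, "SW"
    return IncrementalResult(
        delta_cost=dc,
        delta_effect=de_reported,
        effect_kind=effect_kind,
        verdict=verdict,
        icer=icer,
        quadrant=quadrant,
    )


def incremental(costs_ig, costs_cg, effects_ig, effects_cg, effect_kind: str) -> IncrementalResult:
    """Point incremental result from per-patient costs and effects."""
    ci = np.asarray(costs_ig, float)
    cc = np.asarray(costs_cg, float)
    if ci.size == 0 or cc.size == 0:
        raise ValueError("both arms must be nonempty")
    dc = float(ci.mean() - cc.mean())
    de = delta_effect(effects_ig, effects_cg, effect_kind)
    de_units = de / 100.0 if effect_kind == "dcdl" else de
    return _classify(dc, de_units, de, effect_kind)


@dataclass
class BootstrapCloud:
    """Paired (delta cost, delta effect) bootstrap replicates."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray  # reported scale (pp for dcdl)
    effect_kind: str
    seed: int
    point: IncrementalResult | None = None

    @property
    def B(self) -> int:
        return len(self.delta_cost)

    def effect_units(self) -> np.ndarray:
        """Effects on the natural ratio scale (proportion for dcdl)."""
        if self.effect_kind == "dcdl":
            return self.delta_effect / 100.0
        return self.delta_effect


def bootstrap_cloud(
    costs_ig,
    costs_cg,
    effects_ig,
    effects_cg,
    effect_kind: str,
    B: int = 10_000,
    seed: int = 0,
) -> BootstrapCloud:
    """Within-arm bootstrap of the incremental pair.

    Per replicate, patients are resampled with replacement within each
    arm (preserving the two-sample design and arm sizes) and the
    incremental statistic recomputed; cost and effect come from the
    same resampled patients, so their correlation is preserved.
    Deterministic given the seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    ci = np.asarray(costs_ig, float)
    cc = np.asarray(costs_cg, float)
    ei = np.asarray(effects_ig, float)
    ec = np.asarray(effects_cg, float)
    if np.isnan(ci).any() or np.isnan(cc).any() or np.isnan(ei).any() or np.isnan(ec).any():
        raise ValueError("bootstrap requires a complete analysis-ready dataset")

    rng = np.random.default_rng(seed)
    idx_i = rng.integers(0, len(ci), size=(B, len(ci)))
    idx_c = rng.integers(0, len(cc), size=(B, len(cc)))
    mean_ci = ci[idx_i].mean(axis=1)
    mean_cc = cc[idx_c].mean(axis=1)
    mean_ei = ei[idx_i].mean(axis=1)
    mean_ec = ec[idx_c].mean(axis=1)

    dc = mean_ci - mean_cc
    if effect_kind == "qaly":
        de = mean_ei - mean_ec
    elif effect_kind == "dcdl":
        de = (mean_ec - mean_ei) * 100.0
    elif effect_kind == "whodas":
        de = mean_ec - mean_ei
    else:
        raise ValueError(f"effect_kind must be one of {EFFECT_KINDS}")

    point = incremental(ci, cc, ei, ec, effect_kind)
    return BootstrapCloud(
        delta_cost=dc, delta_effect=de, effect_kind=effect_kind, seed=seed, point=point
    )


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval whose endpoints are order statistics (type-1 quantiles)."""
    v = np.asarray(values, float)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [a, 1.0 - a], method="inverted_cdf")
    return float(lo), float(hi)


def attach_cis(cloud: BootstrapCloud, level: float = 0.95) -> IncrementalResult:
    """Point result with bootstrap percentile CIs for cost and effect."""
    res = cloud.point
    if res is None:
        raise ValueError("cloud has no point estimate attached")
    res.ci_cost = percentile_ci(cloud.delta_cost, level)
    res.ci_effect = percentile_ci(cloud.delta_effect, level)
    return res


# --------------------------------------------------------------------------
# CEAC
# --------------------------------------------------------------------------


@dataclass
class CEAC:
    """Probability of cost-effectiveness over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp_value: float) -> float:
        i = int(np.argmin(np.abs(self.wtp - wtp_value)))
        return float(self.probability[i])


def default_wtp_grid() -> np.ndarray:
    """0 to 100,000 EUR in 500-EUR steps."""
    return np.linspace(0.0, 100_000.0, 201)


def ceac(cloud: BootstrapCloud, wtp_grid=None) -> CEAC:
    """Net-monetary-benefit acceptability: P(lambda * dE - dC > 0)."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if (grid < 0).any():
        raise ValueError("willingness-to-pay thresholds must be nonnegative")
    if cloud.B == 0:
        raise ValueError("empty bootstrap cloud")
    de = cloud.effect_units()
    nmb = grid[:, None] * de[None, :] - cloud.delta_cost[None, :]
    return CEAC(wtp=grid, probability=(nmb > 0).mean(axis=1))


def ceac_threshold_rule(cloud: BootstrapCloud, wtp_grid=None) -> CEAC:
    """Alternative quadrant/ICER-threshold acceptability rule.

    A replicate counts as cost-effective at lambda when it lies in the
    dominant quadrant, or in the NE quadrant with ICER <= lambda, or in
    the SW quadrant with ratio >= lambda.  Provided for comparison with
    the default NMB rule; the two agree except on the treatment of the
    boundary dE = 0.
    """
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    de = cloud.effect_units()
    dc = cloud.delta_cost
    probs = np.empty(len(grid))
    for i, lam in enumerate(grid):
        dominant = (de > 0) & (dc <= 0)
        ne_ok = (de > 0) & (dc > 0) & (dc / de <= lam)
        sw_ok = (de < 0) & (dc < 0) & (dc / de >= lam)
        probs[i] = (dominant | ne_ok | sw_ok).mean()
    return CEAC(wtp=grid, probability=probs)


# --------------------------------------------------------------------------
# cost-effectiveness plane
# --------------------------------------------------------------------------


@dataclass
class PlaneSummary:
    """Bootstrap cloud geometry on the cost-effectiveness plane.

    Ellipse: bivariate-normal contour from the cloud mean/covariance at
    the chi-square(2) quantile of the confidence level.  Quadrant
    shares use the reported effect scale; the axis-crossing flags state
    whether the ellipse extends across dE = 0 / dC = 0.
    """

    mean: np.ndarray  # (dE, dC)
    cov: np.ndarray  # 2x2, rows/cols (dE, dC)
    confidence: float
    chi2_q: float
    axis_half_widths: np.ndarray  # ellipse extent along (dE, dC)
    crosses_effect_axis: bool
    crosses_cost_axis: bool
    quadrant_shares: dict[str, float]
    degenerate: bool

    def ellipse_params(self) -> tuple[np.ndarray, float, float, float]:
        """(centre, width, height, angle_deg) for drawing."""
        evals, evecs = np.linalg.eigh(self.cov)
        width, height = 2.0 * np.sqrt(self.chi2_q * np.maximum(evals, 0.0))
        angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
        return self.mean, float(width), float(height), angle


def ce_plane(cloud: BootstrapCloud, confidence: float = 0.95) -> PlaneSummary:
    """Summarise the cloud and its confidence ellipse."""
    if cloud.B < 3:
        raise ValueError("need at least 3 replicates for a plane summary")
    de = cloud.delta_effect
    dc = cloud.delta_cost
    xy = np.column_stack([de, dc])
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    degenerate = bool(np.linalg.det(cov) <= 1e-300)
    q = float(stats.chi2.ppf(confidence, df=2))
    half = np.sqrt(q * np.diag(cov))
    shares = {
        "NE": float(((de > 0) & (dc > 0)).mean()),
        "SE": float(((de > 0) & (dc <= 0)).mean()),
        "NW": float(((de <= 0) & (dc > 0)).mean()),
        "SW": float(((de <= 0) & (dc <= 0)).mean()),
    }
    return PlaneSummary(
        mean=mean,
        cov=cov,
        confidence=confidence,
        chi2_q=q,
        axis_half_widths=half,
        crosses_effect_axis=bool(abs(mean[0]) <= half[0]),
        crosses_cost_axis=bool(abs(mean[1]) <= half[1]),
        quadrant_shares=shares,
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# plotting (thin matplotlib wrappers)
# --------------------------------------------------------------------------


def plot_ce_plane(cloud: BootstrapCloud, confidence: float = 0.95, ax=None):
    """Scatter the cloud with its confidence ellipse."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    summary = ce_plane(cloud, confidence)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(cloud.delta_effect, cloud.delta_cost, s=2, alpha=0.2, color="#d46a9e")
    centre, width, height, angle = summary.ellipse_params()
    ax.add_patch(
        Ellipse(centre, width, height, angle=angle, fill=False, color="crimson", lw=1.5)
    )
    ax.plot(*centre[::1], marker="o", color="crimson", ms=4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    unit = {"qaly": "QALYs", "dcdl": "prevented deteriorations (pp)", "whodas": "WHODAS points"}
    ax.set_xlabel(f"Incremental effect ({unit[cloud.effect_kind]})")
    ax.set_ylabel("Incremental cost (EUR)")
    return ax


def plot_ceac(curves: dict[str, CEAC], reference_wtp: float = 50_000.0, ax=None):
    """Overlay acceptability curves; mark the reference threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.wtp, curve.probability, label=label)
    ax.axvline(reference_wtp, color="grey", ls="--", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (EUR)")
    ax.set_ylabel("Probability cost-effective")
    ax.legend(fontsize=8)
    return ax
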