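"""Baseline balance (standardised mean differences) and propensity matching.

Randomisation is checked with standardised mean differences (SMD); any
covariate with SMD >= 0.10 flags a need for adjustment.  The
per-protocol and setting-subgroup analyses compare post-randomisation
subsets of the intervention arm against the control arm, so a matched
control group is selected by 1:1 nearest-neighbour matching without
replacement on a logistic propensity score.

Nearest neighbours are found on the *pooled rank* of the propensity
score rather than the raw probability: rank distance is invariant to
any strictly monotone transform of the score (probability vs. linear
predictor), which removes one arbitrary software convention.  Treated
units are processed in descending propensity order (ties shuffled by
seed); rank-distance ties go to the lower-ranked donor.  No caliper is
applied by default; an optional probability-scale caliper is available
(using it sacrifices the monotone-transform invariance).

Matched analyses are non-randomised, exploratory comparisons and are
labelled as such in every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

#: Imbalance flag threshold for standardised mean differences.
SMD_THRESHOLD = 0.10

#: Label attached to every matched (non-randomised) comparison.
MATCHED_LABEL = "non-randomised, exploratory (propensity-score matched)"


def smd(group_a, group_b, kind: str = "continuous") -> float:
    """Absolute standardised mean difference between two groups.

    continuous: ``|m_a - m_b| / sqrt((v_a + v_b) / 2)`` with sample
    variances; binary: proportions with Bernoulli variances.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if kind == "continuous":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group for continuous SMD")
        denom = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        num = abs(a.mean() - b.mean())
    elif kind == "binary":
        pa, pb = a.mean(), b.mean()
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        num = abs(pa - pb)
    else:
        raise ValueError(f"unknown SMD kind {kind!r}")
    if denom == 0:
        if num == 0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(num / denom)


def balance_report(
    df: pd.DataFrame, arm_col: str, covariates: dict[str, str]
) -> pd.DataFrame:
    """SMD per covariate between the two arms, with the >= 10% flag.

    ``covariates`` maps column -> kind ("continuous" or "binary");
    non-numeric binary columns are compared against their first level.
    """
    arms = sorted(df[arm_col].dropna().unique())
    if len(arms) != 2:
        raise ValueError(f"expected exactly two arms, got {arms}")
    rows = []
    for col, kind in covariates.items():
        series = df[col]
        if not pd.api.types.is_numeric_dtype(series):
            ref = sorted(series.dropna().unique())[0]
            series = (series == ref).astype(float)
        a = series[df[arm_col] == arms[0]]
        b = series[df[arm_col] == arms[1]]
        val = smd(a, b, kind)
        rows.append({"covariate": col, "smd": val, "needs_adjustment": val >= SMD_THRESHOLD})
    return pd.DataFrame(rows).set_index("covariate")


@dataclass
class MatchSpec:
    """1:1 nearest-neighbour matching settings.

    ``covariates``: main-effects propensity model terms (categorical
    columns are one-hot encoded).  Matching is without replacement and
    has no caliper unless one is given (probability scale).
    """

    covariates: list[str] = field(default_factory=list)
    ratio: int = 1
    replacement: bool = False
    caliper: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio != 1 or self.replacement:
            raise ValueError("only 1:1 matching without replacement is supported")


def propensity_scores(
    treated: pd.DataFrame, donors: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Fitted treated-status probabilities from a main-effects logistic model."""
    both = pd.concat([treated[covariates], donors[covariates]], axis=0)
    X = pd.get_dummies(both, drop_first=True, dtype=float)
    if X.isna().any().any():
        raise ValueError("missing covariate values: run matching after imputation")
    y = np.r_[np.ones(len(treated)), np.zeros(len(donors))]
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(), y)
    if int(np.max(model.n_iter_)) >= 5000:
        warnings.warn("propensity model did not converge within 5000 iterations")
    p = model.predict_proba(X.to_numpy())[:, 1]
    return p[: len(treated)], p[len(treated):]


def match_by_score(
    score_treated: np.ndarray,
    score_donor: np.ndarray,
    seed: int = 0,
    caliper: float | None = None,
) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbour matching on pooled score ranks.

    Returns a frame with positional indices ``treated_pos`` /
    ``donor_pos`` and the probability-scale distance.  Every donor is
    used at most once.  With a caliper, treated units with no donor
    inside it are dropped (reported via the returned frame's length).
    """
    st = np.asarray(score_treated, float)
    sd = np.asarray(score_donor, float)
    if caliper is None and len(sd) < len(st):
        raise ValueError("donor pool smaller than treated pool")
    ranks = rankdata(np.concatenate([st, sd]), method="average")
    rt, rd = ranks[: len(st)], ranks[len(st):]

    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(st))
    order = np.lexsort((tiebreak, -st))  # descending score, ties by seed

    used = np.zeros(len(sd), bool)
    rows = []
    for ti in order:
        cand = ~used
        if caliper is not None:
            cand &= np.abs(sd - st[ti]) <= caliper
        if not cand.any():
            if caliper is None:
                raise ValueError("ran out of donors")
            continue
        dist = np.where(cand, np.abs(rd - rt[ti]), np.inf)
        best = dist.min()
        # rank-distance ties go to the lower-ranked donor
        winners = np.flatnonzero(dist == best)
        di = winners[np.argmin(rd[winners])]
        used[di] = True
        rows.append(
            {
                "treated_pos": int(ti),
                "donor_pos": int(di),
                "distance": float(abs(st[ti] - sd[di])),
                "rank_distance": float(best),
            }
        )
    return pd.DataFrame(rows).sort_values("treated_pos").reset_index(drop=True)


def propensity_match(
    treated: pd.DataFrame, donors: pd.DataFrame, spec: MatchSpec
) -> pd.DataFrame:
    """1:1 propensity-matched pairs (treated id, donor id, distance).

    Treated and donor pools must be disjoint and covariate-complete
    (match after imputation/combination).  Output groups are equal in
    size; no donor is reused.
    """
    if treated.index.intersection(donors.index).size:
        raise ValueError("treated and donor pools must be disjoint")
    pt, pd_ = propensity_scores(treated, donors, spec.covariates)
    pairs = match_by_score(pt, pd_, seed=spec.seed, caliper=spec.caliper)
    pairs["treated_id"] = treated.index.to_numpy()[pairs["treated_pos"].to_numpy()]
    pairs["donor_id"] = donors.index.to_numpy()[pairs["donor_pos"].to_numpy()]
    return pairs[["treated_id", "donor_id", "distance", "rank_distance"]]
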