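"""Predictor values at target specificity levels.

A threshold rule "score >= t is test-positive" attains specificity p
exactly when t sits at the p-quantile of the score distribution among
outcome-negative patients.  This module inverts that relationship: given
a target specificity level (e.g. 95%), it returns the empirical
p-quantile of the negatives' scores, with a distribution-free confidence
interval from binomial order-statistic bounds.

Quantile convention: linear interpolation between order statistics
(NumPy's default, R type 7).  When ties straddle the quantile badly
enough that the realised specificity would fall more than one order
statistic short of the target, the value is nudged just above the tied
block (midpoint to the next distinct value), resolving ties toward
higher specificity — consistent with the inclusive >= positivity rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (60.0, 80.0, 95.0, 98.0, 99.0)

#: Below this many outcome-negative subjects the order-statistic CI is
#: not attempted (both bounding ranks would sit at the sample edge).
MIN_NEGATIVES_FOR_CI = 20


@dataclass(frozen=True)
class CentileEstimate:
    outcome: str | None
    specificity_level: float
    value: float
    ci_lo: float
    ci_hi: float
    n_negative: int


def _quantile_order_statistic_ci(
    sorted_neg: np.ndarray, p: float, level: float
) -> tuple[float, float]:
    """Distribution-free CI for the p-quantile from order statistics.

    Bounding ranks l, u are chosen from the Binomial(n, p) distribution so
    that P(X_(l) <= quantile < X_(u)) >= level approximately; the interval
    is conservative for continuous data.
    """
    n = len(sorted_neg)
    alpha = 1.0 - level
    l = int(stats.binom.ppf(alpha / 2.0, n, p))
    u = int(stats.binom.ppf(1.0 - alpha / 2.0, n, p)) + 1
    l = min(max(l, 1), n)
    u = min(max(u, 1), n)
    return float(sorted_neg[l - 1]), float(sorted_neg[u - 1])


def value_at_specificity(
    scores,
    labels,
    level: float,
    ci_level: float = 0.95,
    outcome: str | None = None,
) -> CentileEstimate:
    """The predictor value whose >=-threshold yields the target specificity.

    ``level`` is a percentage in (0, 100); 0 and 100 are accepted as the
    minimum/maximum of the negatives' scores.  Scores must already be on
    a higher-is-worse scale.  With fewer than 20 negatives the point
    estimate is returned with a missing CI and a warning.
    """
    if not 0.0 <= level <= 100.0:
        raise ValueError(f"specificity level must be in [0, 100], got {level}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(s)
    neg = np.sort(s[keep & ~y])
    n = len(neg)
    if n == 0:
        raise ValueError("no outcome-negative subjects with a non-missing score")
    p = level / 100.0
    value = float(np.quantile(neg, p, method="linear"))
    # Tie handling: realised specificity under >=-positivity is the
    # fraction of negatives strictly below the threshold.  If a tied block
    # at the quantile drags it more than one order statistic under the
    # target, step just above the block.
    realised = np.mean(neg < value)
    if p - realised > 1.0 / n and np.any(neg == value):
        above = neg[neg > value]
        value = float((value + above.min()) / 2.0) if len(above) else float(value)
    if n < MIN_NEGATIVES_FOR_CI:
        logger.warning(
            "only %d outcome-negative subjects; centile CI not computed", n
        )
        lo = hi = float("nan")
    else:
        lo, hi = _quantile_order_statistic_ci(neg, p, ci_level)
    return CentileEstimate(
        outcome=outcome,
        specificity_level=float(level),
        value=value,
        ci_lo=lo,
        ci_hi=hi,
        n_negative=n,
    )


def centile_table(
    df: pd.DataFrame,
    predictor: str = "si",
    outcomes=("death", "smo", "smo_ci"),
    levels=DEFAULT_LEVELS,
) -> pd.DataFrame:
    """One row per outcome x specificity level for one predictor.

    Centiles depend only on outcome-negative patients, so rows remain
    computable for outcomes without a single positive.
    """
    if predictor not in df.columns:
        raise ValueError(f"predictor {predictor!r} not in table")
    scores = df[predictor].to_numpy(dtype=float)
    rows = []
    for outcome in outcomes:
        if outcome not in df.columns:
            raise ValueError(f"outcome {outcome!r} not in table")
        y = df[outcome].astype(bool).to_numpy()
        for level in levels:
            est = value_at_specificity(scores, y, level, outcome=outcome)
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": predictor,
                    "specificity_level": est.specificity_level,
                    "value": est.value,
                    "ci_lo": est.ci_lo,
                    "ci_hi": est.ci_hi,
                    "n_negative": est.n_negative,
                }
            )
    return pd.DataFrame(rows)
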