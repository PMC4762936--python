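"""Operating characteristics at candidate predictor thresholds.

For a cut-point t on a higher-is-worse score, a patient tests positive
when score >= t (inclusive, matching the "SI >= 0.9" phrasing of clinical
threshold rules).  From the resulting 2x2 table this module reports
sensitivity, specificity, positive and negative predictive value — each
as a percentage with an exact (Clopper-Pearson) binomial 95% confidence
interval on its own denominator — plus outcome prevalence and the
proportion of patients at or above each threshold.

Exact intervals are used deliberately: the all-success lower bound is
(alpha/2)^(1/n), e.g. 90.75% for 38/38, a signature that distinguishes
the Clopper-Pearson method from Wilson or Wald intervals in published
tables.  All internal arithmetic is unrounded; ``round_half_up`` is the
presentation-layer rounding helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (e.g. 0.25 -> 0.3 at 1 digit)."""
    x = float(x)
    if np.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts at a threshold (test-positive means score >= / > threshold)."""

    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float
    direction: str = "ge"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


def confusion_at_threshold(
    scores, labels, threshold: float, direction: str = "ge"
) -> ConfusionCounts:
    """Cross-classify test result (score vs threshold) against the outcome.

    Missing scores are excluded from all four cells, with the dropped
    count logged.  ``direction`` is ``ge`` (score >= t positive) or ``gt``.
    """
    if direction not in ("ge", "gt"):
        raise ValueError(f"unknown direction {direction!r}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(s)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("confusion_at_threshold: %d missing scores excluded", dropped)
    s, y = s[keep], y[keep]
    test_pos = s >= threshold if direction == "ge" else s > threshold
    return ConfusionCounts(
        tp=int((test_pos & y).sum()),
        fp=int((test_pos & ~y).sum()),
        fn=int((~test_pos & y).sum()),
        tn=int((~test_pos & ~y).sum()),
        threshold=float(threshold),
        direction=direction,
    )


def clopper_pearson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval, as percentages.

    Beta-quantile form: lower bound Beta(alpha/2; x, n-x+1), upper bound
    Beta(1-alpha/2; x+1, n-x); 0 and 100 at the respective boundaries.
    """
    if trials < 1:
        raise ValueError("clopper_pearson_ci requires trials >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be within [0, trials]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else stats.beta.ppf(
        alpha / 2.0, successes, trials - successes + 1
    )
    hi = 1.0 if successes == trials else stats.beta.ppf(
        1.0 - alpha / 2.0, successes + 1, trials - successes
    )
    return float(lo * 100.0), float(hi * 100.0)


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage with its exact CI and the counts it was computed from."""

    value: float
    ci_lo: float
    ci_hi: float
    numerator: int
    denominator: int


@dataclass(frozen=True)
class ThresholdReport:
    """Operating characteristics of one threshold for one outcome."""

    outcome: str | None
    threshold: float
    counts: ConfusionCounts
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    prevalence: MetricEstimate | None


def _metric(numerator: int, denominator: int, level: float) -> MetricEstimate | None:
    if denominator == 0:
        return None
    lo, hi = clopper_pearson_ci(numerator, denominator, level)
    return MetricEstimate(
        value=100.0 * numerator / denominator,
        ci_lo=lo,
        ci_hi=hi,
        numerator=numerator,
        denominator=denominator,
    )


def diagnostic_metrics(
    counts: ConfusionCounts, outcome: str | None = None, level: float = 0.95
) -> ThresholdReport:
    """Sensitivity, specificity, PPV, NPV and prevalence with exact CIs.

    A metric whose denominator is empty (e.g. NPV when nobody tests
    negative) is reported as None, not zero.
    """
    return ThresholdReport(
        outcome=outcome,
        threshold=counts.threshold,
        counts=counts,
        sensitivity=_metric(counts.tp, counts.tp + counts.fn, level),
        specificity=_metric(counts.tn, counts.tn + counts.fp, level),
        ppv=_metric(counts.tp, counts.tp + counts.fp, level),
        npv=_metric(counts.tn, counts.tn + counts.fn, level),
        prevalence=_metric(counts.positives, counts.total, level),
    )


def proportion_above(scores, thresholds) -> np.ndarray:
    """Fraction of non-missing scores at or above each threshold."""
    s = np.asarray(scores, dtype=float)
    s = s[~np.isnan(s)]
    out = np.array([np.mean(s >= t) if len(s) else np.nan for t in thresholds])
    return out


def threshold_table(
    df: pd.DataFrame,
    predictor: str = "si",
    thresholds=(0.7, 0.9, 1.4, 1.7),
    outcomes=("death", "smo", "smo_ci"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Report rows for every outcome x threshold of one predictor.

    Emits the 2x2 counts alongside each percentage so every figure can be
    re-derived from the table itself.
    """
    if predictor not in df.columns:
        raise ValueError(f"predictor {predictor!r} not in table")
    scores = df[predictor].to_numpy(dtype=float)
    rows = []
    for outcome in outcomes:
        if outcome not in df.columns:
            raise ValueError(f"outcome {outcome!r} not in table")
        y = df[outcome].astype(bool).to_numpy()
        for t in thresholds:
            counts = confusion_at_threshold(scores, y, t)
            rep = diagnostic_metrics(counts, outcome, level)
            row = {
                "outcome": outcome,
                "predictor": predictor,
                "threshold": t,
                "n": counts.total,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
            }
            for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
                est = getattr(rep, name)
                if est is None:
                    row[name] = np.nan
                    row[f"{name}_lo"] = np.nan
                    row[f"{name}_hi"] = np.nan
                else:
                    row[name] = est.value
                    row[f"{name}_lo"] = est.ci_lo
                    row[f"{name}_hi"] = est.ci_hi
            row["prevalence_n"] = counts.positives
            row["proportion_at_or_above"] = float(
                proportion_above(scores, [t])[0]
            )
            rows.append(row)
    return pd.DataFrame(rows)
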