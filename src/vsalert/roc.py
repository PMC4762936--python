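"""Nonparametric ROC analysis with DeLong comparison of correlated AUCs.

The AUC is estimated as the Mann-Whitney U-statistic with midrank tie
handling: the probability that a randomly chosen outcome-positive patient
scores worse than a randomly chosen outcome-negative patient (ties count
one half).  This equals the trapezoidal area under the empirical ROC
curve.

Variances and covariances of correlated AUC estimates (several predictors
scored on the same patients) use the DeLong structural-component
decomposition: for each positive subject, the mean placement of its score
against all negatives (V10); for each negative, the analogous quantity
(V01).  The AUC is the mean of either set, and

    Cov(AUC_a, AUC_b) = S10_ab / n_pos + S01_ab / n_neg

with S10, S01 the sample covariance matrices of the components.  Equality
of two correlated AUCs is tested with the 1-df chi-square statistic

    chi2 = (AUC_a - AUC_b)^2 / (var_a + var_b - 2 cov_ab),

Bonferroni-adjusted over the set of comparisons against the reference
predictor.

Orientation: predictors where *lower* values indicate worse status (SBP,
DBP, MAP) are negated before ranking so every score is higher-is-worse.
Pulse pressure is deliberately left higher-is-worse, which yields AUC
below 0.5 when it is (weakly) protective — matching how such predictors
are conventionally reported un-reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PREDICTORS = ("si", "pulse", "sbp", "dbp", "map", "pulse_pressure")

#: Fixed per-predictor orientation; "lower_is_worse" scores are negated
#: before ranking.
ORIENTATION = {
    "si": "higher_is_worse",
    "pulse": "higher_is_worse",
    "sbp": "lower_is_worse",
    "dbp": "lower_is_worse",
    "map": "lower_is_worse",
    "pulse_pressure": "higher_is_worse",
}


class DegenerateClassError(ValueError):
    """AUC is undefined without at least one positive and one negative."""


def oriented(scores, orientation: str = "higher_is_worse") -> np.ndarray:
    """Return scores on a higher-is-worse scale (negated when needed)."""
    scores = np.asarray(scores, dtype=float)
    if orientation == "higher_is_worse":
        return scores
    if orientation == "lower_is_worse":
        return -scores
    raise ValueError(f"unknown orientation {orientation!r}")


def _split(scores, labels, orientation):
    s = oriented(scores, orientation)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if not y.any() or y.all():
        raise DegenerateClassError(
            "need at least one positive and one negative with a non-missing score"
        )
    return s[y], s[~y]


def delong_components(
    scores, labels, orientation: str = "higher_is_worse"
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative).

    Components use midranks, so mean(V10) = mean(V01) = AUC exactly, ties
    included.
    """
    pos, neg = _split(scores, labels, orientation)
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return float(auc), v10, v01


def auc_mann_whitney(
    scores, labels, orientation: str = "higher_is_worse"
) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    auc, _, _ = delong_components(scores, labels, orientation)
    return auc


def delong_variance(
    scores, labels, orientation: str = "higher_is_worse"
) -> tuple[float, float]:
    """(AUC, DeLong variance) for a single predictor."""
    auc, v10, v01 = delong_components(scores, labels, orientation)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise DegenerateClassError(
            "DeLong variance needs >= 2 positives and >= 2 negatives"
        )
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_cov(
    score_matrix, labels, orientations=None
) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for predictors on common patients.

    ``score_matrix`` has one row per predictor; subjects with a missing
    value for *any* predictor are dropped (complete-pairs analysis).
    """
    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("score_matrix must be 2-d (predictors x subjects)")
    k = x.shape[0]
    if orientations is None:
        orientations = ["higher_is_worse"] * k
    x = np.vstack([oriented(x[i], orientations[i]) for i in range(k)])
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(x).any(axis=0)
    x, y = x[:, keep], y[keep]
    m, n = int(y.sum()), int((~y).sum())
    if m < 2 or n < 2:
        raise DegenerateClassError(
            "DeLong covariance needs >= 2 positives and >= 2 negatives"
        )
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for i in range(k):
        aucs[i], v10[i], v01[i] = delong_components(x[i], y)
    s10 = np.atleast_2d(np.cov(v10, ddof=1))
    s01 = np.atleast_2d(np.cov(v01, ddof=1))
    return aucs, s10 / m + s01 / n


def auc_ci(
    auc: float, var_auc: float, level: float = 0.95, scale: str = "linear"
) -> tuple[float, float]:
    """Wald confidence interval for an AUC, truncated to [0, 1].

    ``scale="logit"`` computes the interval on the log-odds scale and
    back-transforms, which avoids truncation for AUCs near the boundary.
    """
    if var_auc < 0:
        raise ValueError("var_auc must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(var_auc)
    if scale == "linear":
        return (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if scale == "logit":
        if se == 0 or auc <= 0 or auc >= 1:
            return (auc, auc)
        lo_logit = np.log(auc / (1 - auc)) - z * se / (auc * (1 - auc))
        hi_logit = np.log(auc / (1 - auc)) + z * se / (auc * (1 - auc))
        expit = lambda t: 1.0 / (1.0 + np.exp(-t))
        return (float(expit(lo_logit)), float(expit(hi_logit)))
    raise ValueError(f"unknown scale {scale!r}")


@dataclass
class AUCComparison:
    """Paired chi-square test of AUC equality against a reference predictor."""

    reference: str
    comparand: str
    outcome: str | None
    n_common: int
    auc_reference: float
    auc_comparand: float
    chi2: float
    df: int
    p_raw: float
    p_bonferroni: float
    m: int


def compare_auc_paired(
    ref_scores,
    other_scores,
    labels,
    ref_orientation: str = "higher_is_worse",
    other_orientation: str = "higher_is_worse",
    m: int = 1,
    reference: str = "reference",
    comparand: str = "comparand",
    outcome: str | None = None,
) -> AUCComparison:
    """DeLong paired test that two correlated AUCs are equal (1-df chi-square).

    Computed on the subset of patients where both predictors and the
    outcome are non-missing.  ``m`` is the Bonferroni multiplier (number
    of comparisons in the family); p_bonferroni = min(1, m * p_raw).
    """
    x = np.vstack(
        [np.asarray(ref_scores, dtype=float), np.asarray(other_scores, dtype=float)]
    )
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(x).any(axis=0)
    aucs, cov = delong_cov(x[:, keep], y[keep],
                           [ref_orientation, other_orientation])
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var_diff <= 1e-15:
        # Zero-variance difference: distinct AUCs are then infinitely
        # significant; identical AUCs are trivially equal.
        chi2 = np.inf if abs(diff) > 1e-12 else 0.0
        p_raw = 0.0 if abs(diff) > 1e-12 else 1.0
    else:
        chi2 = diff**2 / var_diff
        p_raw = float(stats.chi2.sf(chi2, df=1))
    return AUCComparison(
        reference=reference,
        comparand=comparand,
        outcome=outcome,
        n_common=int(keep.sum()),
        auc_reference=float(aucs[0]),
        auc_comparand=float(aucs[1]),
        chi2=float(chi2),
        df=1,
        p_raw=p_raw,
        p_bonferroni=min(1.0, m * p_raw),
        m=m,
    )


def roc_curve_points(
    scores, labels, orientation: str = "higher_is_worse"
) -> pd.DataFrame:
    """Empirical ROC curve as (threshold, fpr, tpr) rows.

    The curve starts at (0, 0), ends at (1, 1), steps only at distinct
    score values (tied values form a single diagonal segment), and its
    trapezoidal area equals the Mann-Whitney AUC.
    """
    pos, neg = _split(scores, labels, orientation)
    s = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    last_of_run = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last_of_run] / len(pos)]
    fpr = np.r_[0.0, fps[last_of_run] / len(neg)]
    thresholds = np.r_[np.inf, s[last_of_run]]
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


@dataclass
class ROCResult:
    predictor: str
    outcome: str
    n: int
    n_pos: int
    n_neg: int
    auc: float
    var_auc: float
    ci95: tuple[float, float]
    curve: pd.DataFrame


def roc_single(
    scores, labels, predictor: str = "score", outcome: str = "outcome",
    orientation: str | None = None, level: float = 0.95,
) -> ROCResult:
    """AUC, DeLong CI and curve for one predictor/outcome pair."""
    if orientation is None:
        orientation = ORIENTATION.get(predictor, "higher_is_worse")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(s)
    auc, var = delong_variance(s[keep], y[keep], orientation)
    return ROCResult(
        predictor=predictor,
        outcome=outcome,
        n=int(keep.sum()),
        n_pos=int(y[keep].sum()),
        n_neg=int((~y[keep]).sum()),
        auc=auc,
        var_auc=var,
        ci95=auc_ci(auc, var, level),
        curve=roc_curve_points(s[keep], y[keep], orientation),
    )


def roc_table(
    df: pd.DataFrame,
    predictors=PREDICTORS,
    outcomes=("death", "smo", "smo_ci"),
    reference: str = "si",
    bonferroni_m: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per predictor x outcome: n, AUC, CI, and DeLong comparison vs reference.

    ``df`` is a derived table with one row per patient, predictor columns
    and boolean outcome columns.  Comparisons run on complete pairs (both
    predictors non-missing); significance flags use the Bonferroni-
    adjusted p-value at 0.05 and 0.01.
    """
    unknown = [p for p in predictors if p not in df.columns]
    unknown += [o for o in outcomes if o not in df.columns]
    if unknown:
        raise ValueError(f"columns not in derived table: {unknown}")
    if reference is not None and reference not in predictors:
        raise ValueError(f"reference {reference!r} not among predictors")
    m = bonferroni_m
    if m is None:
        m = max(1, len([p for p in predictors if p != reference]))
    rows = []
    for outcome in outcomes:
        y_all = df[outcome].astype(bool).to_numpy()
        for predictor in predictors:
            s_all = df[predictor].to_numpy(dtype=float)
            keep = ~np.isnan(s_all)
            try:
                res = roc_single(
                    s_all[keep], y_all[keep], predictor, outcome, level=level
                )
            except DegenerateClassError:
                rows.append(
                    {"predictor": predictor, "outcome": outcome,
                     "n": int(keep.sum())}
                )
                continue
            row = {
                "predictor": predictor,
                "outcome": outcome,
                "n": res.n,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
                "auc": res.auc,
                "ci_lo": res.ci95[0],
                "ci_hi": res.ci95[1],
            }
            if reference is not None and predictor != reference:
                cmp = compare_auc_paired(
                    df[reference].to_numpy(dtype=float),
                    s_all,
                    y_all,
                    ref_orientation=ORIENTATION.get(reference, "higher_is_worse"),
                    other_orientation=ORIENTATION.get(predictor, "higher_is_worse"),
                    m=m,
                    reference=reference,
                    comparand=predictor,
                    outcome=outcome,
                )
                row.update(
                    {
                        "n_common": cmp.n_common,
                        "chi2_vs_reference": cmp.chi2,
                        "p_raw": cmp.p_raw,
                        "p_bonferroni": cmp.p_bonferroni,
                        "significant_05": cmp.p_bonferroni < 0.05,
                        "significant_01": cmp.p_bonferroni < 0.01,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)
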