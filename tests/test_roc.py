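"""Mann-Whitney AUC, DeLong components/covariance, and paired comparison."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from vsalert import (
    auc_ci,
    auc_mann_whitney,
    compare_auc_paired,
    delong_components,
    delong_cov,
    delong_variance,
    roc_curve_points,
    roc_table,
)
from vsalert.roc import DegenerateClassError, ORIENTATION
from vsalert.thresholds import round_half_up


def brute_force_auc(pos, neg):
    """U-statistic by explicit double loop (the independent oracle)."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def _scores_labels(pos, neg):
    scores = np.concatenate([pos, neg])
    labels = np.r_[np.ones(len(pos), bool), np.zeros(len(neg), bool)]
    return scores, labels


class TestAUC:
    def test_worked_example_with_tie(self):
        scores, labels = _scores_labels([3.0, 2.0], [1.0, 2.0])
        assert auc_mann_whitney(scores, labels) == pytest.approx(0.875)

    def test_perfect_separation(self):
        scores, labels = _scores_labels([5.0, 6.0], [1.0, 2.0])
        assert auc_mann_whitney(scores, labels) == 1.0

    def test_all_ties(self):
        scores, labels = _scores_labels([1.0, 1.0], [1.0, 1.0, 1.0])
        assert auc_mann_whitney(scores, labels) == 0.5

    def test_degenerate_classes_raise(self):
        with pytest.raises(DegenerateClassError):
            auc_mann_whitney([1.0, 2.0], [True, True])

    def test_orientation_negates_lower_is_worse(self):
        scores, labels = _scores_labels([80.0, 70.0], [110.0, 120.0])
        assert auc_mann_whitney(scores, labels, "lower_is_worse") == 1.0

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        labels[:2] = [True, False]
        a1 = auc_mann_whitney(scores, labels)
        a2 = auc_mann_whitney(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_matches_sklearn_with_ties(self, rng):
        """Cross-library check on random discretized (tied) scores."""
        for _ in range(25):
            n = rng.integers(10, 60)
            scores = rng.integers(0, 6, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestDeLongComponents:
    def test_hand_enumerated_components(self):
        scores, labels = _scores_labels([3.0, 2.0], [1.0, 2.0])
        auc, v10, v01 = delong_components(scores, labels)
        assert auc == pytest.approx(0.875)
        assert v10.tolist() == [1.0, 0.75]
        assert v01.tolist() == [1.0, 0.75]

    def test_single_pair(self):
        scores, labels = _scores_labels([2.0], [1.0])
        auc, v10, v01 = delong_components(scores, labels)
        assert (auc, v10.tolist(), v01.tolist()) == (1.0, [1.0], [1.0])

    def test_label_swap_antisymmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            1.0 - auc_mann_whitney(scores, ~labels), abs=1e-12
        )

    def test_component_means_equal_auc(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 8, 30).astype(float)
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            auc, v10, v01 = delong_components(scores, labels)
            assert v10.mean() == pytest.approx(auc, abs=1e-12)
            assert v01.mean() == pytest.approx(auc, abs=1e-12)


class TestDeLongCovariance:
    def test_duplicated_predictor_gives_equal_entries(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        aucs, cov = delong_cov(np.vstack([scores, scores]), labels)
        assert aucs[0] == aucs[1]
        assert cov[0, 0] == pytest.approx(cov[0, 1], abs=1e-15)
        assert cov[0, 0] == pytest.approx(cov[1, 1], abs=1e-15)

    def test_diagonal_matches_single_predictor_variance(self, rng):
        x = rng.normal(size=(2, 50))
        labels = rng.random(50) < 0.4
        labels[:2] = [True, False]
        aucs, cov = delong_cov(x, labels)
        for i in range(2):
            auc_i, var_i = delong_variance(x[i], labels)
            assert aucs[i] == pytest.approx(auc_i)
            assert cov[i, i] == pytest.approx(var_i, abs=1e-15)

    def test_positive_semidefinite(self, rng):
        x = rng.normal(size=(3, 40)) + rng.normal(size=40) * 0.5
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        _, cov = delong_cov(x, labels)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-12

    @staticmethod
    def _plain_jackknife(x, labels):
        n = len(labels)
        k = x.shape[0]
        loo = np.empty((n, k))
        for j in range(n):
            mask = np.arange(n) != j
            for i in range(k):
                loo[j, i] = auc_mann_whitney(x[i][mask], labels[mask])
        centered = loo - loo.mean(axis=0)
        return (n - 1) / n * centered.T @ centered

    def test_stratified_jackknife_identity_on_six_subjects(self):
        """Class-wise delete-one jackknife with matched ddof reproduces the
        DeLong covariance exactly on a 6-subject instance."""
        x = np.array(
            [[3.0, 2.5, 1.8, 2.0, 1.0, 1.5], [2.8, 2.0, 2.2, 1.9, 1.2, 0.8]]
        )
        labels = np.array([True, True, True, False, False, False])
        _, cov = delong_cov(x, labels)
        # stratified jackknife: drop one positive (resp. negative) at a time;
        # pseudo-value covariance within class / class size
        m = n = 3
        jack = np.zeros((2, 2))
        for cls, size in ((True, m), (False, n)):
            loo = np.empty((size, 2))
            idx = np.flatnonzero(labels == cls)
            for j, drop in enumerate(idx):
                mask = np.arange(6) != drop
                for i in range(2):
                    loo[j, i] = auc_mann_whitney(x[i][mask], labels[mask])
            centered = (loo - loo.mean(axis=0)) * (size - 1)
            jack += centered.T @ centered / (size - 1) / size
        assert cov == pytest.approx(jack, rel=1e-9)

    def test_plain_jackknife_agrees_at_moderate_n(self, rng):
        """The unstratified delete-one jackknife converges to the DeLong
        covariance; at 40 subjects they agree within 10%."""
        z = rng.normal(size=40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        x = np.vstack(
            [z + rng.normal(0, 0.8, 40), z + rng.normal(0, 0.8, 40)]
        ) + 1.0 * labels
        _, cov = delong_cov(x, labels)
        jack = self._plain_jackknife(x, labels)
        assert np.all(np.abs(cov / jack - 1.0) < 0.10)


class TestAUCConfidenceInterval:
    def test_zero_variance_degenerate(self):
        assert auc_ci(0.5, 0.0) == (0.5, 0.5)

    def test_truncation_at_one(self):
        lo, hi = auc_ci(0.99, 0.01)
        assert hi == 1.0 and lo > 0.7

    def test_published_interval_round_trip(self):
        """se back-solved from a printed interval 0.87 (0.80-0.94)
        reproduces the interval after rounding."""
        lo, hi = auc_ci(0.87, 0.0357**2)
        assert (round_half_up(lo, 2), round_half_up(hi, 2)) == (0.80, 0.94)

    def test_logit_scale_stays_inside_unit_interval(self):
        lo, hi = auc_ci(0.97, 0.02, scale="logit")
        assert 0.0 < lo < 0.97 < hi < 1.0


class TestPairedComparison:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.4
        labels[:2] = [True, False]
        cmp = compare_auc_paired(scores, scores, labels)
        assert cmp.chi2 == 0.0
        assert cmp.p_raw == 1.0

    def test_statistic_matches_covariance_formula(self, rng):
        z = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        labels[:2] = [True, False]
        x = np.vstack([z + rng.normal(0, 1, 80), rng.normal(0, 1, 80)])
        cmp = compare_auc_paired(x[0], x[1], labels)
        aucs, cov = delong_cov(x, labels)
        expected = (aucs[0] - aucs[1]) ** 2 / (
            cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        )
        assert cmp.chi2 == pytest.approx(expected, rel=1e-12)
        # for independently generated predictors the covariance term is
        # negligible and the paired chi2 approaches the unpaired z^2
        unpaired = (aucs[0] - aucs[1]) ** 2 / (cov[0, 0] + cov[1, 1])
        assert abs(cov[0, 1]) < 0.2 * (cov[0, 0] + cov[1, 1])
        assert cmp.chi2 == pytest.approx(unpaired, rel=0.5)

    def test_bonferroni_multiplication(self, rng):
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.3
        labels[:2] = [True, False]
        other = scores + rng.normal(0, 0.5, 200)
        cmp = compare_auc_paired(scores, other, labels, m=5)
        assert cmp.p_bonferroni == pytest.approx(min(1.0, 5 * cmp.p_raw))

    def test_complete_pairs_subset(self, rng):
        scores = rng.normal(size=60)
        other = scores.copy()
        other[:10] = np.nan
        labels = rng.random(60) < 0.5
        labels[10:12] = [True, False]
        cmp = compare_auc_paired(scores, other, labels)
        assert cmp.n_common == 50


class TestROCCurve:
    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.integers(0, 5, 40).astype(float)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        curve = roc_curve_points(scores, labels)
        assert (curve.iloc[0].fpr, curve.iloc[0].tpr) == (0.0, 0.0)
        assert (curve.iloc[-1].fpr, curve.iloc[-1].tpr) == (1.0, 1.0)
        assert (curve.fpr.diff().dropna() >= 0).all()
        assert (curve.tpr.diff().dropna() >= 0).all()

    def test_trapezoid_area_equals_u_statistic(self, rng):
        for _ in range(30):
            n = rng.integers(8, 30)
            scores = rng.integers(0, 4, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            curve = roc_curve_points(scores, labels)
            area = np.trapezoid(curve.tpr, curve.fpr)
            assert area == pytest.approx(
                auc_mann_whitney(scores, labels), abs=1e-12
            )


class TestROCTable:
    def test_reference_is_top_two_for_all_outcomes(self, analysis_table):
        """On the calibrated synthetic cohort the shock index ranks among
        the top two predictors for death, SMO and SMO-CI."""
        table = roc_table(analysis_table)
        for outcome in ("death", "smo", "smo_ci"):
            sub = table[table.outcome == outcome].sort_values(
                "auc", ascending=False
            )
            assert "si" in sub.predictor.head(2).tolist()

    def test_outcome_independent_scores_cover_half(self, rng):
        import pandas as pd

        n = 400
        df = pd.DataFrame(
            {
                "si": rng.normal(size=n),
                "pulse": rng.normal(size=n),
                "death": rng.random(n) < 0.3,
            }
        )
        table = roc_table(df, predictors=("si", "pulse"),
                          outcomes=("death",), reference="si")
        for _, row in table.iterrows():
            assert row.ci_lo <= 0.5 <= row.ci_hi

    def test_single_predictor_run_has_no_comparison_columns(self, analysis_table):
        table = roc_table(
            analysis_table, predictors=("si",), outcomes=("death",),
            reference="si",
        )
        assert len(table) == 1
        assert "chi2_vs_reference" not in table.columns

    def test_dbp_comparisons_use_complete_pairs(self, analysis_table):
        table = roc_table(analysis_table)
        row = table[(table.predictor == "dbp") & (table.outcome == "death")]
        assert int(row.n_common.iloc[0]) == int(row.n.iloc[0])
        assert int(row.n.iloc[0]) < int(
            table[(table.predictor == "si") & (table.outcome == "death")].n.iloc[0]
        )

    def test_pulse_pressure_oriented_higher_is_worse(self, analysis_table):
        """PP is deliberately not re-oriented, so its AUC falls below 0.5
        on the synthetic cohort (weakly protective predictor)."""
        assert ORIENTATION["pulse_pressure"] == "higher_is_worse"
        table = roc_table(analysis_table)
        pp = table[(table.predictor == "pulse_pressure")
                   & (table.outcome == "death")]
        assert pp.auc.iloc[0] < 0.5
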