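"""Univariate ROC and multivariate panel evaluation."""

import numpy as np
import pandas as pd
import pytest

from lipidmrm.biomarker_roc import CvConfig, fit_panel, predict_validation, univariate_roc
from lipidmrm.ingest import FeatureMatrix
from lipidmrm.reference import CERAMIDE_PANEL
from lipidmrm.synthetic_data import CohortConfig, generate_cohort
from lipidmrm.ingest import assemble_matrix, profiles_from_table


def _pairwise_auc(values, labels):
    """Brute-force AUC over all (positive, negative) pairs, ties half."""
    pos = values[labels == "cpdm"]
    neg = values[labels != "cpdm"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auc = wins / (len(pos) * len(neg))
    return max(auc, 1 - auc)


class TestUnivariate:
    def test_perfect_separation(self):
        values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array(["WT"] * 3 + ["cpdm"] * 3)
        res = univariate_roc(values, labels)
        assert res.auc == 1.0
        assert 3 < res.threshold < 10

    def test_orientation_flips_to_at_least_half(self):
        values = np.array([10, 11, 12, 1, 2, 3], dtype=float)
        labels = np.array(["WT"] * 3 + ["cpdm"] * 3)
        res = univariate_roc(values, labels)
        assert res.auc == 1.0
        assert res.direction == "less"

    def test_random_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        values = rng.random(10000)
        labels = np.where(rng.random(10000) < 0.5, "cpdm", "WT")
        assert univariate_roc(values, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_rank_auc_equals_pairwise_and_trapezoid(self):
        """Rank statistic == pair counting == sklearn's trapezoidal ROC."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(6, 40)
            # coarse levels force ties, including ties across the boundary
            values = rng.integers(0, 6, n).astype(float)
            labels = np.where(rng.random(n) < 0.5, "cpdm", "WT")
            if len(set(labels)) < 2:
                continue
            ours = univariate_roc(values, labels).auc
            assert ours == pytest.approx(_pairwise_auc(values, labels), abs=1e-12)
            sk = roc_auc_score((labels == "cpdm").astype(int), values)
            assert ours == pytest.approx(max(sk, 1 - sk), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_roc(np.arange(5.0), np.array(["WT"] * 5))


@pytest.fixture(scope="module")
def panel_matrix(method_pos):
    table = generate_cohort(CohortConfig(seed=21), method_pos)
    return assemble_matrix(profiles_from_table(table, method_pos))


class TestPanel:
    def test_informative_panel_has_perfect_cv_auc(self, panel_matrix):
        _, cv_auc, cv_acc = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(seed=0))
        assert cv_auc == pytest.approx(1.0)
        assert cv_acc == pytest.approx(1.0)

    def test_uninformative_panel_is_chance_level(self, method_pos):
        cfg = CohortConfig(effects={t: 1.0 for t in CERAMIDE_PANEL}, seed=5)
        table = generate_cohort(cfg, method_pos)
        matrix = assemble_matrix(profiles_from_table(table, method_pos))
        _, cv_auc, _ = fit_panel(matrix, CERAMIDE_PANEL, cv=CvConfig(seed=0))
        assert cv_auc == pytest.approx(0.5, abs=0.25)

    def test_same_seed_reproduces_metrics(self, panel_matrix):
        a = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(seed=3))
        b = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(seed=3))
        assert a[1] == b[1] and a[2] == b[2]

    def test_missing_panel_feature_rejected(self, panel_matrix):
        with pytest.raises(KeyError, match="missing"):
            fit_panel(panel_matrix, ["1.0->1.0"])

    def test_random_forest_backend(self, panel_matrix):
        model, cv_auc, _ = fit_panel(
            panel_matrix, CERAMIDE_PANEL, algorithm="rf", cv=CvConfig(repeats=10, seed=0)
        )
        assert model.algorithm == "rf"
        assert cv_auc > 0.9

    def test_effect_size_monotonicity(self, method_pos):
        """Stronger generator effects never reduce expected CV AUC."""
        mean_aucs = []
        for fc in (1.0, 2.0, 5.0, 20.0):
            aucs = []
            for seed in range(3):
                cfg = CohortConfig(
                    effects={t: fc for t in CERAMIDE_PANEL},
                    cv=0.4,  # noisy regime so weak effects stay imperfect
                    seed=100 + seed,
                    n_wt_validation=0,
                    n_cpdm_validation=0,
                )
                table = generate_cohort(cfg, method_pos)
                matrix = assemble_matrix(profiles_from_table(table, method_pos))
                _, cv_auc, _ = fit_panel(
                    matrix, CERAMIDE_PANEL, cv=CvConfig(repeats=30, seed=seed)
                )
                aucs.append(cv_auc)
            mean_aucs.append(np.mean(aucs))
        assert all(b >= a - 0.02 for a, b in zip(mean_aucs, mean_aucs[1:]))


class TestValidationPrediction:
    def test_blind_prediction_is_exact_on_panel_cohort(self, panel_matrix):
        model, _, _ = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(seed=0))
        pred = predict_validation(model, panel_matrix)
        assert pred.accuracy == 1.0
        assert ((pred.probabilities >= 0) & (pred.probabilities <= 1)).all()

    def test_empty_validation_set_is_not_an_error(self, method_pos):
        cfg = CohortConfig(n_wt_validation=0, n_cpdm_validation=0, seed=2)
        table = generate_cohort(cfg, method_pos)
        matrix = assemble_matrix(profiles_from_table(table, method_pos))
        model, _, _ = fit_panel(matrix, CERAMIDE_PANEL, cv=CvConfig(repeats=10, seed=0))
        pred = predict_validation(model, matrix)
        assert pred.probabilities is None and pred.accuracy is None

    def test_split_leakage_detected(self, panel_matrix):
        model, _, _ = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(repeats=5, seed=0))
        leaked = FeatureMatrix(
            panel_matrix.X,
            panel_matrix.groups,
            pd.Series("validation", index=panel_matrix.X.index),
        )
        with pytest.raises(ValueError, match="seen in training"):
            predict_validation(model, leaked)

    def test_shuffled_validation_labels_leave_weights_untouched(self, panel_matrix):
        model, _, _ = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(repeats=5, seed=0))
        coef_before = np.array(model.estimator.coef_, copy=True)
        shuffled = FeatureMatrix(
            panel_matrix.X,
            pd.Series(
                np.random.default_rng(0).permutation(panel_matrix.groups.to_numpy()),
                index=panel_matrix.X.index,
            ),
            panel_matrix.splits,
        )
        predict_validation(model, shuffled)
        assert np.array_equal(coef_before, np.array(model.estimator.coef_))

    def test_missing_feature_refused_at_prediction(self, panel_matrix):
        model, _, _ = fit_panel(panel_matrix, CERAMIDE_PANEL, cv=CvConfig(repeats=5, seed=0))
        reduced = FeatureMatrix(
            panel_matrix.X.drop(columns=[CERAMIDE_PANEL[0]]),
            panel_matrix.groups,
            panel_matrix.splits,
        )
        with pytest.raises(KeyError, match="lacks panel features"):
            predict_validation(model, reduced)
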