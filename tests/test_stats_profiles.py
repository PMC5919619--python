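"""Univariate tests, multiple-testing control, PCA, clustering, profiles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lipidmrm.attribution import attribute_method
from lipidmrm.ingest import FeatureMatrix
from lipidmrm.stats_profiles import (
    FeatureStat,
    aggregate_profiles,
    autoscale,
    cluster_heatmap,
    holm_sidak_reject,
    holm_sidak_ttests,
    pca_autoscaled,
    volcano_select,
)


def _matrix(X, groups, splits=None):
    X = pd.DataFrame(X)
    X.index = [f"s{i:02d}" for i in range(len(X))]
    groups = pd.Series(groups, index=X.index)
    splits = pd.Series(splits or ["testing"] * len(X), index=X.index)
    return FeatureMatrix(X, groups, splits)


def _literal_holm_sidak(pvals, alpha):
    """The step-down definition, applied literally (independent oracle)."""
    m = len(pvals)
    order = np.argsort(pvals)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        threshold = 1 - (1 - alpha) ** (1.0 / (m - rank))
        if pvals[idx] <= threshold:
            reject[idx] = True
        else:
            break  # step-down: stop at the first acceptance
    return reject


class TestHolmSidak:
    def test_three_p_closed_form_example(self):
        # m=3, alpha=0.05: thresholds 0.016952 / 0.025321 / 0.05
        reject = holm_sidak_reject([0.001, 0.2, 0.9], alpha=0.05)
        assert reject.tolist() == [True, False, False]
        # the first threshold in closed form
        assert 1 - 0.95 ** (1 / 3) == pytest.approx(0.016952, abs=1e-6)

    def test_matches_literal_definition_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 25)
            # mixture of nulls and signals so both branches are exercised
            p = np.where(rng.random(m) < 0.4, rng.random(m) * 0.05, rng.random(m))
            assert np.array_equal(
                holm_sidak_reject(p, 0.05), _literal_holm_sidak(p, 0.05)
            )

    def test_rejection_monotone_in_raw_p(self):
        p = np.array([0.001, 0.004, 0.02, 0.3, 0.6])
        reject = holm_sidak_reject(p, 0.05)
        assert all(reject[i] >= reject[i + 1] for i in range(len(p) - 1))

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        base = rng.random(5)
        X = np.abs(base + rng.normal(0, 1e-3, size=(40, 5)))
        X = X / X.sum(axis=1, keepdims=True)
        matrix = _matrix(X, ["WT"] * 20 + ["cpdm"] * 20)
        stats = holm_sidak_ttests(matrix)
        assert not any(s.significant for s in stats)

    def test_zero_variance_feature_flagged_untested(self):
        X = np.ones((6, 2))
        X[:, 1] = [1, 2, 3, 4, 5, 6]
        matrix = _matrix(X, ["WT"] * 3 + ["cpdm"] * 3)
        stats = holm_sidak_ttests(matrix)
        assert not stats[0].tested and np.isnan(stats[0].raw_p)
        assert stats[1].tested

    def test_sample_order_invariance(self, cohort_matrix):
        stats_a = holm_sidak_ttests(cohort_matrix)
        perm = np.random.default_rng(3).permutation(len(cohort_matrix.X))
        shuffled = FeatureMatrix(
            cohort_matrix.X.iloc[perm],
            cohort_matrix.groups.iloc[perm],
            cohort_matrix.splits.iloc[perm],
        )
        stats_b = holm_sidak_ttests(shuffled)
        for a, b in zip(stats_a, stats_b):
            assert a.transition == b.transition
            assert a.fold_change == pytest.approx(b.fold_change)
            assert a.raw_p == pytest.approx(b.raw_p, nan_ok=True)
            assert a.significant == b.significant


class TestVolcano:
    @pytest.mark.parametrize(
        "fc, p, kept",
        [
            (2.31, 7.67e-12, True),  # up-regulated
            (0.42, 7.40e-06, True),  # down-regulated side
            (1.5, 1e-9, False),  # fails the fold criterion
            (3.0, 0.2, False),  # fails the p criterion
        ],
    )
    def test_selection_rule(self, fc, p, kept):
        stat = FeatureStat("t", 1.0, fc, fc, p, False)
        selected = volcano_select([stat])
        assert (stat in selected) is kept


class TestPca:
    def test_autoscaled_columns_have_unit_moments(self, cohort_matrix):
        Z = autoscale(cohort_matrix.X)
        assert np.allclose(Z.mean(), 0.0, atol=1e-12)
        assert np.allclose(Z.std(ddof=1), 1.0, atol=1e-12)

    def test_explained_variance_fractions(self, cohort_matrix):
        res = pca_autoscaled(cohort_matrix)
        ev = res.explained_variance_ratio
        assert (ev >= -1e-12).all()
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() == pytest.approx(1.0)

    def test_duplicated_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.random(6)
        b = a + 3.0
        X = np.vstack([a + rng.normal(0, 1e-6, (5, 6)), b + rng.normal(0, 1e-6, (5, 6))])
        matrix = _matrix(X, ["WT"] * 5 + ["cpdm"] * 5)
        res = pca_autoscaled(matrix)
        assert res.explained_variance_ratio[0] > 0.999
        pc1 = res.scores["PC1"]
        assert pc1.iloc[:5].max() < pc1.iloc[5:].min() or pc1.iloc[5:].max() < pc1.iloc[:5].min()

    def test_sign_convention_fixed(self, cohort_matrix):
        res = pca_autoscaled(cohort_matrix)
        for col in res.loadings.columns:
            loading = res.loadings[col]
            assert loading.iloc[np.argmax(np.abs(loading.to_numpy()))] > 0

    def test_constant_feature_dropped_with_warning(self):
        X = np.random.default_rng(0).random((8, 3))
        X[:, 2] = 0.5
        matrix = _matrix(X, ["WT"] * 4 + ["cpdm"] * 4)
        with pytest.warns(UserWarning, match="constant"):
            res = pca_autoscaled(matrix)
        assert res.loadings.shape[0] == 2


class TestClustering:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 4))
        X[1] = X[0]  # exact duplicates
        matrix = _matrix(X, ["WT"] * 3 + ["cpdm"] * 2)
        res = cluster_heatmap(matrix)
        first_merge = res.sample_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0)

    def test_row_permutation_preserves_topology(self, cohort_matrix):
        res_a = cluster_heatmap(cohort_matrix)
        perm = np.random.default_rng(5).permutation(len(cohort_matrix.X))
        shuffled = FeatureMatrix(
            cohort_matrix.X.iloc[perm],
            cohort_matrix.groups.iloc[perm],
            cohort_matrix.splits.iloc[perm],
        )
        res_b = cluster_heatmap(shuffled)
        # same set of merge heights regardless of input order
        assert np.allclose(
            np.sort(res_a.sample_linkage[:, 2]), np.sort(res_b.sample_linkage[:, 2])
        )

    def test_cohort_partitions_by_phenotype(self, cohort_matrix):
        from scipy.cluster.hierarchy import fcluster

        res = cluster_heatmap(cohort_matrix)
        cut = fcluster(res.sample_linkage, 2, criterion="maxclust")
        labels = (cohort_matrix.groups == "cpdm").astype(int).to_numpy()
        agreement = max((cut - 1 == labels).mean(), (2 - cut == labels).mean())
        assert agreement == 1.0


class TestAggregateProfiles:
    def test_shares_sum_to_one_per_scheme_and_phenotype(self, cohort_matrix, method_pos):
        attributions = attribute_method(method_pos)
        for agg in aggregate_profiles(cohort_matrix, attributions):
            for group, chunk in agg.table.groupby("group"):
                assert chunk["share"].sum() == pytest.approx(1.0)

    def test_pure_single_base_matrix(self, method_pos):
        attributions = attribute_method(method_pos)
        cer_s = [t for t, r in attributions.items() if r.class_call == "Cer[S]"]
        others = [t for t, r in attributions.items() if r.class_call in ("Cer[DS]", "Cer[P]")]
        cols = cer_s + others
        X = np.zeros((4, len(cols)))
        X[:, : len(cer_s)] = 1.0 / len(cer_s)
        matrix = FeatureMatrix(
            pd.DataFrame(X, index=[f"s{i}" for i in range(4)], columns=cols),
            pd.Series(["WT", "WT", "cpdm", "cpdm"], index=[f"s{i}" for i in range(4)]),
            pd.Series(["testing"] * 4, index=[f"s{i}" for i in range(4)]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aggs = {a.scheme: a for a in aggregate_profiles(matrix, attributions)}
        base = aggs["ceramide_base"].table.set_index(["category", "group"])["share"]
        assert base[("Cer[S]", "WT")] == pytest.approx(1.0)
        assert base[("Cer[DS]", "WT")] == pytest.approx(0.0)
        assert base[("Cer[P]", "WT")] == pytest.approx(0.0)

    def test_empty_scheme_warns_and_is_omitted(self, cohort_matrix_neg, method_neg):
        attributions = attribute_method(method_neg)  # FFA only
        with pytest.warns(UserWarning, match="omitted"):
            aggs = aggregate_profiles(cohort_matrix_neg, attributions)
        schemes = {a.scheme for a in aggs}
        assert "ceramide_base" not in schemes
        assert {"ffa_saturation", "ffa_chain_length"} <= schemes
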