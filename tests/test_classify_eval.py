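import numpy as np
import pytest
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin

import kddc
from kddc.classify_eval import (
    FAMILY_ORDER,
    ClassifierGrid,
    EvalReport,
    SplitConfig,
    best_model_table,
    build_pipeline,
    class_scores,
    default_grid,
    derive_seed,
    evaluate_dataset,
    grid_search_fit,
    macro_auc,
    permutation_pvalue,
    shared_kmer_analysis,
    stratified_split,
    top_kmers,
)
from kddc.feature_select import SelectionConfig

from conftest import auc_concordance_oracle


class TestStratifiedSplit:
    def test_four_to_one_balanced(self):
        labels = np.repeat([0, 1, 2], 33)[:99]
        tr, te = stratified_split(labels, SplitConfig(seed=1))
        assert len(tr) + len(te) == 99
        assert len(te) == 20  # 0.2 of 99, rounded
        for c in (0, 1, 2):
            assert abs((labels[te] == c).sum() - len(te) / 3) <= 1

    def test_deterministic_and_partition(self):
        labels = np.repeat([0, 1], 20)
        a = stratified_split(labels, SplitConfig(seed=5))
        b = stratified_split(labels, SplitConfig(seed=5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert set(a[0]) | set(a[1]) == set(range(40))
        assert set(a[0]) & set(a[1]) == set()

    def test_singleton_class_error(self):
        with pytest.raises(ValueError, match="single row"):
            stratified_split(np.array([0, 0, 0, 1]), SplitConfig(seed=0))

    def test_train_fraction_validated(self):
        with pytest.raises(ValueError):
            SplitConfig(train_fraction=1.0)


class TestMacroAuc:
    def test_perfect_ranking(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[labels] * 0.8 + 0.1
        macro, per_class = macro_auc(scores, labels)
        assert macro == 1.0
        assert all(v == 1.0 for v in per_class.values())

    def test_binary_concordant_pair_example(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.1}: all 4 pairs concordant
        scores_pos = np.array([0.9, 0.8, 0.7, 0.1])
        scores = np.column_stack([1 - scores_pos, scores_pos])
        labels = np.array([1, 1, 0, 0])
        macro, per_class = macro_auc(scores, labels)
        assert per_class[1] == 1.0
        assert auc_concordance_oracle([0.9, 0.8], [0.7, 0.1]) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_concordance_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]  # both classes present
        s = rng.random(40)
        scores = np.column_stack([1 - s, s])
        _, per_class = macro_auc(scores, labels)
        expected = auc_concordance_oracle(s[labels == 1], s[labels == 0])
        assert per_class[1] == pytest.approx(expected, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 3, size=2000)
        scores = rng.dirichlet(np.ones(3), size=2000)
        macro, _ = macro_auc(scores, labels)
        assert macro == pytest.approx(0.5, abs=0.05)

    def test_macro_is_exact_mean_of_per_class(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=60)
        scores = rng.dirichlet(np.ones(3), size=60)
        macro, per_class = macro_auc(scores, labels)
        assert macro == np.mean(list(per_class.values()))

    def test_absent_class_excluded_with_warning(self, caplog):
        labels = np.array([0, 0, 1, 1])
        scores = np.column_stack([np.ones(4), np.zeros(4), np.zeros(4)])
        with caplog.at_level("WARNING"):
            macro, per_class = macro_auc(scores, labels, classes=[0, 1, 2])
        assert 2 not in per_class
        assert "absent" in caplog.text


@pytest.fixture(scope="module")
def separable_matrix(small_benchmark):
    (records, _), _ = small_benchmark
    return kddc.build_count_matrix(records, ks={3})


class TestGridSearchFit:
    def test_single_point_grid_identity(self, separable_matrix):
        m = separable_matrix
        spec = ClassifierGrid(family="LR", grid={"C": [2.0]}, cv_folds=3)
        gs = grid_search_fit(m.counts, m.labels, spec, seed=0,
                            selection=SelectionConfig())
        assert gs.best_params_ == {"clf__C": 2.0}

    def test_dominated_point_rejected(self, separable_matrix):
        # with k = fold size, KNN scores are the constant class prior
        # (AUC exactly 0.5 on every fold); k=3 separates the planted motifs
        m = separable_matrix
        spec = ClassifierGrid(family="KNN", grid={"n_neighbors": [3, 30]}, cv_folds=3)
        gs = grid_search_fit(m.counts, m.labels, spec, seed=0,
                            selection=SelectionConfig())
        assert gs.best_params_ == {"clf__n_neighbors": 3}
        scores = gs.cv_results_["mean_test_score"]
        assert scores.max() > 0.5 and scores.min() == pytest.approx(0.5)

    def test_rf_separates_planted_motifs(self, separable_matrix):
        m = separable_matrix
        gs = grid_search_fit(m.counts, m.labels, default_grid("RF", cv_folds=3),
                            seed=0, selection=SelectionConfig())
        assert gs.best_score_ >= 0.95

    def test_infeasible_folds_error(self):
        X = sparse.csr_matrix(np.ones((4, 3)))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="folds"):
            grid_search_fit(X, y, default_grid("LR"), seed=0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierGrid(family="GBM")


class _RowSumScorer(BaseEstimator, ClassifierMixin):
    """Deterministic stub: scores rows by (signed) row sum, ignores training."""

    def __init__(self, sign=1.0):
        self.sign = sign

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        s = self.sign * np.asarray(X.sum(axis=1)).ravel()
        s = (s - s.min()) / (s.max() - s.min() + 1e-12)
        return np.column_stack([1 - s, s])


@pytest.fixture(scope="module")
def rowsum_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(100, 5)) + np.arange(100)[:, None]
    y = (np.arange(100) >= 50).astype(int)  # exactly the row-sum order
    return sparse.csr_matrix(X), y


class TestPermutationPvalue:
    def test_observed_beats_all_permutations(self, rowsum_data):
        X, y = rowsum_data
        p = permutation_pvalue(_RowSumScorer(sign=1.0), X, y, n_perm=99, seed=0)
        assert p == pytest.approx(0.01)

    def test_floor_when_observed_is_worst(self, rowsum_data):
        X, y = rowsum_data
        p = permutation_pvalue(_RowSumScorer(sign=-1.0), X, y, n_perm=19, seed=0)
        assert p == pytest.approx(1.0)

    def test_minimum_permutations_enforced(self, rowsum_data):
        X, y = rowsum_data
        with pytest.raises(ValueError, match="19"):
            permutation_pvalue(_RowSumScorer(), X, y, n_perm=10, seed=0)


class TestBestModelTable:
    @staticmethod
    def report(dataset, family, auc, p):
        return EvalReport(
            dataset_name=dataset, family=family, macro_auc=auc,
            per_class_auc={0: auc, 1: auc, 2: auc}, p_value=p, best_params={},
        )

    def test_significance_gate(self):
        reports = [
            self.report("kmer2", "RF", 0.90, 0.01),
            self.report("kmer2", "XGB", 0.95, 0.20),
        ]
        table = best_model_table(reports, alpha=0.05)
        assert table.loc[0, "Model"] == "RF"
        assert table.loc[0, "significant"]

    def test_tie_breaks_by_family_order(self):
        reports = [
            self.report("kmer2", "RF", 0.9, 0.01),
            self.report("kmer2", "LR", 0.9, 0.01),
        ]
        table = best_model_table(reports)
        assert table.loc[0, "Model"] == "LR"

    def test_single_report_identity(self):
        table = best_model_table([self.report("kmer3", "MLP", 0.8, 0.02)])
        assert table.loc[0, "Model"] == "MLP" and table.loc[0, "best"]

    def test_no_significant_model_flagged(self):
        table = best_model_table([self.report("kmer2", "RF", 0.9, 0.5)])
        assert not table.loc[0, "significant"]
        assert table.loc[0, "macro_AUC"] == 0.9

    def test_table_columns_match_report_shape(self):
        table = best_model_table([self.report("kmer2", "RF", 0.9, 0.01)])
        assert list(table.columns)[:7] == [
            "kmer", "Model", "macro_AUC", "p-value", "H", "M", "S"
        ]


class TestSharedKmers:
    def test_intersection(self):
        reports = shared_kmer_analysis(
            {"sub1": [("A", 3.0), ("B", 2.0), ("C", 1.0)],
             "sub2": [("B", 5.0), ("C", 4.0), ("D", 3.0)]},
            top_n=3,
        )
        (rep,) = reports
        assert rep.subset_pair == ("sub1", "sub2")
        assert [k for k, _, _ in rep.shared] == ["B", "C"]

    def test_disjoint_sets_empty(self):
        (rep,) = shared_kmer_analysis(
            {"a": [("AA", 1.0)], "b": [("CC", 1.0)]}, top_n=5
        )
        assert rep.shared == []

    def test_needs_two_subsets(self):
        with pytest.raises(ValueError):
            shared_kmer_analysis({"a": [("AA", 1.0)]})

    def test_planted_motif_shared_between_subsets(self):
        config = kddc.SimConfig(
            n_samples_per_class=10, cells_per_sample=60,
            subsets=("subA", "subB"), seed=2,
        )
        records, truth = kddc.generate_repertoire(config)
        tops = {}
        for subset in config.subsets:
            m = kddc.build_count_matrix(records, ks={3}, subset=subset)
            result = kddc.select_features(m)
            f = np.where(np.isfinite(result.f_stat), result.f_stat, 0.0)
            order = np.argsort(-f)[:20]
            tops[subset] = [(m.feature_space.columns[i], float(f[i])) for i in order]
        (rep,) = shared_kmer_analysis(tops, top_n=20)
        shared_names = {k for k, _, _ in rep.shared}
        assert set(truth.planted_motifs()) <= shared_names


class TestEvaluateAndImportance:
    def test_evaluate_reports_and_reproducibility(self, separable_matrix):
        m = separable_matrix
        kwargs = dict(families=["LR"], n_perm=None, seed=42, cv_folds=3)
        a = evaluate_dataset(m, "kmer3", **kwargs)
        b = evaluate_dataset(m, "kmer3", **kwargs)
        assert a[0].to_dict() == b[0].to_dict()
        assert 0.0 <= a[0].macro_auc <= 1.0
        assert a[0].macro_auc == pytest.approx(
            np.mean(list(a[0].per_class_auc.values()))
        )

    def test_pre_split_selection_leaks_on_null_data(self):
        """Selecting features on the full dataset before splitting inflates
        held-out AUC on label-permuted data; the default mode does not."""
        aucs = {"pre-split": [], "split-safe": []}
        for s in range(5):
            records, _ = kddc.generate_repertoire(
                kddc.SimConfig(n_samples_per_class=20, cells_per_sample=50,
                               seed=700 + s)
            )
            m = kddc.build_count_matrix(records, ks={2})
            rng = np.random.default_rng(800 + s)
            m.labels = rng.permutation(m.labels)
            for mode in aucs:
                (report,) = evaluate_dataset(
                    m, "kmer2", families=["LR"], n_perm=None, seed=s,
                    cv_folds=3, selection_mode=mode,
                )
                aucs[mode].append(report.macro_auc)
        assert np.mean(aucs["pre-split"]) > np.mean(aucs["split-safe"]) + 0.15
        assert np.mean(aucs["split-safe"]) == pytest.approx(0.5, abs=0.12)

    def test_top_kmers_recovers_planted_motifs(self, separable_matrix, small_benchmark):
        (_, truth), _ = small_benchmark
        m = separable_matrix
        gs = grid_search_fit(m.counts, m.labels, default_grid("RF", cv_folds=3),
                            seed=1, selection=SelectionConfig())
        top = top_kmers(gs.best_estimator_, m.feature_space, top_n=20)
        names = {k for k, _ in top}
        planted = set(truth.planted_motifs())
        assert len(planted & names) >= 4  # most of the six 3-mers surface


def test_derive_seed_stable_and_bounded():
    assert derive_seed(7, "a", "b") == derive_seed(7, "a", "b")
    assert derive_seed(7, "a") != derive_seed(7, "b")
    assert 0 <= derive_seed(2**20, "x") < 2**31


def test_class_scores_svm_decision_values(separable_matrix):
    m = separable_matrix
    pipe = build_pipeline("SVM", seed=0, selection=SelectionConfig())
    tr, te = stratified_split(m.labels, SplitConfig(seed=0))
    pipe.fit(m.counts[tr], m.labels[tr])
    scores = class_scores(pipe, m.counts[te])
    assert scores.shape == (len(te), 3)
    assert np.allclose(scores.sum(axis=1), 1.0)
    assert (scores >= 0).all()
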