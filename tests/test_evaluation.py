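import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import taphunter as th
from taphunter.errors import ValidationError
from taphunter.evaluation import ConfusionCounts, counts_from_predictions

from conftest import brute_force_auc


class TestConfusionMetrics:
    def test_direct_arithmetic(self):
        se, sp, acc = th.confusion_metrics(ConfusionCounts(TP=3, FN=1, TN=4, FP=0))
        assert (se, sp, acc) == (0.75, 1.0, 0.875)

    def test_all_correct(self):
        se, sp, acc = th.confusion_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (se, sp, acc) == (1.0, 1.0, 1.0)

    def test_undefined_se_flagged_as_nan(self):
        se, sp, acc = th.confusion_metrics(ConfusionCounts(TP=0, FN=0, TN=4, FP=1))
        assert math.isnan(se) and sp == 0.8

    def test_counts_from_predictions(self):
        c = counts_from_predictions([1, 1, -1, -1], [1, -1, -1, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        r = th.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert r.auc == 1.0
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)

    def test_single_tie_is_half(self):
        assert th.roc_auc([0.5, 0.5], [1, -1]).auc == 0.5

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=2000)
        labels = np.array([1] * 1000 + [-1] * 1000)
        assert th.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            th.roc_auc([0.1, 0.2], [1, 1])

    def test_roc_points_monotone(self, strong_dataset, anchor_config):
        X, y = th.encode_set(strong_dataset, anchor_config)
        clf = th.TapBinderClassifier().fit(X, y)
        r = th.roc_auc(clf.decision_function(X), y)
        fpr = [p[0] for p in r.points]
        tpr = [p[1] for p in r.points]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    @given(
        n_pos=st.integers(1, 25),
        n_neg=st.integers(1, 25),
        seed=st.integers(0, 10_000),
        ties=st.booleans(),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_all_pairs_oracle(self, n_pos, n_neg, seed, ties):
        rng = np.random.default_rng(seed)
        n = n_pos + n_neg
        scores = rng.integers(0, 6, size=n).astype(float) if ties else rng.normal(size=n)
        labels = np.array([1] * n_pos + [-1] * n_neg)
        assert th.roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.array([1] * 20 + [-1] * 20)
        a = th.roc_auc(scores, labels).auc
        b = th.roc_auc(np.exp(scores / 3) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestKfoldSplit:
    def test_stratified_sizes_on_study_split(self, null_dataset):
        folds = th.kfold_split(null_dataset, 5, seed=0)
        y = np.array(null_dataset.labels)
        for _, te in folds:
            assert len(te) == 74
            n_pos = int(np.sum(y[te] == 1))
            assert n_pos in (55, 56)
            assert len(te) - n_pos in (18, 19)

    def test_small_balanced(self):
        recs = [(th.Peptide(f"ACDEFGHI{aa}"), 1) for aa in "KRWYF"]
        recs += [(th.Peptide(f"ACDEFGHV{aa}"), -1) for aa in "KRWYF"]
        pset = th.LabeledPeptideSet(recs)
        folds = th.kfold_split(pset, 5, seed=1)
        y = np.array(pset.labels)
        for _, te in folds:
            assert len(te) == 2
            assert set(y[te]) == {-1, 1}

    def test_class_smaller_than_k(self):
        recs = [(th.Peptide(f"ACDEFGHI{aa}"), 1) for aa in "KRWY"]
        recs += [(th.Peptide(f"ACDEFGHV{aa}"), -1) for aa in "KRWYF"]
        with pytest.raises(ValidationError):
            th.kfold_split(th.LabeledPeptideSet(recs), 5, seed=1)

    def test_disjoint_cover_deterministic(self, strong_dataset):
        a = th.kfold_split(strong_dataset, 5, seed=9)
        b = th.kfold_split(strong_dataset, 5, seed=9)
        seen = np.concatenate([te for _, te in a])
        assert sorted(seen) == list(range(len(strong_dataset)))
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb) and np.array_equal(tra, trb)
            assert not set(tea) & set(tra)


class TestCrossValidate:
    def test_fold_list_lengths_and_ranges(self, strong_dataset, anchor_config):
        cv = th.cross_validate(strong_dataset, anchor_config, k=5, seed=3)
        assert len(cv.fold_auc) == 5 and len(cv.fold_acc) == 5
        assert 0 <= cv.mean_auc <= 1 and 0 <= cv.pooled_acc <= 1

    def test_null_auc_near_chance(self, null_dataset, anchor_config):
        cv = th.cross_validate(null_dataset, anchor_config, k=5, seed=3)
        assert 0.4 <= cv.mean_auc <= 0.6

    def test_strong_motif_auc_high(self, strong_dataset, anchor_config):
        cv = th.cross_validate(strong_dataset, anchor_config, k=5, seed=3)
        assert cv.mean_auc >= 0.85


class TestBootstrapCompare:
    def test_self_comparison(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=60)
        labels = np.array([1] * 30 + [-1] * 30)
        res = th.bootstrap_compare(scores, scores, labels, B=200, seed=4)
        assert res.mean_delta == 0.0
        assert res.p_value == 1.0
        assert len(res.delta_distribution) == 200

    def test_perfect_vs_shuffled_significant(self):
        rng = np.random.default_rng(8)
        labels = np.array([1] * 50 + [-1] * 50)
        perfect = labels.astype(float) + rng.normal(0, 0.05, 100)
        shuffled = rng.permutation(perfect)
        res = th.bootstrap_compare(perfect, shuffled, labels, B=1000, seed=4)
        assert res.p_value < 0.01
        assert res.mean_auc_a > res.mean_auc_b

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(size=40)
        labels = np.array([1] * 20 + [-1] * 20)
        r1 = th.bootstrap_compare(a, b, labels, B=100, seed=77)
        r2 = th.bootstrap_compare(a, b, labels, B=100, seed=77)
        assert r1.delta_distribution == r2.delta_distribution
        assert r1.p_value == r2.p_value

    def test_ci_shrinks_with_test_size(self):
        """Percentile CI half-width decreases as the test set doubles."""
        rng = np.random.default_rng(5)

        def halfwidth(n):
            labels = np.array([1] * n + [-1] * n)
            scores = labels + rng.normal(0, 1.2, 2 * n)
            widths = []
            for seed in range(5):
                r = th.bootstrap_compare(
                    scores, rng.permutation(scores), labels, B=300, seed=seed
                )
                widths.append(r.ci95_a[1] - r.ci95_a[0])
            return np.mean(widths)

        assert halfwidth(200) < halfwidth(50)

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValidationError):
            th.bootstrap_compare([1.0], [1.0, 2.0], [1, -1], B=10, seed=0)
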