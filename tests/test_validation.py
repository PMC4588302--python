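import numpy as np
import pytest

from braingpc import (
    Group,
    PredictionResult,
    Sex,
    SubjectRecord,
    accuracy,
    auc,
    downsample_to_match,
    loocv,
    match_pairs,
    permutation_test,
    ploocv,
    transfer_predict,
)
from braingpc.validation import FoldScaler
from braingpc.gpc import fit_gpc, predict_proba

from conftest import contrast_arrays
from oracles import auc_pair_count


def _rec(sid, age, sex=Sex.M, group=Group.HC):
    return SubjectRecord(sid, group, age, sex)


class TestMatchPairs:
    def test_unique_optimum(self):
        a = [_rec("a1", 30), _rec("a2", 40)]
        b = [_rec("b1", 31, group=Group.SCZ), _rec("b2", 39, group=Group.SCZ)]
        m = match_pairs(a, b)
        assert set(m.pairs) == {(0, 0), (1, 1)}
        assert m.mean_abs_age_gap == pytest.approx(1.0)

    def test_identical_ages_zero_gap(self):
        a = [_rec("a1", 30), _rec("a2", 45)]
        b = [_rec("b1", 30, group=Group.SCZ), _rec("b2", 45, group=Group.SCZ)]
        assert match_pairs(a, b).mean_abs_age_gap == 0.0

    def test_infeasible_sex_counts(self):
        a = [_rec("a1", 30, Sex.F), _rec("a2", 40, Sex.F)]
        b = [_rec(f"b{i}", 30 + i, Sex.F, Group.SCZ) for i in range(3)]
        with pytest.raises(ValueError, match="sex"):
            match_pairs(a, b)

    def test_pairs_share_sex_and_indices_unique(self):
        rng = np.random.default_rng(0)
        a = [
            _rec(f"a{i}", float(rng.uniform(20, 60)), Sex.M if i % 2 else Sex.F)
            for i in range(12)
        ]
        b = [
            _rec(f"b{i}", float(rng.uniform(20, 60)),
                 Sex.M if i % 2 else Sex.F, Group.SCZ)
            for i in range(10)
        ]
        m = match_pairs(a, b)
        assert len(m.pairs) == 10
        ai = [i for i, _ in m.pairs]
        bi = [j for _, j in m.pairs]
        assert len(set(ai)) == len(ai) and sorted(bi) == list(range(10))
        for i, j in m.pairs:
            assert a[i].sex is b[j].sex


class TestDownsample:
    def test_keep_all_is_identity(self):
        g = [_rec(f"g{i}", 30 + i) for i in range(5)]
        ref = [_rec("r0", 33, group=Group.T_PLUS)]
        assert downsample_to_match(g, ref, 5) == (0, 1, 2, 3, 4)

    def test_all_female_reference_keeps_females(self):
        g = [_rec(f"g{i}", 30 + i, Sex.F if i < 4 else Sex.M) for i in range(8)]
        ref = [_rec(f"r{i}", 31 + i, Sex.F, Group.T_PLUS) for i in range(3)]
        kept = downsample_to_match(g, ref, 3)
        assert all(g[i].sex is Sex.F for i in kept)

    def test_n_keep_too_large(self):
        g = [_rec("g0", 30)]
        with pytest.raises(ValueError):
            downsample_to_match(g, g, 2)

    def test_kept_subset_age_closer_to_reference(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = [
                _rec(f"g{i}", float(rng.uniform(20, 70)),
                     Sex.M if i % 2 else Sex.F)
                for i in range(20)
            ]
            ref = [
                _rec(f"r{i}", float(rng.uniform(35, 50)),
                     Sex.M if i % 2 else Sex.F, Group.T_PLUS)
                for i in range(8)
            ]
            kept = downsample_to_match(g, ref, 10)
            ref_mean = np.mean([r.age for r in ref])
            full_gap = abs(np.mean([r.age for r in g]) - ref_mean)
            kept_gap = abs(np.mean([g[i].age for i in kept]) - ref_mean)
            hits += kept_gap <= full_gap + 1e-9
        assert hits >= 18


def _separable(n_pairs=2, gap=10.0):
    X = np.vstack([
        np.full((n_pairs, 2), -gap) + np.arange(n_pairs)[:, None] * 0.1,
        np.full((n_pairs, 2), gap) + np.arange(n_pairs)[:, None] * 0.1,
    ])
    y = np.array([-1.0] * n_pairs + [1.0] * n_pairs)
    pairs = [(k, n_pairs + k) for k in range(n_pairs)]
    return X, y, pairs


class TestCrossValidation:
    def test_ploocv_separable_perfect(self):
        X, y, pairs = _separable()
        res = ploocv(X, y, pairs)
        assert accuracy(res) == 100.0
        assert res.p_positive.shape == (4,)

    def test_ploocv_requires_full_cover(self):
        X, y, _ = _separable()
        with pytest.raises(ValueError, match="cover"):
            ploocv(X, y, [(0, 2)])

    def test_loocv_separable_perfect(self):
        X, y, _ = _separable(3)
        assert accuracy(loocv(X, y)) == 100.0

    def test_fold_preprocessing_excludes_held_out_pair(self):
        # fold-k prediction must equal a manual fit on the fold's training
        # rows only; making the held-out pair extreme must not perturb the
        # training-fold statistics
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        y = np.array([-1.0] * 4 + [1.0] * 4)
        pairs = [(k, 4 + k) for k in range(4)]
        X_extreme = X.copy()
        X_extreme[[0, 4]] *= 1e6  # held-out pair of fold 0
        res = ploocv(X_extreme, y, pairs)
        train_idx = [1, 2, 3, 5, 6, 7]
        scaler = FoldScaler(X[train_idx])
        np.testing.assert_array_equal(
            scaler.mean_, X_extreme[train_idx].mean(axis=0)
        )
        model = fit_gpc(scaler.transform(X[train_idx]), y[train_idx])
        manual = predict_proba(model, scaler.transform(X_extreme[[0, 4]]))
        np.testing.assert_allclose(res.p_positive[[0, 4]], manual, atol=1e-12)

    def test_ploocv_and_loocv_agree_on_balanced_data(self, strong_cohort):
        X, y, _ = contrast_arrays(strong_cohort, Group.HC, Group.SCZ)
        n = len(y) // 2
        pairs = [(k, n + k) for k in range(n)]
        acc_p = accuracy(ploocv(X, y, pairs))
        acc_l = accuracy(loocv(X, y))
        assert abs(acc_p - acc_l) <= 10.0

    def test_single_class_training_fold_rejected(self):
        X = np.array([[-1.0], [1.0], [2.0], [3.0]])
        y = np.array([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="single class"):
            loocv(X[:2], y[:2])


class TestTransfer:
    def test_duplicated_training_row_on_correct_side(self):
        rng = np.random.default_rng(2)
        X = np.vstack([
            rng.normal(-3.0, 0.5, size=(5, 3)),
            rng.normal(3.0, 0.5, size=(5, 3)),
        ])
        y = np.array([-1.0] * 5 + [1.0] * 5)
        res = transfer_predict(X, y, X[[0, 9]])
        assert res.p_positive[0] < 0.5 < res.p_positive[1]

    def test_row_permutation_permutes_outputs(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        y = np.array([-1.0, 1.0] * 4)
        Xt = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        p1 = transfer_predict(X, y, Xt).p_positive
        p2 = transfer_predict(X, y, Xt[perm]).p_positive
        np.testing.assert_array_equal(p1[perm], p2)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            transfer_predict(
                np.zeros((4, 3)), np.array([-1.0, 1.0, -1.0, 1.0]),
                np.zeros((2, 4)),
            )

    def test_carriers_recovered_by_case_control_model(self, strong_cohort):
        # carriers share the cases' thinning pattern, noncarriers do not:
        # the case-control model should sort them accordingly
        X, y, _ = contrast_arrays(strong_cohort, Group.HC, Group.SCZ)
        Xt_minus, _, _ = contrast_arrays(
            strong_cohort, Group.T_MINUS, Group.T_MINUS
        )
        Xt_plus, _, _ = contrast_arrays(strong_cohort, Group.T_PLUS, Group.T_PLUS)
        res_minus = transfer_predict(X, y, Xt_minus)
        res_plus = transfer_predict(X, y, Xt_plus)
        assert np.mean(res_minus.p_positive < 0.5) > 0.5
        assert np.mean(res_plus.p_positive >= 0.5) > 0.5


class TestMetrics:
    def test_perfect_predictions(self):
        res = PredictionResult(
            subject_ids=("a", "b", "c", "d"),
            p_positive=np.array([0.1, 0.2, 0.8, 0.9]),
            true_label=np.array([-1.0, -1.0, 1.0, 1.0]),
        )
        assert accuracy(res) == 100.0
        assert auc(res) == 1.0

    def test_all_equal_probabilities_auc_half(self):
        res = PredictionResult(
            subject_ids=("a", "b", "c", "d"),
            p_positive=np.full(4, 0.5) - 1e-12,
            true_label=np.array([-1.0, 1.0, -1.0, 1.0]),
        )
        assert auc(res) == pytest.approx(0.5)

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            p = rng.choice(np.linspace(0.05, 0.95, 7), size=n)
            truth = rng.choice([-1.0, 1.0], size=n)
            if np.unique(truth).size < 2:
                truth[0] = -truth[0]
            res = PredictionResult(
                subject_ids=tuple(map(str, range(n))),
                p_positive=p, true_label=truth,
            )
            assert auc(res) == pytest.approx(auc_pair_count(p, truth), abs=1e-12)

    def test_order_invariance(self, rng):
        n = 12
        p = rng.uniform(0.05, 0.95, n)
        truth = np.array([-1.0, 1.0] * 6)
        res = PredictionResult(tuple(map(str, range(n))), p, truth)
        perm = rng.permutation(n)
        shuffled = PredictionResult(
            tuple(map(str, perm)), p[perm], truth[perm]
        )
        assert accuracy(res) == accuracy(shuffled)
        assert auc(res) == pytest.approx(auc(shuffled), abs=1e-12)

    def test_single_class_truth_auc_undefined(self):
        res = PredictionResult(
            ("a", "b"), np.array([0.3, 0.7]), np.array([1.0, 1.0])
        )
        with pytest.raises(ValueError):
            auc(res)


class TestPermutationTest:
    def test_observed_below_all_nulls_gives_p_one(self):
        def proc(rng):
            return 40.0 if rng is None else 60.0

        res = permutation_test(proc, n_perm=20, seed=0)
        assert res.p_value == 1.0

    def test_observed_above_all_nulls_gives_p_zero(self):
        def proc(rng):
            return 95.0 if rng is None else 50.0

        res = permutation_test(proc, n_perm=20, seed=0)
        assert res.p_value == 0.0

    def test_add_one_convention(self):
        def proc(rng):
            return 95.0 if rng is None else 50.0

        res = permutation_test(proc, n_perm=19, seed=0, add_one=True)
        assert res.p_value == pytest.approx(1 / 20)

    def test_p_is_exact_count_fraction(self):
        def proc(rng):
            return 50.0 if rng is None else float(rng.integers(40, 61))

        res = permutation_test(proc, n_perm=50, seed=3)
        count = int(np.sum(res.null_accuracies >= res.observed_accuracy))
        assert res.p_value == count / 50

    def test_reproducible_given_seed(self):
        def proc(rng):
            return 50.0 if rng is None else float(rng.uniform(0, 100))

        r1 = permutation_test(proc, n_perm=10, seed=7)
        r2 = permutation_test(proc, n_perm=10, seed=7)
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)

    def test_nonfinite_procedure_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            permutation_test(lambda rng: np.nan, n_perm=2, seed=0)
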