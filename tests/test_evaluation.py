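"""Evaluation protocol: CV plans, metrics, AUC, t-test, RSD."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwfdr import evaluation as ev
from uwfdr.errors import DegenerateTestError, ValidationError


class TestMakeCvPlan:
    def test_stratified_counts_small(self):
        labels = [1] * 5 + [0] * 15
        runs = ev.make_cv_plan(labels, ev.CVPlan(n_runs=2, n_folds=4, seed=0))
        for folds in runs:
            pos_counts = sorted(int(np.sum(np.array(labels)[f.test_idx])) for f in folds)
            assert pos_counts == [1, 1, 1, 2]
            all_test = np.concatenate([f.test_idx for f in folds])
            assert sorted(all_test) == list(range(20))

    def test_balanced_exact_division(self):
        labels = [0] * 50 + [1] * 50
        runs = ev.make_cv_plan(labels, ev.CVPlan(n_runs=1, n_folds=10, seed=1))
        for f in runs[0]:
            y = np.array(labels)[f.test_idx]
            assert (y == 1).sum() == 5 and (y == 0).sum() == 5

    def test_inner_holdout_is_stratified_tenth(self):
        labels = [0] * 100 + [1] * 100
        runs = ev.make_cv_plan(labels, ev.CVPlan(n_runs=1, n_folds=10, seed=2))
        f = runs[0][0]
        assert len(f.val_idx) == pytest.approx(len(f.train_idx) / 9, abs=2)
        assert set(f.val_idx).isdisjoint(f.test_idx)
        assert set(f.train_idx).isdisjoint(f.val_idx)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValidationError):
            ev.make_cv_plan([1] * 9 + [0] * 100, ev.CVPlan(n_folds=10))

    def test_reproducible(self):
        labels = [0] * 30 + [1] * 30
        a = ev.make_cv_plan(labels, ev.CVPlan(n_runs=2, n_folds=3, seed=7))
        b = ev.make_cv_plan(labels, ev.CVPlan(n_runs=2, n_folds=3, seed=7))
        for fa, fb in zip(sum(a, []), sum(b, [])):
            assert np.array_equal(fa.test_idx, fb.test_idx)
            assert np.array_equal(fa.val_idx, fb.val_idx)


class TestComputeMetrics:
    def test_formulas(self):
        sens, spec, acc = ev.compute_metrics(ev.ConfusionCounts(tp=80, fn=20, tn=90, fp=10))
        assert (sens, spec, acc) == (0.80, 0.90, 0.85)

    def test_perfect(self):
        assert ev.compute_metrics(ev.ConfusionCounts(10, 0, 10, 0)) == (1.0, 1.0, 1.0)

    def test_degenerate_side(self):
        sens, spec, acc = ev.compute_metrics(ev.ConfusionCounts(tp=0, fn=10, tn=10, fp=0))
        assert (sens, spec, acc) == (0.0, 1.0, 0.5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            ev.compute_metrics(ev.ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


def brute_force_threshold(scores, labels):
    """Oracle: scan every threshold interval explicitly."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    uniq = np.unique(s)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    rows = []
    for thr in cands:
        pred = s >= thr
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        rows.append((abs(sens - spec), -(sens + spec), thr))
    return min(rows)[2]


class TestOperatingThreshold:
    def test_perfect_separation(self):
        scores = [0.9, 0.9, 0.1, 0.1]
        labels = [1, 1, 0, 0]
        thr = ev.pick_operating_threshold(scores, labels)
        sens, spec, _ = ev.compute_metrics(ev.confusion_at(scores, labels, thr))
        assert sens == spec == 1.0

    def test_worked_example_balance(self):
        scores = [0.9, 0.4, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        thr = ev.pick_operating_threshold(scores, labels)
        sens, spec, _ = ev.compute_metrics(ev.confusion_at(scores, labels, thr))
        assert sens == spec == 0.5

    def test_all_equal_scores_deterministic(self):
        thr1 = ev.pick_operating_threshold([0.5] * 6, [1, 1, 1, 0, 0, 0])
        thr2 = ev.pick_operating_threshold([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert thr1 == thr2

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ev.pick_operating_threshold([0.1, 0.9], [1, 1])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 10 ** 9))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 30)
        scores = np.round(rng.uniform(size=n), 2)
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            return
        assert ev.pick_operating_threshold(scores, labels) == pytest.approx(
            brute_force_threshold(scores, labels))


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeAuc:
    def test_worked_example(self):
        assert ev.compute_auc([0.9, 0.8, 0.85, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert ev.compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert ev.compute_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 10 ** 9))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 40)
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if labels.min() == labels.max():
            return
        assert ev.compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            ev.compute_auc([0.5, 0.6], [1, 1])


class TestPairedTTest:
    def test_hand_computed_example(self):
        t, p, h = ev.paired_t_test([2, 3, 4], [1, 1, 1])
        assert t == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-6)  # = 3.4641...

    def test_identical_inputs_degenerate(self):
        with pytest.raises(DegenerateTestError):
            ev.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_power_at_large_shift(self):
        rng = np.random.default_rng(42)
        b = rng.normal(0, 1, size=100)
        a = b + 1.0 + rng.normal(0, 0.1, size=100)
        t, p, h = ev.paired_t_test(a, b, alpha=0.001)
        assert h == 1 and t > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ev.paired_t_test([1, 2], [1, 2, 3])


class TestComputeRsd:
    def test_formula(self):
        rsds, avg = ev.compute_rsd([[9, 10, 11]])
        assert rsds[0] == pytest.approx(10.0)
        assert avg == pytest.approx(10.0)

    def test_constant_scores_zero(self):
        rsds, avg = ev.compute_rsd([[0.7, 0.7, 0.7]])
        assert rsds[0] == pytest.approx(0.0, abs=1e-9)
        assert avg == pytest.approx(0.0, abs=1e-9)

    def test_average_of_two_images(self):
        rsds, avg = ev.compute_rsd([[9, 10, 11], [8, 10, 12]])
        assert avg == pytest.approx((rsds[0] + rsds[1]) / 2)

    def test_zero_mean_excluded(self):
        rsds, avg = ev.compute_rsd([[0.0, 0.0], [9, 10, 11]])
        assert rsds[0] is None
        assert avg == pytest.approx(10.0)


class TestCompareScoredVariants:
    def _setup(self, shift=0.3, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * 20)
        folds = ev.make_cv_plan(labels, ev.CVPlan(n_runs=2, n_folds=4, seed=3))
        base = rng.uniform(size=(2, 40))
        good = np.clip(base + shift * labels[None, :], 0, 1)
        return labels, folds, base, good

    def test_better_variant_wins(self):
        labels, folds, base, good = self._setup()
        res = ev.compare_scored_variants(labels, good, base, folds)
        assert res.report_a.summary()["auc"][0] > res.report_b.summary()["auc"][0]

    def test_self_comparison_reports_no_difference(self):
        labels, folds, base, _ = self._setup()
        res = ev.compare_scored_variants(labels, base, base, folds)
        assert (res.t_tests["H"] == 0).all()

    def test_report_summary_recomputable(self):
        labels, folds, base, good = self._setup()
        res = ev.compare_scored_variants(labels, good, base, folds)
        table = res.report_a.table
        mean, sd = res.report_a.summary()["accuracy"]
        assert mean == pytest.approx(table["accuracy"].mean())
        assert sd == pytest.approx(table["accuracy"].std(ddof=1))

    def test_single_run_reduction(self):
        labels = np.array([0, 1] * 15)
        folds = ev.make_cv_plan(labels, ev.CVPlan(n_runs=1, n_folds=3, seed=1))
        rng = np.random.default_rng(5)
        a = np.clip(rng.uniform(size=(1, 30)) + 0.4 * labels, 0, 1)
        b = rng.uniform(size=(1, 30))
        res = ev.compare_scored_variants(labels, a, b, folds)
        assert len(res.report_a.table) == 3
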