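"""Metric protocol: confusion accounting, ROC construction, threshold
selection, bootstrap intervals, stratified splitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phantomqc import evaluate, qualify, rules, synth
from phantomqc.scores import Score

Z, H, F = Score.ZERO, Score.HALF, Score.FULL


class TestConfusion:
    def test_perfect_predictions(self):
        y = [Z, H, F, F, H, Z, F]
        rep = evaluate.confusion_metrics(y, y)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert np.trace(rep.matrix) == len(y)

    def test_hand_computed_twelve_sample_example(self):
        """Frozen against a hand-filled 3x3 table: rows (true) 0.0/0.5/
        1.0 with supports 4/4/4."""
        y_true = [Z, Z, Z, Z, H, H, H, H, F, F, F, F]
        y_pred = [Z, Z, H, F, Z, H, H, F, F, F, F, H]
        rep = evaluate.confusion_metrics(y_true, y_pred)
        assert rep.matrix.tolist() == [[2, 1, 1], [1, 2, 1], [0, 1, 3]]
        assert rep.accuracy == pytest.approx(7 / 12)
        assert rep.precision["0.0"] == pytest.approx(2 / 3)
        assert rep.recall["0.0"] == pytest.approx(2 / 4)
        assert rep.precision["0.5"] == pytest.approx(2 / 4)
        assert rep.recall["1.0"] == pytest.approx(3 / 4)
        # per-class F1: 4/7, 1/2, 2/3; macro average
        assert rep.macro_f1 == pytest.approx((4 / 7 + 1 / 2 + 2 / 3) / 3)

    def test_single_class_predictions_zero_division_flagged(self):
        rep = evaluate.confusion_metrics([Z, H, F], [F, F, F])
        assert rep.recall["1.0"] == 1.0
        assert rep.precision["0.0"] == 0.0
        assert rep.zero_division

    def test_empty_or_na_rejected(self):
        with pytest.raises(ValueError):
            evaluate.confusion_metrics([], [])
        with pytest.raises(ValueError):
            evaluate.confusion_metrics([Score.NA], [F])


def _auc_pairwise(scores, labels):
    """Mann-Whitney oracle: concordant-pair fraction with half credit
    for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total


class TestRoc:
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.booleans()
            ),
            min_size=4,
            max_size=20,
        ).filter(lambda v: any(l for _, l in v) and any(not l for _, l in v))
    )
    def test_auc_equals_pairwise_concordance(self, data):
        scores = np.array([s for s, _ in data])
        labels = np.array([l for _, l in data])
        got = evaluate._roc(scores, labels).auc
        assert got == pytest.approx(_auc_pairwise(scores, labels), abs=1e-9)

    def test_separated_scores_auc_one(self):
        probs = np.array([[0.9, 0], [0.8, 0], [0.1, 0], [0.2, 0]])
        truths = [F, H, Z, Z]
        assert evaluate.roc_existence(probs, truths).auc == 1.0

    def test_truth_independent_predictions_auc_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        probs = np.column_stack([rng.random(n), rng.random(n)])
        truths = [F if rng.random() < 0.7 else Z for _ in range(n)]
        assert evaluate.roc_existence(probs, truths).auc == pytest.approx(
            0.5, abs=0.03
        )

    def test_abnormality_excludes_zero_scored(self):
        rng = np.random.default_rng(1)
        probs = np.column_stack([rng.random(40), rng.random(40)])
        truths = [H if i % 3 == 0 else F for i in range(40)]
        base = evaluate.roc_abnormality(probs, truths)
        extra_p = np.vstack([probs, rng.random((15, 2))])
        extra_t = truths + [Z] * 15
        aug = evaluate.roc_abnormality(extra_p, extra_t)
        np.testing.assert_array_equal(base.fpr, aug.fpr)
        np.testing.assert_array_equal(base.tpr, aug.tpr)

    def test_all_zero_truths_rejected(self):
        probs = np.array([[0.5, 0.5]] * 4)
        with pytest.raises(ValueError):
            evaluate.roc_abnormality(probs, [Z, Z, Z, Z])


class TestThresholds:
    def test_eight_point_example_matches_exhaustive_scan(self):
        p_ex = np.array([0.1, 0.2, 0.35, 0.4, 0.55, 0.6, 0.8, 0.9])
        exist = np.array([False, False, True, False, True, True, True, True])
        best_f1, best_t = -1.0, None
        for t in sorted(set(p_ex)):
            pred = p_ex >= t
            tp = np.sum(pred & exist)
            fp = np.sum(pred & ~exist)
            fn = np.sum(~pred & exist)
            f1 = 2 * tp / (2 * tp + fp + fn)
            if f1 > best_f1 + 1e-12:
                best_f1, best_t = f1, t
        got = evaluate._best_f1_threshold(p_ex, exist)
        assert got == best_t

    def test_perfectly_separated_returns_smallest_positive_score(self):
        p = np.array([0.1, 0.2, 0.7, 0.9])
        y = np.array([False, False, True, True])
        # every threshold in (0.2, 0.7] gives F1=1; smallest candidate wins
        assert evaluate._best_f1_threshold(p, y) == 0.7

    def test_truth_independent_matches_all_positive_baseline(self):
        rng = np.random.default_rng(2)
        n = 400
        p = rng.random(n)
        y = rng.random(n) < 0.6
        t = evaluate._best_f1_threshold(p, y)
        pred = p >= t
        tp = np.sum(pred & y)
        f1 = 2 * tp / (2 * tp + np.sum(pred & ~y) + np.sum(~pred & y))
        pi = y.mean()
        baseline = 2 * pi / (1 + pi)  # predict everything positive
        assert f1 >= baseline - 1e-9
        assert f1 == pytest.approx(baseline, abs=0.03)

    def test_degenerate_falls_back_to_half_with_warning(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2]])
        with pytest.warns(UserWarning):
            t = evaluate.pick_thresholds(probs, [F, F])
        assert t.t_exist == 0.5 and t.t_abnormal == 0.5


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        ci = evaluate.bootstrap_ci(lambda d: 1.23, [1, 2, 3], n_resamples=50)
        assert ci.low == ci.high == 1.23

    def test_same_seed_identical_interval(self):
        data = list(np.random.default_rng(0).normal(size=40))
        a = evaluate.bootstrap_ci(np.mean, data, n_resamples=200, seed=9)
        b = evaluate.bootstrap_ci(np.mean, data, n_resamples=200, seed=9)
        assert (a.low, a.high) == (b.low, b.high)

    def test_mean_interval_width_close_to_t_interval(self):
        rng = np.random.default_rng(4)
        data = list(rng.normal(0, 1, 100))
        ci = evaluate.bootstrap_ci(np.mean, data, n_resamples=4000, seed=1)
        sem = stats.sem(data)
        t_lo, t_hi = stats.t.interval(0.95, len(data) - 1,
                                      loc=np.mean(data), scale=sem)
        assert (ci.high - ci.low) == pytest.approx(t_hi - t_lo, rel=0.15)
        assert ci.low <= ci.point <= ci.high

    def test_undefined_resamples_redrawn_and_counted(self):
        def metric(d):
            if sum(d) % 2:
                raise ValueError("undefined")
            return float(sum(d))

        ci = evaluate.bootstrap_ci(metric, [1, 2, 3, 4], n_resamples=30, seed=0)
        assert ci.n_redrawn > 0


class TestStratifiedSplit:
    def test_reference_corpus_allocation(self):
        """Pass/fail strata of 4,029 and 1,784 split 70/10/20 give the
        canonical (2820, 403, 806) and (1249, 178, 357) allocations."""
        sp = evaluate.stratified_split(
            {"pass": 4029, "fail": 1784}, (0.7, 0.1, 0.2), seed=0
        )
        assert sp.counts["pass"] == (2820, 403, 806)
        assert sp.counts["fail"] == (1249, 178, 357)
        assert sp.subset_sizes() == (4069, 581, 1163)

    def test_degenerate_fractions(self):
        sp = evaluate.stratified_split([10, 7], (1.0, 0.0, 0.0), seed=1)
        assert sp.counts[0] == (10, 0, 0)
        assert sp.counts[1] == (7, 0, 0)

    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=4),
        st.integers(0, 10_000),
    )
    def test_allocations_conserve_stratum_sizes(self, sizes, seed):
        sp = evaluate.stratified_split(sizes, (0.7, 0.1, 0.2), seed=seed)
        for i, size in enumerate(sizes):
            assert sum(sp.counts[i]) == size
            assert len(sp.assignment[i]) == size

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            evaluate.stratified_split([10], (0.5, 0.4))


@pytest.fixture(scope="module")
def noiseless_dataset():
    rng = np.random.default_rng(31)
    cfg = synth.SamplingConfig(noise_sigma=(0.0, 0.0), blur_sigma=(0.5, 0.5),
                               fine_rotation_deg=(0, 0), shift_frac=(0, 0))
    out = []
    for _ in range(10):
        spec = synth.sample_spec(rng, cfg)
        tiles, truth = synth.render_subimages(spec)
        out.append((tiles, truth.scores))
    return out


class TestEvaluateSystem:
    def test_rule_scorer_perfect_on_noiseless_set(self, noiseless_dataset,
                                                  rule_scorer):
        rep = evaluate.evaluate_system(rule_scorer, noiseless_dataset, n_boot=0)
        assert rep.phantom_level["accuracy"] == 1.0
        for t in rep.per_type:
            assert rep.per_type[t].accuracy == 1.0
            assert rep.feature_level[t]["accuracy"] == 1.0

    def test_report_serializes(self, noiseless_dataset, rule_scorer, tmp_path):
        rep = evaluate.evaluate_system(rule_scorer, noiseless_dataset, n_boot=50)
        text = rep.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
        assert '"phantom_level"' in text
        for t, ci in rep.f1_ci.items():
            assert ci.low <= ci.point <= ci.high

    def test_empty_dataset_rejected(self, rule_scorer):
        with pytest.raises(ValueError):
            evaluate.evaluate_system(rule_scorer, [])
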