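"""Confusion counts, MCC, ROC/AUC equivalences, threshold search, resampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabvar import evaluate
from stabvar.evaluate import ConfusionCounts


class TestConfusion:
    def test_table3_style_cutoff(self):
        counts = evaluate.confusion([-2.0, -0.5], [1, 0], -1.1, "pathogenic_if_le")
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)

    def test_all_pathogenic_below_threshold(self):
        counts = evaluate.confusion([-3, -2, -4], [1, 1, 1], 0.0)
        assert counts.fn == 0 and counts.tp == 3

    def test_all_benign_predicted_pathogenic(self):
        counts = evaluate.confusion([-1, -1, -1], [0, 0, 0], 0.0)
        assert counts.fp == 3

    def test_boundary_score_predicts_pathogenic(self):
        counts = evaluate.confusion([-1.1], [1], -1.1, "pathogenic_if_le")
        assert counts.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate.confusion([1.0, 2.0], [1], 0.0)

    def test_rate_identities(self):
        counts = evaluate.confusion(
            np.linspace(-3, 3, 40), np.tile([0, 1], 20), -0.5
        )
        assert counts.tpr + counts.fnr == pytest.approx(1.0)
        assert counts.accuracy == (counts.tp + counts.tn) / counts.total


class TestMcc:
    def test_perfect(self):
        assert evaluate.mcc(ConfusionCounts(50, 50, 0, 0)) == 1.0

    def test_chance(self):
        assert evaluate.mcc(ConfusionCounts(25, 25, 25, 25)) == 0.0

    def test_hand_evaluated(self):
        expected = 1000 / math.sqrt(60 * 50 * 50 * 40)
        assert evaluate.mcc(ConfusionCounts(40, 30, 20, 10)) == pytest.approx(expected)
        assert expected == pytest.approx(0.408, abs=5e-4)

    def test_degenerate_denominator_convention(self):
        assert evaluate.mcc(ConfusionCounts(5, 0, 0, 0)) == 0.0

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(derandomize=True, deadline=None)
    def test_range_and_class_swap_symmetry(self, tpfn):
        tp, tn, fp, fn = tpfn
        m = evaluate.mcc(ConfusionCounts(tp, tn, fp, fn))
        assert -1.0 <= m <= 1.0
        assert m == pytest.approx(evaluate.mcc(ConfusionCounts(tn, tp, fn, fp)))


def _random_instance(rng, n_max=200, tie_prob=0.5):
    n = int(rng.integers(4, n_max + 1))
    y = rng.integers(0, 2, size=n)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    if rng.random() < tie_prob:
        scores = rng.integers(-5, 6, size=n).astype(float)  # many ties
    else:
        scores = rng.normal(size=n)
    return scores, y


class TestAucConcordance:
    def test_perfect_separation(self):
        auc = evaluate.auc_concordance([-3, -2, 0, 1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_is_chance(self):
        assert evaluate.auc_concordance([2.0] * 6, [0, 1] * 3) == 0.5

    def test_enumerated_pairs(self):
        # pathogenic {−3, −1}, benign {−2, 0}: 3 of 4 pairs concordant
        auc = evaluate.auc_concordance([-3, -1, -2, 0], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            evaluate.auc_concordance([1.0, 2.0], [1, 1])

    def test_brute_force_pair_enumeration(self):
        """Midrank estimator equals the O(n²) pair count on random data."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            scores, y = _random_instance(rng, n_max=60)
            pos = scores[y == 1]
            neg = scores[y == 0]
            brute = np.mean(
                (pos[:, None] < neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            fast = evaluate.auc_concordance(scores, y)
            assert fast == pytest.approx(float(brute), abs=1e-12)


class TestRocCurve:
    def test_perfect_separation_curve(self):
        roc = evaluate.roc_curve([-3, -2, 0, 1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        # passes through (FPR 0, TPR 1)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))

    def test_endpoints_and_monotone(self):
        rng = np.random.default_rng(3)
        scores, y = _random_instance(rng)
        roc = evaluate.roc_curve(scores, y)
        assert roc.tpr[0] == 0.0 and roc.fpr[0] == 0.0
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            scores, y = _random_instance(rng)
            auc_t = evaluate.roc_curve(scores, y).auc
            auc_c = evaluate.auc_concordance(scores, y)
            assert abs(auc_t - auc_c) < 1e-12

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(50):
            scores, y = _random_instance(rng)
            ours = evaluate.auc_concordance(scores, y, higher_is_pathogenic=True)
            assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_direction_flip_complements_auc(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=80)  # continuous, tie-free
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        a = evaluate.auc_concordance(scores, y, higher_is_pathogenic=False)
        b = evaluate.auc_concordance(scores, y, higher_is_pathogenic=True)
        assert a + b == pytest.approx(1.0, abs=1e-12)


def brute_force_optimal(scores, labels, rule):
    """Independent exhaustive scan: plain loop over every candidate."""
    scores = np.asarray(scores, dtype=float)
    u = np.unique(scores)
    candidates = np.r_[u[0] - 1.0, (u[:-1] + u[1:]) / 2.0, u[-1] + 1.0]
    results = []
    for t in candidates:
        m = evaluate.mcc(evaluate.confusion(scores, labels, t, rule))
        results.append((t, m))
    best = max(m for _, m in results)
    tied = [t for t, m in results if abs(m - best) <= 1e-12]
    tied.sort(key=lambda t: (abs(t), t))
    return tied[0], best


class TestOptimalThreshold:
    def test_hand_scan(self):
        t, m = evaluate.optimal_threshold([-3, -2, 0, 1], [1, 1, 0, 0])
        assert m == 1.0
        assert t == pytest.approx(-1.0)  # midpoint of −2 and 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            evaluate.optimal_threshold([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("rule", ["pathogenic_if_le", "pathogenic_if_ge"])
    def test_matches_brute_force(self, rule):
        rng = np.random.default_rng(23)
        for _ in range(100):
            scores, y = _random_instance(rng, n_max=50)
            t_fast, m_fast = evaluate.optimal_threshold(scores, y, rule)
            t_slow, m_slow = brute_force_optimal(scores, y, rule)
            assert m_fast == pytest.approx(m_slow, abs=1e-12)
            assert t_fast == pytest.approx(t_slow)

    def test_translation_equivariance(self):
        scores = np.array([-4.0, -2.0, -1.0, 1.0, 3.0, 5.0])
        y = np.array([1, 1, 1, 0, 0, 0])
        t0, m0 = evaluate.optimal_threshold(scores, y)
        t1, m1 = evaluate.optimal_threshold(scores + 10.0, y)
        assert m1 == pytest.approx(m0)
        assert t1 == pytest.approx(t0 + 10.0)

    def test_permutation_null_keeps_mcc_small(self):
        rng = np.random.default_rng(29)
        scores = rng.normal(size=200)
        best = []
        for _ in range(100):
            y = rng.permutation(np.repeat([0, 1], 100))
            best.append(evaluate.optimal_threshold(scores, y)[1])
        assert np.mean(best) < 0.25


class TestBalancedResampling:
    def test_perfect_rule_exact(self):
        y = np.repeat([0, 1], 30)
        scores = np.where(y == 1, -3.0, 1.0)
        s = evaluate.balanced_resample_evaluate(
            y, scores=scores, threshold=-1.0, n_repeats=100, seed=0
        )
        assert s.mean["tpr"] == 1.0 and s.sd["tpr"] == 0.0
        assert s.mean["fpr"] == 0.0 and s.mean["accuracy"] == 1.0

    def test_sample_size_definition(self):
        y = np.repeat([0, 1], [10, 40])
        s = evaluate.balanced_resample_evaluate(
            y, predictions=np.ones_like(y), n_repeats=5, seed=1
        )
        assert s.n_per_class == 5  # floor(0.5 · min(10, 40))

    def test_always_pathogenic_rule_accuracy_half(self):
        y = np.repeat([0, 1], [20, 50])
        s = evaluate.balanced_resample_evaluate(
            y, predictions=np.ones_like(y), n_repeats=50, seed=2
        )
        assert s.mean["accuracy"] == 0.5 and s.sd["accuracy"] == 0.0

    def test_tpr_plus_fnr_is_one(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        s = evaluate.balanced_resample_evaluate(y, predictions=pred, n_repeats=40, seed=3)
        assert s.mean["tpr"] + s.mean["fnr"] == pytest.approx(1.0)

    def test_mean_matches_hypergeometric_expectation(self):
        """For a fixed rule the per-repeat TPR is a hypergeometric mean whose
        expectation is the population true-positive fraction."""
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], [300, 400])
        pred = rng.random(700) < np.where(y == 1, 0.8, 0.2)
        expected_tpr = pred[y == 1].mean()
        expected_fpr = pred[y == 0].mean()
        s = evaluate.balanced_resample_evaluate(y, predictions=pred, n_repeats=400, seed=6)
        for key, expected in (("tpr", expected_tpr), ("fpr", expected_fpr)):
            tol = 3 * s.sd[key] / np.sqrt(s.n_repeats) + 1e-12
            assert abs(s.mean[key] - expected) < tol

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            evaluate.balanced_resample_evaluate(
                np.array([0, 1]), predictions=np.array([0, 1])
            )


class TestStratifiedAuc:
    def test_group_at_min_count_excluded(self, annotated_4k):
        import pandas as pd

        df = annotated_4k.head(200).copy()
        df["grp"] = ["a"] * 100 + ["b"] * 100
        out = evaluate.stratified_auc(df, "grp", "ddg_p1", min_count=100)
        assert out.empty  # both groups have exactly n=100: strict >

    def test_single_group_equals_global_auc(self, annotated_4k):
        df = annotated_4k.copy()
        df["grp"] = "all"
        out = evaluate.stratified_auc(df, "grp", "ddg_p1", min_count=100)
        assert len(out) == 1
        global_auc = evaluate.auc_concordance(df["ddg_p1"], df["label"])
        assert out["auc"].iloc[0] == pytest.approx(global_auc)

    def test_per_group_parameter_recovery(self):
        """Groups generated with different separations recover their own
        analytic AUC within ±0.03 at n=2000/group/class."""
        from stabvar import synth

        targets = {}
        frames = []
        for name, mu_p in (("strong", -2.0), ("weak", -0.6)):
            cfg = synth.GeneratorConfig(
                seed=31 if name == "strong" else 32,
                ddg_pathogenic=synth.GaussianParams((mu_p,) * 3, (1.5,) * 3),
            )
            df = synth.generate_annotated(cfg, 2000, 2000)
            df["grp"] = name
            targets[name] = synth.analytic_auc(cfg)
            frames.append(df)
        import pandas as pd

        combined = pd.concat(frames, ignore_index=True)
        out = evaluate.stratified_auc(combined, "grp", "ddg_p1", min_count=100)
        for _, row in out.iterrows():
            assert abs(row["auc"] - targets[row["group"]]) < 0.03

    def test_missing_grouping_column_rejected(self, annotated_4k):
        with pytest.raises(ValueError, match="grouping"):
            evaluate.stratified_auc(annotated_4k, "nope", "ddg_p1")
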