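import numpy as np
import pandas as pd
import pytest

from bryorisk.thresholding import (
    RocPoint,
    auc,
    choose_cutoff,
    concordance_auc,
    index_of_union,
    roc_curve,
    select_cutoff,
    two_graph_roc,
)


def brute_force_auc(scores, labels):
    """Independent pairwise concordance (ties = 1/2), plain double loop."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_hand_counted_point(self):
        roc = roc_curve([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        by_t = {p.threshold: p for p in roc}
        assert by_t[0.4].sensitivity == 1.0
        assert by_t[0.4].specificity == 0.5

    def test_extreme_thresholds(self):
        roc = roc_curve([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        by_t = {p.threshold: p for p in roc}
        assert by_t[0.0].sensitivity == 1.0  # everything called positive
        assert by_t[1.0].sensitivity == 0.0  # nothing reaches threshold 1

    def test_perfect_separation_has_perfect_point(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in roc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_se_sp_recomputable_from_confusion_matrix(self):
        rng = np.random.default_rng(0)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        for p in roc_curve(s, y):
            tp = np.sum((s >= p.threshold) & (y == 1))
            fn = np.sum((s < p.threshold) & (y == 1))
            tn = np.sum((s < p.threshold) & (y == 0))
            fp = np.sum((s >= p.threshold) & (y == 0))
            assert p.sensitivity == pytest.approx(tp / (tp + fn))
            assert p.specificity == pytest.approx(tn / (tn + fp))


class TestAUC:
    def test_perfect_and_tied(self):
        assert auc(roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])) == pytest.approx(1.0)
        assert auc(roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])) == pytest.approx(0.5)

    def test_hand_counted_example(self):
        assert auc(roc_curve([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])) == pytest.approx(0.75)

    def test_trapezoid_equals_concordance_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(10, 60)
            s = np.round(rng.random(n), 2)  # rounding forces ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            a = auc(roc_curve(s, y))
            assert abs(a - brute_force_auc(s, y)) < 1e-12
            assert abs(a - concordance_auc(s, y)) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        assert auc(roc_curve(s, y)) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestIndexOfUnion:
    def test_se_sp_equal_auc_is_rank_one(self):
        roc = [RocPoint(0.3, 0.7, 0.7), RocPoint(0.5, 0.9, 0.4)]
        ranking = index_of_union(roc, 0.7)
        assert ranking.iloc[0]["threshold"] == 0.3
        assert ranking.iloc[0]["iu"] == pytest.approx(0.0)

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(3)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        roc = roc_curve(s, y)
        a = auc(roc)
        ranking = index_of_union(roc, a)
        brute = sorted(
            roc,
            key=lambda p: (
                abs(p.sensitivity - a) + abs(p.specificity - a),
                abs(p.sensitivity - p.specificity),
                p.threshold,
            ),
        )
        assert list(ranking["threshold"]) == [p.threshold for p in brute]

    def test_tie_break_prefers_balanced_point(self):
        roc = [RocPoint(0.4, 0.9, 0.7), RocPoint(0.5, 0.85, 0.75)]
        ranking = index_of_union(roc, 0.7)  # both IU = 0.2
        assert ranking.iloc[0]["threshold"] == 0.5


class TestSelectCutoff:
    def _ranking(self, rows):
        return pd.DataFrame(rows, columns=["threshold", "iu", "sensitivity", "specificity"])

    def test_walks_to_third_best_when_sensitivity_low(self):
        # mirrors the all-species model narrative: IU optimum Se=0.53 rejected,
        # third-ranked cutoff 0.21 with Se=0.75 accepted
        ranking = self._ranking(
            [(0.30, 0.05, 0.53, 0.74), (0.27, 0.08, 0.62, 0.60), (0.21, 0.12, 0.75, 0.51)]
        )
        cutoff, rule, warning = select_cutoff(ranking, 0.70)
        assert cutoff == 0.21
        assert rule == "sensitivity_override"
        assert warning == ""

    def test_iu_optimum_kept_when_sensitive_enough(self):
        # the morphology model narrative: optimum 0.18, Se=0.75 accepted as-is
        ranking = self._ranking([(0.18, 0.02, 0.75, 0.62), (0.25, 0.1, 0.6, 0.8)])
        cutoff, rule, _ = select_cutoff(ranking, 0.70)
        assert cutoff == 0.18
        assert rule == "iu_optimal"

    def test_fallback_when_no_cutoff_qualifies(self):
        ranking = self._ranking([(0.4, 0.05, 0.5, 0.9), (0.5, 0.2, 0.4, 0.95)])
        cutoff, rule, warning = select_cutoff(ranking, 0.70)
        assert cutoff == 0.4
        assert warning != ""

    def test_never_skips_a_qualifying_higher_rank(self):
        rng = np.random.default_rng(4)
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        sel = choose_cutoff(s, y, 0.70)
        ranking = sel.iu_ranking
        chosen_pos = ranking.index[ranking["threshold"] == sel.chosen_cutoff][0]
        earlier = ranking.loc[: chosen_pos - 1] if chosen_pos > 0 else ranking.iloc[:0]
        assert (earlier["sensitivity"] < 0.70).all()


class TestTwoGraphRoc:
    def test_monotone_se_sp(self):
        rng = np.random.default_rng(5)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        table, _ = two_graph_roc(roc_curve(s, y))
        assert (table["sensitivity"].diff().dropna() <= 0).all()
        assert (table["specificity"].diff().dropna() >= 0).all()

    def test_crossing_by_linear_interpolation(self):
        roc = [RocPoint(0.2, 0.8, 0.2), RocPoint(0.4, 0.4, 0.6)]
        _, crossing = two_graph_roc(roc)
        # gap goes +0.6 -> -0.2, zero at t = 0.2 + 0.2*(0.6/0.8)
        assert crossing == pytest.approx(0.35)

    def test_degenerate_two_point_no_crossing(self):
        roc = [RocPoint(0.1, 1.0, 0.0), RocPoint(0.9, 0.9, 0.1)]
        table, crossing = two_graph_roc(roc)
        assert len(table) == 2
        assert crossing is None
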