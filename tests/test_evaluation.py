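"""Evaluation metrics: Mann-Whitney AUC against brute force, balancing,
bootstrap, confusion-matrix metrics, and the four reporting phases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import edwarn.evaluation as ev
from edwarn.crowding import CrowdingScheme


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert ev.auc([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_enumerated_example(self):
        assert ev.auc([3, 1, 2, 0], [1, 0, 0, 1]) == 0.5

    def test_single_class_is_undefined_not_half(self):
        with pytest.raises(ev.UndefinedAUCError):
            ev.auc([1, 2, 3], [1, 1, 1])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 20), st.booleans()),
                    min_size=2, max_size=200))
    def test_matches_brute_force_all_pairs(self, pairs):
        scores = np.array([p[0] for p in pairs], dtype=float)
        labels = np.array([p[1] for p in pairs], dtype=int)
        if labels.sum() in (0, len(labels)):
            return
        assert ev.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        a1 = ev.auc(scores, labels)
        a2 = ev.auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestDownsample:
    def test_balances_majority_class(self):
        scores = np.arange(100.0)
        labels = np.r_[np.ones(10), np.zeros(90)]
        s, l = ev.downsample_balance(scores, labels, seed=4)
        assert l.sum() == 10 and len(l) == 20

    def test_deterministic_given_seed(self):
        scores = np.arange(100.0)
        labels = np.r_[np.ones(10), np.zeros(90)]
        a = ev.downsample_balance(scores, labels, seed=4)
        b = ev.downsample_balance(scores, labels, seed=4)
        np.testing.assert_array_equal(a[0], b[0])

    def test_degenerate_positive_majority(self):
        scores = np.arange(10.0)
        labels = np.r_[np.ones(8), np.zeros(2)]
        s, l = ev.downsample_balance(scores, labels, seed=0)
        assert l.sum() == 2 and len(l) == 4

    def test_downsampled_auc_unbiased(self):
        rng = np.random.default_rng(17)
        scores = np.r_[rng.normal(1.0, 1, 50), rng.normal(0, 1, 500)]
        labels = np.r_[np.ones(50), np.zeros(500)]
        full = ev.auc(scores, labels)
        draws = [ev.auc(*ev.downsample_balance(scores, labels, seed=s))
                 for s in range(200)]
        assert np.mean(draws) == pytest.approx(full, abs=0.03)


class TestBootstrap:
    def test_perfect_separation_pins_interval(self):
        scores = np.r_[np.ones(8), np.zeros(8)]
        labels = np.r_[np.ones(8), np.zeros(8)]
        assert ev.bootstrap_ci(scores, labels, seed=0) == (1.0, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        assert ev.bootstrap_ci(scores, labels, seed=7) == \
            ev.bootstrap_ci(scores, labels, seed=7)


class TestBinaryMetrics:
    def test_confusion_matrix_arithmetic(self):
        # TP=8, FN=2, FP=4, TN=16
        scores = np.r_[np.ones(8), np.zeros(2), np.ones(4), np.zeros(16)]
        labels = np.r_[np.ones(10), np.zeros(20)]
        m = ev.binary_metrics(scores, labels, threshold=0.5)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(8 / 11)
        assert m["specificity"] == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = ev.binary_metrics([1, 1, 0, 0], [1, 1, 0, 0], threshold=0.5)
        assert m["sensitivity"] == m["specificity"] == m["f1"] == 1.0

    def test_no_predicted_positives(self):
        m = ev.binary_metrics([0, 0, 0], [1, 0, 1], threshold=0.5)
        assert np.isnan(m["precision"])
        assert m["sensitivity"] == 0.0


class TestContinuous:
    @staticmethod
    def rows_from_errors(errors):
        return pd.DataFrame({"model_id": "AHWM", "target": "occupancy",
                             "yhat": np.asarray(errors, float), "y_actual": 0.0})

    def test_direct_arithmetic(self):
        g = ev.continuous_metrics(self.rows_from_errors([1, -2, 3]))
        assert g.loc[0, "mae"] == pytest.approx(2.0)
        assert g.loc[0, "mse"] == pytest.approx(14 / 3)
        assert g.loc[0, "rmse"] == pytest.approx(np.sqrt(14 / 3))

    def test_zero_error(self):
        g = ev.continuous_metrics(self.rows_from_errors([0, 0]))
        assert g.loc[0, "mae"] == g.loc[0, "rmse"] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50))
    def test_rmse_at_least_mae(self, errors):
        g = ev.continuous_metrics(self.rows_from_errors(errors))
        assert g.loc[0, "rmse"] >= g.loc[0, "mae"] - 1e-9


def _oracle_rows(n_days=40, seed=0):
    """Evaluation rows for an oracle forecaster (yhat == y_actual) on a
    synthetic occupancy-like signal with sparse crowding."""
    rng = np.random.default_rng(seed)
    origins = pd.date_range("2022-01-01", periods=n_days * 24, freq="h")
    recs = []
    t0 = origins[0]
    hours = np.arange(n_days * 24 + 25)
    occ = 50 + 30 * np.sin(2 * np.pi * ((hours % 24) - 10) / 24) \
        + rng.normal(0, 8, len(hours))
    label = (occ >= 88).astype(float)
    for i, o in enumerate(origins):
        for h in range(1, 25):
            recs.append((o, "AHWM", "occupancy", h, occ[i + h], occ[i + h],
                         label[i + h], o.hour))
    return pd.DataFrame(recs, columns=["origin", "model_id", "target", "horizon",
                                       "yhat", "y_actual", "hour_label",
                                       "origin_hour"])


class TestPhases:
    rows = _oracle_rows()
    scheme = CrowdingScheme(threshold=88.0)

    def test_oracle_pph_is_perfect(self):
        out = ev.pph(self.rows, seed=0, n_boot=20)
        assert (out["auc"].dropna() == 1.0).all()

    def test_label_independent_scores_are_no_skill(self):
        rng = np.random.default_rng(3)
        rows = self.rows.copy()
        rows["yhat"] = rng.normal(size=len(rows))
        out = ev.pph(rows, seed=0, n_boot=20, n_draws=10)
        ok = out["auc"].dropna()
        assert len(ok) == 24
        assert np.abs(ok - 0.5).mean() < 0.06

    def test_oracle_ppo_is_perfect(self):
        out = ev.ppo(self.rows, self.scheme, seed=0, n_boot=20)
        assert (out["auc"].dropna() == 1.0).all()

    def test_matrix_cells_match_filtered_auc(self):
        mat = ev.auc_matrix(self.rows, "AHWM")
        sub = self.rows
        for o in (0, 13):
            for h in (1, 24):
                g = sub[(sub.origin_hour == o) & (sub.horizon == h)]
                cell = mat.loc[o, f"t+{h}"]
                if g.hour_label.nunique() == 2:
                    assert cell == pytest.approx(ev.auc(g.yhat, g.hour_label))
                else:
                    assert np.isnan(cell)

    def test_matrix_missing_without_crowding_events(self):
        rows = self.rows.copy()
        rows.loc[(rows.origin_hour == 2) & (rows.horizon == 3), "hour_label"] = 0.0
        mat = ev.auc_matrix(rows, "AHWM")
        assert np.isnan(mat.loc[2, "t+3"])
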