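"""Evaluation statistics: precision/recall/F1 (macro & micro), count agreement."""

import numpy as np
import pytest

from earcount.metrics import (
    class_metrics,
    confusion_from_labels,
    count_agreement,
    f1_scores,
    micro_f1,
    precision_recall,
    round_percent,
)

# published per-class precision/recall of a four-class ear classifier at
# 1000 test patches per class (percent)
REF_PRECISION = (99.80, 97.50, 98.07, 98.50)
REF_RECALL = (98.42, 97.70, 97.98, 99.80)
REF_F1 = (99.11, 97.60, 98.03, 99.14)
REF_MACRO_F1 = 98.47
REF_MICRO_F1 = 98.47


class TestPrecisionRecall:
    def test_diagonal_matrix_is_perfect(self):
        p, r = precision_recall(np.diag([5, 7, 3, 9]))
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(r, 1.0)

    def test_two_class_hand_arithmetic(self):
        p, r = precision_recall(np.array([[8, 2], [1, 9]]))
        assert p[0] == pytest.approx(8 / 9)
        assert r[0] == pytest.approx(0.8)

    def test_zero_denominator_yields_zero_with_warning(self):
        cm = np.array([[5, 0], [3, 0]])  # class 1 never predicted correctly
        with pytest.warns(UserWarning):
            p, r = precision_recall(cm)
        assert p[1] == 0.0 and r[1] == 0.0

    def test_confusion_from_labels_hand_tally(self):
        true = [0, 0, 1, 2, 3, 3, 1, 2]
        pred = [0, 1, 1, 2, 3, 2, 1, 0]
        cm = confusion_from_labels(true, pred)
        want = np.zeros((4, 4), int)
        for t, p in zip(true, pred):
            want[t, p] += 1
        np.testing.assert_array_equal(cm, want)
        assert cm.sum() == 8


class TestF1:
    def test_reference_per_class_f1_reproduced(self):
        p = np.array(REF_PRECISION) / 100
        r = np.array(REF_RECALL) / 100
        f1, macro = f1_scores(p, r)
        for got, want in zip(f1, REF_F1):
            assert round_percent(got) == pytest.approx(want, abs=0.011)
        assert round_percent(macro) == pytest.approx(REF_MACRO_F1, abs=0.011)

    def test_equal_precision_recall_gives_f1_equal_to_them(self):
        p = np.array([0.5, 0.9, 0.1, 1.0])
        f1, _ = f1_scores(p, p)
        np.testing.assert_allclose(f1, p)

    def test_macro_is_mean_of_per_class(self, rng):
        p = rng.random(4)
        r = rng.random(4)
        f1, macro = f1_scores(p, r)
        assert macro == pytest.approx(f1.mean())

    def test_zero_zero_class_defined_as_zero(self):
        f1, _ = f1_scores(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert f1[0] == 0.0


class TestMicroF1:
    def test_single_label_micro_equals_accuracy(self, rng):
        cm = rng.integers(0, 50, (4, 4))
        p_mi, r_mi, f_mi = micro_f1(cm)
        acc = np.trace(cm) / cm.sum()
        assert p_mi == pytest.approx(acc)
        assert r_mi == pytest.approx(acc)
        assert f_mi == pytest.approx(acc)

    def test_hand_arithmetic(self):
        _, _, f_mi = micro_f1(np.array([[3, 1], [0, 4]]))
        assert f_mi == pytest.approx(7 / 8)

    def test_reference_recalls_at_equal_class_sizes(self):
        # 1000 patches/class: micro F1 = accuracy = mean recall
        cm = np.zeros((4, 4))
        for i, rec in enumerate(REF_RECALL):
            cm[i, i] = rec * 10  # rec% of 1000
            cm[i, (i + 1) % 4] = 1000 - rec * 10
        _, _, f_mi = micro_f1(cm)
        assert round_percent(f_mi) == pytest.approx(REF_MICRO_F1, abs=0.011)


class TestCountAgreement:
    def test_perfect_prediction(self):
        ev = count_agreement([10, 20, 30], [10, 20, 30])
        assert ev.r2 == 1.0 and ev.rmse == 0.0 and ev.bias == 0.0

    def test_hand_arithmetic_two_images(self):
        ev = count_agreement([10, 20], [8, 24])
        assert ev.bias == pytest.approx(((10 - 8) + (20 - 24)) / 2)  # -1
        assert ev.rmse == pytest.approx(np.sqrt(10))

    def test_reference_rrmse_late_grain_filling(self):
        # residuals of +/-3.24 around a mean manual count of 233 ears
        manual = [232.0, 234.0]
        predicted = [232.0 - 3.24, 234.0 + 3.24]
        ev = count_agreement(manual, predicted)
        assert ev.rmse == pytest.approx(3.24)
        assert ev.rrmse == pytest.approx(1.39, abs=0.005)

    def test_r2_can_be_negative_for_bad_predictor(self):
        ev = count_agreement([10, 12, 14], [30, 0, 50])
        assert ev.r2 < 0

    def test_rmse_bounds_bias(self, rng):
        for _ in range(20):
            m = rng.integers(1, 100, 10).astype(float)
            c = rng.integers(0, 100, 10).astype(float)
            ev = count_agreement(m, c)
            assert ev.rmse >= abs(ev.bias) - 1e-12

    def test_rrmse_scale_invariant_rmse_linear(self, rng):
        m = rng.integers(10, 100, 15).astype(float)
        c = m + rng.normal(0, 5, 15)
        ev1 = count_agreement(m, c)
        ev3 = count_agreement(3 * m, 3 * c)
        assert ev3.rrmse == pytest.approx(ev1.rrmse)
        assert ev3.rmse == pytest.approx(3 * ev1.rmse)

    def test_errors(self):
        with pytest.raises(ValueError):
            count_agreement([1, 2], [1])
        with pytest.raises(ValueError):
            count_agreement([], [])
        with pytest.raises(ValueError):
            count_agreement([0, 0], [1, 1])  # zero manual mean


def test_all_metrics_match_naive_loop_oracle(rng):
    """Vectorized metrics vs plain-Python loops on random matrices."""
    for _ in range(10):
        cm = rng.integers(0, 30, (4, 4)).astype(float)
        cm[np.diag_indices(4)] += 1  # avoid zero-denominator warnings
        p, r = precision_recall(cm)
        f1, macro = f1_scores(p, r)
        p_mi, r_mi, f_mi = micro_f1(cm)
        tp = [cm[i][i] for i in range(4)]
        fp = [sum(cm[j][i] for j in range(4)) - cm[i][i] for i in range(4)]
        fn = [sum(cm[i][j] for j in range(4)) - cm[i][i] for i in range(4)]
        for i in range(4):
            pi = tp[i] / (tp[i] + fp[i])
            ri = tp[i] / (tp[i] + fn[i])
            assert abs(p[i] - pi) < 1e-10
            assert abs(r[i] - ri) < 1e-10
            assert abs(f1[i] - 2 * pi * ri / (pi + ri)) < 1e-10
        assert abs(macro - sum(f1) / 4) < 1e-10
        pm = sum(tp) / (sum(tp) + sum(fp))
        rm = sum(tp) / (sum(tp) + sum(fn))
        assert abs(f_mi - 2 * pm * rm / (pm + rm)) < 1e-10


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=50, derandomize=True)
    @given(
        cm=st.lists(
            st.lists(st.integers(0, 500), min_size=4, max_size=4),
            min_size=4,
            max_size=4,
        )
    )
    def test_confusion_matrix_invariants_hold_for_any_counts(cm):
        """Micro F1 equals accuracy and macro F1 is the per-class mean for
        every single-label confusion matrix."""
        cm = np.array(cm, dtype=float)
        if cm.sum() == 0:
            return
        p_mi, r_mi, f_mi = micro_f1(cm)
        assert p_mi == pytest.approx(np.trace(cm) / cm.sum())
        assert r_mi == pytest.approx(p_mi)
        assert f_mi == pytest.approx(p_mi)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            p, r = precision_recall(cm)
        f1, macro = f1_scores(p, r)
        assert macro == pytest.approx(f1.mean())
        assert ((f1 >= 0) & (f1 <= 1)).all()

    @settings(max_examples=50, derandomize=True)
    @given(
        manual=st.lists(st.integers(1, 400), min_size=2, max_size=20),
        noise=st.lists(st.integers(-50, 50), min_size=2, max_size=20),
    )
    def test_count_agreement_invariants_hold_for_any_counts(manual, noise):
        """RMSE bounds |bias| and RRMSE is scale-free for any paired counts."""
        n = min(len(manual), len(noise))
        m = np.array(manual[:n], dtype=float)
        c = np.clip(m + np.array(noise[:n], dtype=float), 0, None)
        ev = count_agreement(m, c)
        assert ev.rmse >= abs(ev.bias) - 1e-9
        ev2 = count_agreement(2 * m, 2 * c)
        assert ev2.rrmse == pytest.approx(ev.rrmse)
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_round_percent_is_half_up():
    assert round_percent(0.98475) == 98.48
    assert round_percent(0.981249) == 98.12


def test_class_metrics_bundle_consistency(rng):
    cm = rng.integers(1, 40, (4, 4))
    m = class_metrics(cm)
    assert m.macro_f1 == pytest.approx(np.mean(m.f1))
    pct = m.as_percent()
    assert all(0 <= v <= 100 for v in pct["f1"])
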