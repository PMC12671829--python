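"""Metrics: hand-computed one-vs-rest values, cross-check against
scikit-learn, fuzzed accuracy identity, and the Grad-CAM analytic oracle."""

import numpy as np
import pytest
import sklearn.metrics as skm

from julite import nn
from julite.metrics_eval import (ConfusionMatrix, TimingReport, confusion_matrix,
                                 grad_cam, measure_fps, metrics_from_cm)
from julite.nn import Tensor


def test_confusion_matrix_hand_tally():
    cm = confusion_matrix((0, 0, 1, 1, 2), (0, 1, 1, 1, 0), 3)
    assert cm.counts.tolist() == [[1, 1, 0], [0, 2, 0], [1, 0, 0]]
    assert cm.total == 5


def test_confusion_matrix_perfect_predictions_is_diagonal(rng):
    y = rng.integers(0, 6, size=200)
    cm = confusion_matrix(y, y, 6)
    assert np.array_equal(cm.counts, np.diag(np.bincount(y, minlength=6)))


def test_confusion_matrix_matches_sklearn(rng):
    y_true = rng.integers(0, 6, size=500)
    y_pred = rng.integers(0, 6, size=500)
    cm = confusion_matrix(y_true, y_pred, 6)
    assert np.array_equal(cm.counts, skm.confusion_matrix(y_true, y_pred,
                                                          labels=range(6)))


def test_confusion_matrix_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion_matrix([0, 6], [0, 0], 6)


def test_metrics_binary_toy_hand_arithmetic():
    """TP=8, FN=2, FP=1, TN=9 for class 0."""
    cm = np.array([[8, 2], [1, 9]])
    rep = metrics_from_cm(cm)
    assert rep.recall[0] == pytest.approx(0.8)
    assert rep.precision[0] == pytest.approx(8 / 9, abs=1e-4)
    assert rep.specificity[0] == pytest.approx(0.9)
    assert rep.accuracy == pytest.approx(0.85)
    assert rep.f1[0] == pytest.approx(16 / 19, abs=1e-4)


def test_metrics_perfect_and_all_wrong():
    perfect = metrics_from_cm(np.diag([5, 3, 7]))
    assert perfect.accuracy == 1.0
    assert np.all(perfect.precision == 1.0) and np.all(perfect.recall == 1.0)
    assert np.all(perfect.specificity == 1.0) and np.all(perfect.f1 == 1.0)

    wrong = metrics_from_cm(np.array([[0, 4], [3, 0]]))
    assert wrong.accuracy == 0.0
    assert np.all(wrong.recall == 0.0)


def test_metrics_match_sklearn_macro(rng):
    y_true = rng.integers(0, 6, size=400)
    y_pred = rng.integers(0, 6, size=400)
    rep = metrics_from_cm(confusion_matrix(y_true, y_pred, 6))
    assert rep.macro_precision == pytest.approx(
        skm.precision_score(y_true, y_pred, average="macro", zero_division=0))
    assert rep.macro_recall == pytest.approx(
        skm.recall_score(y_true, y_pred, average="macro", zero_division=0))
    assert rep.macro_f1 == pytest.approx(
        skm.f1_score(y_true, y_pred, average="macro", zero_division=0))


def test_metrics_permutation_equivariant(rng):
    counts = rng.integers(0, 30, size=(6, 6))
    perm = rng.permutation(6)
    rep = metrics_from_cm(counts)
    rep_p = metrics_from_cm(counts[np.ix_(perm, perm)])
    assert np.allclose(rep.precision[perm], rep_p.precision)
    assert np.allclose(rep.recall[perm], rep_p.recall)
    assert rep.accuracy == pytest.approx(rep_p.accuracy)
    assert rep.macro_f1 == pytest.approx(rep_p.macro_f1)


def test_accuracy_equals_matching_fraction_fuzz(rng):
    """1,000 fuzz cases: trace/total equals the direct matching fraction."""
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        k = int(rng.integers(2, 7))
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        rep = metrics_from_cm(confusion_matrix(y_true, y_pred, k))
        assert rep.accuracy == pytest.approx(float(np.mean(y_true == y_pred)))


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        metrics_from_cm(np.zeros((3, 3), dtype=int))


def test_timing_report_definitional_identity():
    rep = TimingReport.from_time(0.02)
    assert rep.fps == pytest.approx(50.0)
    assert rep.fps * rep.mean_inference_time == pytest.approx(1.0)
    assert TimingReport.from_time(1.0).fps == 1.0


def test_measure_fps_smoke(rng):
    nn.manual_seed(0)

    class Tiny(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = nn.Conv2d(3, 4, 3)
            self.fc = nn.Linear(4, 2)

        def forward(self, x):
            return self.fc(nn.global_avg_pool(self.conv(x)))

    rep = measure_fps(Tiny(), rng.normal(size=(2, 3, 16, 16)), n_repeats=2)
    assert rep.mean_inference_time > 0
    assert rep.fps * rep.mean_inference_time == pytest.approx(1.0)


class _ChannelMeanToy(nn.Module):
    """Logit of class c = global mean of activation channel c."""

    def __init__(self, weight: np.ndarray):
        super().__init__()
        self.conv = nn.Conv2d(3, weight.shape[0], 3)
        self.conv.weight.data = weight.copy()
        self.conv.bias.data[:] = 0.0

    def forward(self, x):
        return nn.global_avg_pool(self.conv(x))


def test_grad_cam_matches_analytic_channel_map(rng):
    """For a model whose class-c logit is the global mean of channel c, the
    heatmap is that channel's activation, ReLU'd and min-max normalized."""
    nn.manual_seed(0)
    w = rng.normal(size=(4, 3, 3, 3))
    model = _ChannelMeanToy(w)
    x = rng.normal(size=(3, 16, 16))
    heat = grad_cam(model, x, target_class=2, target_layer="conv")
    with nn.no_grad():
        act = model.conv(Tensor(x[None])).data[0, 2]
    expected = np.maximum(act, 0.0)
    expected = (expected - expected.min()) / (expected.max() - expected.min())
    assert heat.values.shape == (16, 16)
    assert np.allclose(heat.values, expected, atol=1e-10)
    assert heat.values.min() == 0.0 and heat.values.max() == 1.0


def test_grad_cam_invariant_to_logit_shift(rng):
    nn.manual_seed(0)
    w = rng.normal(size=(4, 3, 3, 3))

    class Shifted(_ChannelMeanToy):
        def forward(self, x):
            return super().forward(x) + 123.0

    x = rng.normal(size=(3, 12, 12))
    h0 = grad_cam(_ChannelMeanToy(w), x, 1, "conv")
    h1 = grad_cam(Shifted(w), x, 1, "conv")
    assert np.allclose(h0.values, h1.values, atol=1e-12)


def test_grad_cam_upsamples_to_input_size(rng):
    nn.manual_seed(0)

    class Strided(nn.Module):
        def __init__(self):
            super().__init__()
            self.conv = nn.Conv2d(3, 5, 3, stride=2)
            self.fc = nn.Linear(5, 3)

        def forward(self, x):
            return self.fc(nn.global_avg_pool(self.conv(x)))

    heat = grad_cam(Strided(), rng.normal(size=(3, 32, 32)), 0, "conv")
    assert heat.values.shape == (32, 32)
    assert heat.values.min() >= 0.0 and heat.values.max() <= 1.0


def test_grad_cam_unknown_layer_raises(rng):
    nn.manual_seed(0)
    with pytest.raises(ValueError):
        grad_cam(_ChannelMeanToy(rng.normal(size=(4, 3, 3, 3))),
                 rng.normal(size=(3, 8, 8)), 0, "nope")


def test_confusion_matrix_csv_round_trip(tmp_path):
    cm = ConfusionMatrix(np.arange(9).reshape(3, 3), ("a", "b", "c"))
    path = tmp_path / "cm.csv"
    cm.to_csv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].endswith("a,b,c")
    assert lines[1] == "a,0,1,2"
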