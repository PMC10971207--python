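"""Confusion matrices, accuracy / macro F1, replicate aggregation, rendering."""

import numpy as np
import pytest

from specseg.evaluate import (
    ConfusionMatrix,
    EvalReport,
    aggregate_replicates,
    comparison_table,
    confusion_matrix,
    metrics_from_confusion,
    render_projection,
)
from specseg.preprocess import DegenerateInputError, LabelMap, ParameterError


def brute_force_metrics(counts):
    """Independent formula oracle: explicit loops, no shared code path."""
    counts = np.asarray(counts, float)
    acc = 100.0 * sum(counts[i, i] for i in range(3)) / counts.sum()
    f1s = []
    for i in range(3):
        tp = counts[i, i]
        p = tp / counts[:, i].sum() if counts[:, i].sum() else 0.0
        r = tp / counts[i, :].sum() if counts[i, :].sum() else 0.0
        f1s.append(2 * p * r / (p + r) if (p + r) else 0.0)
    return acc, sum(f1s) / 3


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        truth = rng.integers(1, 4, (32, 32)).astype(np.uint8)
        cm = confusion_matrix(truth, truth, np.ones_like(truth, bool))
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert np.allclose(np.diag(cm.percent), 100.0)

    def test_four_pixel_hand_tally(self):
        truth = np.array([[1, 1, 2, 3]], np.uint8)
        pred = np.array([[1, 2, 2, 3]], np.uint8)
        cm = confusion_matrix(pred, truth, np.ones((1, 4), bool))
        assert np.array_equal(cm.counts, [[1, 1, 0], [0, 1, 0], [0, 0, 1]])
        assert np.allclose(cm.percent, [[50, 50, 0], [0, 100, 0], [0, 0, 100]])

    def test_rows_sum_to_100(self, rng):
        truth = rng.integers(1, 4, (64, 64)).astype(np.uint8)
        pred = rng.integers(1, 4, (64, 64)).astype(np.uint8)
        cm = confusion_matrix(pred, truth, np.ones_like(truth, bool))
        assert np.allclose(cm.percent.sum(axis=1), 100.0, atol=1e-6)

    def test_all_false_mask_is_degenerate(self):
        lab = np.ones((8, 8), np.uint8)
        with pytest.raises(DegenerateInputError):
            confusion_matrix(lab, lab, np.zeros((8, 8), bool))

    def test_background_truth_pixels_excluded(self):
        truth = np.array([[0, 1], [0, 2]], np.uint8)
        pred = np.array([[3, 1], [3, 2]], np.uint8)
        cm = confusion_matrix(pred, truth, np.ones((2, 2), bool))
        assert cm.n_pixels == 2


class TestMetrics:
    def test_perfect_matrix(self):
        m = metrics_from_confusion(ConfusionMatrix(np.diag([10, 20, 30])))
        assert m.accuracy_pct == 100.0
        assert m.macro_f1 == 1.0

    def test_hand_tally_matrix_against_formula_oracle(self):
        counts = [[8, 1, 1], [2, 7, 1], [0, 1, 9]]
        m = metrics_from_confusion(ConfusionMatrix(counts))
        acc, macro = brute_force_metrics(counts)
        assert m.accuracy_pct == pytest.approx(80.0, abs=1e-9)
        assert m.accuracy_pct == pytest.approx(acc, abs=1e-9)
        assert m.macro_f1 == pytest.approx(macro, abs=1e-9)

    def test_absent_class_excluded_from_macro_with_flag(self):
        counts = [[5, 0, 0], [0, 0, 0], [0, 0, 5]]  # class 2 absent from truth
        m = metrics_from_confusion(ConfusionMatrix(counts))
        assert m.classes_in_truth == (1, 3)
        assert np.isnan(m.recall[2])
        assert m.macro_f1 == pytest.approx(1.0)

    def test_class_permutation_invariance(self, rng):
        truth = rng.integers(1, 4, (64, 64)).astype(np.uint8)
        pred = rng.integers(1, 4, (64, 64)).astype(np.uint8)
        mask = np.ones_like(truth, bool)
        base = metrics_from_confusion(confusion_matrix(pred, truth, mask))
        perm = {1: 2, 2: 3, 3: 1}
        tp = np.vectorize(perm.get)(truth).astype(np.uint8)
        pp = np.vectorize(perm.get)(pred).astype(np.uint8)
        permuted = metrics_from_confusion(confusion_matrix(pp, tp, mask))
        assert base.accuracy_pct == pytest.approx(permuted.accuracy_pct)
        assert base.macro_f1 == pytest.approx(permuted.macro_f1)

    def test_accuracy_equals_direct_agreement_oracle(self, rng):
        truth = rng.integers(0, 4, (64, 64)).astype(np.uint8)
        pred = rng.integers(1, 4, (64, 64)).astype(np.uint8)
        mask = rng.random((64, 64)) > 0.2
        m = metrics_from_confusion(confusion_matrix(pred, truth, mask))
        sel = mask & (truth > 0)
        direct = 100.0 * (pred[sel] == truth[sel]).mean()
        assert m.accuracy_pct == pytest.approx(direct, abs=1e-9)


class TestAggregateReplicates:
    def test_identical_replicates_zero_sd(self):
        mean, sd = aggregate_replicates({"acc": [0.9, 0.9, 0.9]})
        assert mean["acc"] == pytest.approx(0.9)
        assert sd["acc"] == 0.0

    def test_hand_arithmetic_population_sd(self):
        mean, sd = aggregate_replicates({"f1": [0.80, 0.82, 0.84]})
        assert mean["f1"] == pytest.approx(0.82)
        assert sd["f1"] == pytest.approx(0.0163299, abs=1e-5)

    def test_single_replicate(self):
        mean, sd = aggregate_replicates({"acc": [0.77]})
        assert mean["acc"] == pytest.approx(0.77)
        assert sd["acc"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            aggregate_replicates({"acc": []})


class TestEvalReport:
    def test_mean_within_replicate_range_and_sd_nonnegative(self):
        cms = [
            ConfusionMatrix(np.diag([10, 10, 10])),
            ConfusionMatrix([[9, 1, 0], [0, 10, 0], [0, 0, 10]]),
            ConfusionMatrix([[8, 1, 1], [2, 7, 1], [0, 1, 9]]),
        ]
        reps = [metrics_from_confusion(c) for c in cms]
        rep = EvalReport(modality="IR", replicates=reps).finalize()
        accs = [r.accuracy_pct for r in reps]
        assert min(accs) <= rep.mean["accuracy_pct"] <= max(accs)
        assert all(v >= 0 for v in rep.sd.values())
        assert rep.n_replicates == 3

    def test_comparison_table_bookkeeping(self):
        reps = [metrics_from_confusion(ConfusionMatrix(np.diag([5, 5, 5])))] * 2
        reports = {
            m: EvalReport(modality=m, replicates=list(reps)).finalize()
            for m in ("DF", "IR", "COMBINED")
        }
        table = comparison_table(reports)
        assert len(table) == 3 * 2
        assert set(table["modality"]) == {"DF", "IR", "COMBINED"}


class TestRenderProjection:
    def test_deterministic_output_and_distinct_class_colors(self, tmp_path, rng):
        lab = LabelMap(rng.integers(0, 4, (64, 96)).astype(np.uint8))
        chan = rng.random((3, 64, 96)).astype(np.float32)
        p1 = render_projection(lab, lab, chan, tmp_path / "a.png")
        p2 = render_projection(lab, lab, chan, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()
        from specseg.evaluate import CLASS_COLORS

        assert len({tuple(v) for v in CLASS_COLORS.values()}) == 4

    def test_panel_scales_with_section_grid(self, tmp_path, rng):
        import imageio.v3 as iio

        tall = LabelMap(rng.integers(0, 4, (128, 64)).astype(np.uint8))
        wide = LabelMap(rng.integers(0, 4, (64, 128)).astype(np.uint8))
        pt = render_projection(tall, tall, np.zeros((1, 128, 64)), tmp_path / "t.png")
        pw = render_projection(wide, wide, np.zeros((1, 64, 128)), tmp_path / "w.png")
        ht, wt = iio.imread(pt).shape[:2]
        hw, ww = iio.imread(pw).shape[:2]
        assert ht / wt > hw / ww  # taller section yields a taller panel image
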