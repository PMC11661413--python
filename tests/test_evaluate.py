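"""Metric panel: confusion building, one-vs-rest metrics against brute-force
tallies, rank-statistic AUROC against exhaustive pair counting, fold merging
and the binary AF collapse."""
import numpy as np
import pandas as pd
import pytest

from ppgarr.evaluate import (binary_auroc, collapse_to_binary_af,
                             confusion_from_predictions, macro_auroc,
                             merge_and_average, micro_auroc, per_class_metrics,
                             report_from_predictions)


def brute_force_metrics(cm):
    """Per-segment tally oracle: expand the matrix into labeled pairs."""
    true, pred = [], []
    for i in range(3):
        for j in range(3):
            true += [i] * cm[i, j]
            pred += [j] * cm[i, j]
    true, pred = np.array(true), np.array(pred)
    out = {}
    for cls in range(3):
        tp = np.sum((true == cls) & (pred == cls))
        fn = np.sum((true == cls) & (pred != cls))
        fp = np.sum((true != cls) & (pred == cls))
        tn = np.sum((true != cls) & (pred != cls))
        out[cls] = dict(
            sensitivity=tp / (tp + fn) if tp + fn else np.nan,
            specificity=tn / (tn + fp) if tn + fp else np.nan,
            precision=tp / (tp + fp) if tp + fp else np.nan,
            npv=tn / (tn + fn) if tn + fn else np.nan,
            accuracy=(tp + tn) / len(true))
    return out


def pair_counting_auroc(y, s):
    """Exhaustive Mann-Whitney pair count with half credit for ties."""
    pos = s[np.asarray(y, bool)]
    neg = s[~np.asarray(y, bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_is_diagonal(self):
        y = np.array([0, 1, 2, 1])
        p = np.eye(3)[y]
        cm = confusion_from_predictions(y, p)
        assert np.array_equal(cm, np.diag([1, 2, 1]))

    def test_degenerate_predictor_single_column(self):
        y = np.array([0, 1, 2])
        p = np.tile([0.8, 0.1, 0.1], (3, 1))
        cm = confusion_from_predictions(y, p)
        assert cm[:, 0].sum() == 3 and cm[:, 1:].sum() == 0

    def test_count_conservation_and_tie_break(self):
        y = np.array([2, 2])
        p = np.array([[0.4, 0.4, 0.2], [1 / 3, 1 / 3, 1 / 3]])
        cm = confusion_from_predictions(y, p)
        assert cm.sum() == 2
        assert cm[2, 0] == 2  # ties break toward the lower class index

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_predictions(np.array([0]), np.eye(3))


class TestPerClassMetrics:
    def test_worked_example(self):
        cm = np.array([[90, 5, 5], [5, 45, 0], [10, 0, 40]])
        m = per_class_metrics(cm)
        assert m.loc["AF", "sensitivity"] == pytest.approx(0.90)
        assert m.loc["AF", "specificity"] == pytest.approx(145 / 150)
        assert m.loc["AF", "precision"] == pytest.approx(0.90)
        assert m.loc["PACPVC", "sensitivity"] == pytest.approx(0.80)

    def test_diagonal_all_ones(self):
        m = per_class_metrics(np.diag([5, 3, 2]))
        assert np.allclose(m.to_numpy(dtype=float), 1.0)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            cm = rng.integers(0, 40, size=(3, 3))
            if cm.sum() == 0:
                continue
            m = per_class_metrics(cm)
            ref = brute_force_metrics(cm)
            for cls, name in enumerate(("NSR", "AF", "PACPVC")):
                for metric, val in ref[cls].items():
                    got = m.loc[name, metric]
                    assert (np.isnan(val) and np.isnan(got)) or \
                        got == pytest.approx(val)

    def test_zero_denominator_is_nan_not_zero(self):
        cm = np.array([[10, 0, 0], [0, 0, 0], [0, 0, 0]])  # no true AF
        m = per_class_metrics(cm)
        assert np.isnan(m.loc["AF", "sensitivity"])
        assert np.isnan(m.loc["AF", "precision"])
        assert m.loc["AF", "specificity"] == 1.0


class TestAuroc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert binary_auroc(y, s) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, size=10_000)
        p = rng.dirichlet(np.ones(3), size=10_000)
        assert macro_auroc(y, p) == pytest.approx(0.5, abs=0.02)

    def test_toy_set_matches_pair_counting(self):
        y = np.array([0, 1, 2, 1])
        p = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3],
                      [0.3, 0.3, 0.4], [0.4, 0.4, 0.2]])
        expected = np.mean([pair_counting_auroc(y == c, p[:, c])
                            for c in range(3)])
        assert macro_auroc(y, p) == pytest.approx(expected)

    def test_random_instances_match_pair_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 3, size=n)
            if len(np.unique(y)) < 3:
                continue
            p = np.round(rng.dirichlet(np.ones(3), size=n), 2)  # force ties
            expected = np.mean([pair_counting_auroc(y == c, p[:, c])
                                for c in range(3)])
            assert macro_auroc(y, p) == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, size=200)
        p = rng.dirichlet(np.ones(3), size=200)
        before = macro_auroc(y, p)
        assert macro_auroc(y, np.exp(3 * p)) == pytest.approx(before)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        p = np.column_stack([1 - np.r_[0.1, 0.2, 0.8, 0.9],
                             np.r_[0.1, 0.2, 0.8, 0.9], np.zeros(4)])
        with pytest.warns(UserWarning, match="PACPVC"):
            val = macro_auroc(y, p)
        assert val == 1.0

    def test_micro_auroc_flattened(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, size=60)
        p = rng.dirichlet(np.ones(3), size=60)
        flat_y = np.concatenate([(y == c) for c in range(3)])
        flat_s = np.concatenate([p[:, c] for c in range(3)])
        assert micro_auroc(y, p) == pytest.approx(
            pair_counting_auroc(flat_y, flat_s))


class TestMergeAndAverage:
    def test_zero_fold_is_identity(self):
        cm1 = np.array([[8, 1, 0], [1, 5, 1], [0, 1, 3]])
        out = merge_and_average(cm1, np.zeros((3, 3), int))
        pd.testing.assert_frame_equal(out["metrics_merged"],
                                      per_class_metrics(cm1))

    def test_sum_conservation(self):
        rng = np.random.default_rng(5)
        a, b = rng.integers(0, 20, (3, 3)), rng.integers(0, 20, (3, 3))
        out = merge_and_average(a, b)
        assert out["cm_merged"].sum() == a.sum() + b.sum()

    def test_scale_invariance(self):
        cm = np.array([[8, 1, 0], [1, 5, 1], [0, 1, 3]])
        out = merge_and_average(cm, cm)
        pd.testing.assert_frame_equal(out["metrics_merged"],
                                      per_class_metrics(cm))

    def test_pool_average_skips_undefined(self):
        cm = np.array([[8, 1, 0], [1, 5, 1], [0, 1, 3]])
        pool = np.array([[20, 2, 1], [0, 0, 0], [0, 0, 0]])  # NSR-only pool
        out = merge_and_average(cm, cm, pool)
        merged = out["metrics_merged"]
        final = out["metrics_final"]
        # AF sensitivity undefined on the pool -> final equals merged value
        assert final.loc["AF", "sensitivity"] == \
            pytest.approx(merged.loc["AF", "sensitivity"])
        # NSR sensitivity defined in both -> unweighted mean
        pool_m = out["metrics_nsr_pool"]
        assert final.loc["NSR", "sensitivity"] == pytest.approx(
            (merged.loc["NSR", "sensitivity"]
             + pool_m.loc["NSR", "sensitivity"]) / 2)


class TestBinaryCollapse:
    def test_diagonal_stays_diagonal(self):
        out = collapse_to_binary_af(np.diag([10, 5, 3]))
        assert np.array_equal(out["cm_binary"], np.diag([13, 5]))

    def test_af_counts_preserved(self):
        rng = np.random.default_rng(6)
        cm = rng.integers(0, 30, size=(3, 3))
        out = collapse_to_binary_af(cm)
        b = out["cm_binary"]
        assert b[1, 1] == cm[1, 1]
        assert b[1, :].sum() == cm[1, :].sum()
        assert b[:, 1].sum() == cm[:, 1].sum()

    def test_binary_accuracy_at_least_three_class(self):
        """Folding can only convert NSR<->PAC/PVC confusions into hits."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            cm = rng.integers(0, 25, size=(3, 3))
            if cm.sum() == 0:
                continue
            acc3 = np.trace(cm) / cm.sum()
            out = collapse_to_binary_af(cm)
            assert out["metrics"]["accuracy"] >= acc3 - 1e-12

    def test_from_labels_with_auroc(self):
        y = np.array([0, 1, 2, 1, 0])
        p = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.1, 0.7],
                      [0.3, 0.6, 0.1], [0.6, 0.3, 0.1]])
        out = collapse_to_binary_af(true_labels=y, probabilities=p)
        assert out["auroc"] == 1.0
        assert out["metrics"]["accuracy"] == 1.0


class TestReportFromPredictions:
    def test_panel_assembles(self):
        rng = np.random.default_rng(8)
        rows = []
        for pool in ("fold1", "fold2", "nsr_only"):
            for i in range(30):
                cls = 0 if pool == "nsr_only" else int(rng.integers(0, 3))
                p = rng.dirichlet(np.ones(3) + 5 * np.eye(3)[cls])
                rows.append({"segment_id": f"{pool}_{i}", "true_label": cls,
                             "p_nsr": p[0], "p_af": p[1], "p_pacpvc": p[2],
                             "pool": pool})
        panel = report_from_predictions(pd.DataFrame(rows))
        report = panel["report"]
        assert report.n_segments == 90
        assert 0.5 < report.macro_auroc <= 1.0
        assert set(report.per_class.index) == {"NSR", "AF", "PACPVC"}
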