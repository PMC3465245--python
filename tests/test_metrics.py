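"""Metric tests against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import random_instance
from idpmeta.metrics import (
    THRESHOLD_GRID,
    bootstrap_mae,
    confusion_at,
    kfold_residue_bins,
    mcc,
    roc_auc,
    sw,
    sw_grid,
    sww,
    wilcoxon_paired,
    write_evaluation_report,
)
from idpmeta.types import (
    DISORDERED,
    ORDERED,
    UNKNOWN,
    ClassWeights,
    ConfusionCounts,
    DisorderLabels,
    InputError,
    class_weights,
)

D, O = DISORDERED, ORDERED


# ------------------------------------------------------------------ oracles

def brute_confusion(scores, states, t):
    tp = tn = fp = fn = 0
    for s, y in zip(scores, states):
        if y == UNKNOWN or math.isnan(s):
            continue
        pred = s >= t
        if y == D:
            tp, fn = tp + pred, fn + (not pred)
        else:
            fp, tn = fp + pred, tn + (not pred)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def brute_sw(scores, states, t, w):
    c = brute_confusion(scores, states, t)
    num = w.w_disorder * c.tp - w.w_order * c.fp + w.w_order * c.tn - w.w_disorder * c.fn
    den = w.w_disorder * (c.tp + c.fn) + w.w_order * (c.tn + c.fp)
    return num / den


def concordance_auc(scores, states):
    """Pairwise concordance: concordant pairs + half ties over cross pairs."""
    dis = [s for s, y in zip(scores, states) if y == D]
    ordd = [s for s, y in zip(scores, states) if y == O]
    num = sum((sd > so) + 0.5 * (sd == so) for sd in dis for so in ordd)
    return num / (len(dis) * len(ordd))


# ----------------------------------------------------------------- confusion

@pytest.mark.parametrize(
    "scores, states, t, expected",
    [
        ([0.9, 0.1], [D, O], 0.5, (1, 1, 0, 0)),
        ([0.6, 0.6, 0.2], [D, O, D], 0.5, (1, 0, 1, 1)),
    ],
)
def test_confusion_counts(scores, states, t, expected):
    c = confusion_at(np.array(scores), np.array(states, dtype=np.int8), t)
    assert (c.tp, c.tn, c.fp, c.fn) == expected


def test_threshold_zero_calls_everything_disordered(rng):
    scores, states = random_instance(rng)
    c = confusion_at(scores, states, 0.0)
    assert c.fn == 0 and c.tn == 0


def test_empty_input_is_an_error():
    with pytest.raises(InputError):
        confusion_at(np.array([]), np.array([], dtype=np.int8), 0.5)


# ------------------------------------------------------------------ Sw / MCC

class TestSw:
    w = ClassWeights(0.5, 0.5)

    def test_perfect_prediction_scores_one(self):
        assert sw(ConfusionCounts(tp=7, tn=93, fp=0, fn=0), ClassWeights(0.93, 0.07)) == 1.0

    def test_all_disordered_prediction_scores_zero(self):
        # with weights taken from the same reference, calling everything
        # disordered has zero expected reward
        states = np.array([D] * 30 + [O] * 70, dtype=np.int8)
        cw = class_weights(DisorderLabels("x", states))
        c = confusion_at(np.ones(100), states, 0.5)
        assert c.tn == 0 and c.fn == 0
        assert sw(c, cw) == pytest.approx(0.0, abs=1e-12)

    def test_worked_arithmetic(self):
        assert sw(ConfusionCounts(tp=30, fp=10, tn=40, fn=20), self.w) == pytest.approx(0.4)

    def test_printed_denominator_variant_does_not_reach_one(self):
        # the compatibility normalization under-rewards perfect prediction
        # on imbalanced references
        v = sw(
            ConfusionCounts(tp=7, tn=93, fp=0, fn=0),
            ClassWeights(0.93, 0.07),
            printed_denominator=True,
        )
        assert v != 1.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            scores, states = random_instance(rng, n_max=50)
            cw = class_weights(DisorderLabels("x", states))
            t = float(rng.choice(THRESHOLD_GRID))
            got = sw(confusion_at(scores, states, t), cw)
            assert got == pytest.approx(brute_sw(scores, states, t, cw), abs=1e-12)

    def test_random_predictor_scores_near_zero(self):
        # expectation of Sw for label-independent calls is 0 at any call rate
        g = np.random.default_rng(7)
        n = 100_000
        states = np.where(g.random(n) < 0.2, D, O).astype(np.int8)
        cw = class_weights(DisorderLabels("x", states))
        for p in (0.1, 0.3, 0.7):
            calls = (g.random(n) < p).astype(float)
            assert abs(sw(confusion_at(calls, states, 0.5), cw)) < 0.02


class TestMcc:
    def test_perfect_is_one(self):
        assert mcc(ConfusionCounts(tp=10, tn=90, fp=0, fn=0)) == pytest.approx(1.0)

    def test_no_association_is_zero(self):
        assert mcc(ConfusionCounts(tp=25, tn=25, fp=25, fn=25)) == 0.0

    def test_worked_arithmetic(self):
        got = mcc(ConfusionCounts(tp=30, fp=10, tn=40, fn=20))
        assert got == pytest.approx(1000 / math.sqrt(40 * 50 * 50 * 60))

    def test_zero_marginal_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=5, fp=0, fn=5)) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_swap_invariance(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        a = mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        b = mcc(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert a == pytest.approx(b)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(20):
            scores, states = random_instance(rng, n_max=50)
            pred = scores >= 0.5
            got = mcc(confusion_at(scores, states, 0.5))
            assert got == pytest.approx(matthews_corrcoef(states == D, pred), abs=1e-12)


# ----------------------------------------------------------------------- ROC

class TestRocAuc:
    def test_perfect_separator(self):
        states = np.array([D, D, O, O], dtype=np.int8)
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), states)
        assert auc == 1.0

    def test_constant_scores_are_random(self):
        states = np.array([D, O, D, O], dtype=np.int8)
        _, auc = roc_auc(np.full(4, 0.5), states)
        assert auc == 0.5

    def test_worked_example(self):
        states = np.array([D, O, D, O], dtype=np.int8)
        _, auc = roc_auc(np.array([0.9, 0.8, 0.4, 0.3]), states)
        assert auc == 0.75

    def test_endpoints_present(self, rng):
        scores, states = random_instance(rng)
        curve, _ = roc_auc(scores, states)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(InputError):
            roc_auc(np.array([0.1, 0.9]), np.array([D, D], dtype=np.int8))

    def test_equals_concordance_oracle(self, rng):
        for _ in range(200):
            scores, states = random_instance(rng)
            _, auc = roc_auc(scores, states)
            assert auc == pytest.approx(concordance_auc(scores, states), abs=1e-12)

    def test_invariant_under_monotone_transforms(self, rng):
        scores, states = random_instance(rng)
        _, base = roc_auc(scores, states)
        _, via_exp = roc_auc(np.exp(scores) / math.e, states)
        ranks = stats.rankdata(scores) / (len(scores) + 1)
        _, via_rank = roc_auc(ranks, states)
        assert base == pytest.approx(via_exp, abs=1e-12)
        assert base == pytest.approx(via_rank, abs=1e-12)


# ---------------------------------------------------------------------- Sww

class TestSww:
    def test_constant_scores_give_zero(self):
        states = np.array([D, O, D, O, O], dtype=np.int8)
        cw = class_weights(DisorderLabels("x", states))
        assert sww(np.full(5, 0.5), states, cw) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_scores_match_grid_enumeration(self):
        states = np.array([D, D, O, O], dtype=np.int8)
        scores = np.array([1.0, 1.0, 0.0, 0.0])
        cw = class_weights(DisorderLabels("x", states))
        expected = np.mean(
            [brute_sw(scores, states, t, cw) for t in THRESHOLD_GRID]
        )
        assert sww(scores, states, cw) == pytest.approx(expected, abs=1e-12)

    def test_equals_grid_mean_oracle(self, rng):
        for _ in range(50):
            scores, states = random_instance(rng, n_max=60)
            cw = class_weights(DisorderLabels("x", states))
            expected = np.mean([brute_sw(scores, states, t, cw) for t in THRESHOLD_GRID])
            assert sww(scores, states, cw) == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= sww(scores, states, cw) <= 1.0

    def test_sw_grid_matches_pointwise_confusion(self, rng):
        scores, states = random_instance(rng)
        cw = class_weights(DisorderLabels("x", states))
        grid = sw_grid(scores, states, cw)
        for t, v in zip(THRESHOLD_GRID, grid):
            assert v == pytest.approx(sw(confusion_at(scores, states, t), cw), abs=1e-12)


def test_unknown_states_do_not_affect_metrics(rng):
    scores, states = random_instance(rng)
    cw = class_weights(DisorderLabels("x", states))
    pad_scores = np.concatenate([scores, rng.random(30)])
    pad_states = np.concatenate([states, np.full(30, UNKNOWN, dtype=np.int8)])
    assert sw(confusion_at(pad_scores, pad_states, 0.4), cw) == sw(
        confusion_at(scores, states, 0.4), cw
    )
    assert roc_auc(pad_scores, pad_states)[1] == roc_auc(scores, states)[1]
    assert sww(pad_scores, pad_states, cw) == sww(scores, states, cw)


# ------------------------------------------------------------------ bootstrap

class TestBootstrap:
    @staticmethod
    def mean_metric(data):
        return float(np.mean([v for v in data]))

    def test_identical_targets_have_zero_mae(self):
        mean, mae = bootstrap_mae([1.0] * 6, self.mean_metric, seed=0)
        assert mae == 0.0 and mean == 1.0

    def test_same_seed_reproduces(self):
        data = [0.1, 0.5, 0.9, 0.2, 0.7]
        a = bootstrap_mae(data, self.mean_metric, seed=42)
        b = bootstrap_mae(data, self.mean_metric, seed=42)
        assert a == b

    def test_matches_exhaustive_enumeration_of_small_subsets(self):
        # 5 targets at fraction 0.8 -> exactly the 5 leave-one-out subsets
        data = [0.0, 1.0, 2.0, 3.0, 10.0]
        full = np.mean(data)
        subsets = [np.mean(s) for s in itertools.combinations(data, 4)]
        exact_mae = np.mean([abs(v - full) for v in subsets])
        _, mae = bootstrap_mae(data, self.mean_metric, reps=5000, seed=3)
        assert mae == pytest.approx(exact_mae, rel=0.05)

    def test_failing_subsamples_are_redrawn(self):
        # metric fails whenever target 0 is excluded; the draw is retried
        def picky(data):
            if 99.0 not in data:
                raise InputError("single class")
            return float(np.mean(data))

        mean, mae = bootstrap_mae([99.0, 1.0, 1.0], picky, reps=50, seed=0)
        assert np.isfinite(mean) and np.isfinite(mae)

    def test_too_few_targets(self):
        with pytest.raises(InputError):
            bootstrap_mae([1.0], self.mean_metric)


# ------------------------------------------------------------------- Wilcoxon

class TestWilcoxon:
    def test_identical_vectors_give_one(self):
        assert wilcoxon_paired([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]) == 1.0

    def test_six_positive_differences_exact(self):
        # all 6 differences positive: the most extreme of the 2^6 sign
        # assignments, two-sided p = 2/64
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [0.5, 1.5, 2.5, 3.0, 4.0, 5.0]
        assert wilcoxon_paired(a, b) == pytest.approx(2 / 64)

    def test_two_sided_symmetry(self, rng):
        a, b = rng.random(12), rng.random(12)
        assert wilcoxon_paired(a, b) == pytest.approx(wilcoxon_paired(b, a))

    def test_too_few_nonzero_differences(self):
        with pytest.raises(InputError, match=">= 5"):
            wilcoxon_paired([1, 2, 3, 4, 4], [0, 1, 2, 3, 4])

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.random(40)
        b = a + rng.normal(0.2, 0.1, 40)
        p = wilcoxon_paired(a, b)
        assert 0.0 < p < 0.01


# --------------------------------------------------------------------- kfold

class TestKfold:
    def test_divisible(self):
        bins = kfold_residue_bins(100, k=10, seed=0)
        assert sorted(np.bincount(bins, minlength=10)) == [10] * 10

    def test_remainder(self):
        sizes = np.bincount(kfold_residue_bins(101, k=10, seed=0), minlength=10)
        assert sorted(sizes) == [10] * 9 + [11]

    def test_every_residue_assigned_once_and_reproducible(self):
        a = kfold_residue_bins(57, k=10, seed=9)
        b = kfold_residue_bins(57, k=10, seed=9)
        assert a.shape == (57,) and np.array_equal(a, b)
        assert set(np.unique(a)) == set(range(10))

    def test_k_too_small(self):
        with pytest.raises(InputError):
            kfold_residue_bins(100, k=1)


def test_report_writer_layout(tmp_path):
    path = tmp_path / "report.tsv"
    write_evaluation_report(
        path,
        [{"method": "consA", "Sw": 0.6081, "MCC": 0.475, "AUC": 0.868, "sensitivity": 0.7}],
    )
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == [
        "method", "Sw", "Sw_mae", "MCC", "AUC", "AUC_mae", "sensitivity", "specificity",
    ]
    assert lines[1].split("\t") == ["consA", "0.608", "-", "0.475", "0.868", "-", "0.700", "-"]
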