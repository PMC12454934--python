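"""Metric correctness against independent scalar/brute-force oracles."""

import math

import numpy as np
import pytest

from targetpep.infer import Segment
from targetpep.metrics import (
    ConfusionCounts,
    cleavage_accuracy,
    evaluate_dataset,
    f1,
    mcc,
    sov,
)
from targetpep.seqio import SignalAnnotation


def mcc_oracle(tp, fp, tn, fn):
    """Straight transcription of the correlation formula."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1_oracle(tp, fp, tn, fn):
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def sov_oracle(observed, predicted):
    """Brute-force pairing enumeration using explicit residue sets."""
    total = 0.0
    denom = 0
    for obs in observed:
        obs_set = set(range(obs[0], obs[1] + 1))
        denom += len(obs_set)
        best_pred, best_ov = None, 0
        for pred in sorted(predicted):
            ov = len(obs_set & set(range(pred[0], pred[1] + 1)))
            if ov > best_ov:
                best_pred, best_ov = pred, ov
        if best_pred is None:
            continue
        pred_set = set(range(best_pred[0], best_pred[1] + 1))
        union = len(obs_set | pred_set)
        alpha = 1 - abs(len(obs_set) - len(pred_set)) / union
        total += min(best_ov, alpha * union)
    return total / denom


def random_segment_set(rng, max_segments=5, protein_length=200,
                       max_len=50):
    spans = []
    cursor = 1
    for _ in range(rng.integers(1, max_segments + 1)):
        start = cursor + int(rng.integers(0, 30))
        length = int(rng.integers(1, max_len + 1))
        end = min(start + length - 1, protein_length)
        if start > protein_length:
            break
        spans.append((start, end))
        cursor = end + 2
    return spans


# ---------------------------------------------------------------------------
# MCC / F1
# ---------------------------------------------------------------------------

def test_mcc_perfect_chance_and_worked_example():
    assert mcc(ConfusionCounts(5, 0, 5, 0)) == 1.0
    assert mcc(ConfusionCounts(5, 5, 5, 5)) == 0.0
    # worked confusion table, verified against the scalar oracle
    counts = ConfusionCounts(45, 5, 40, 10)
    assert mcc(counts) == pytest.approx(mcc_oracle(45, 5, 40, 10))
    assert mcc(counts) == pytest.approx(0.7035, abs=1e-4)


def test_mcc_conventions():
    with pytest.raises(ValueError):
        mcc(ConfusionCounts(0, 0, 0, 0))
    # zero marginal -> 0 by convention
    assert mcc(ConfusionCounts(0, 0, 10, 5)) == 0.0


def test_mcc_matches_oracle_on_random_tables(rng):
    for _ in range(500):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 200, 4))
        if tp + fp + tn + fn == 0:
            continue
        counts = ConfusionCounts(tp, fp, tn, fn)
        assert mcc(counts) == pytest.approx(mcc_oracle(tp, fp, tn, fn))
        assert -1.0 <= mcc(counts) <= 1.0
        # relabeling both classes swaps TP<->TN and FP<->FN
        assert mcc(counts) == pytest.approx(
            mcc(ConfusionCounts(tn, fn, tp, fp))
        )


def test_f1_worked_example_and_conventions():
    counts = ConfusionCounts(45, 5, 40, 10)
    assert f1(counts) == pytest.approx(f1_oracle(45, 5, 40, 10))
    assert f1(counts) == pytest.approx(0.8571, abs=1e-4)
    assert f1(ConfusionCounts(0, 0, 5, 10)) == 0.0


def test_f1_equals_precision_when_balanced(rng):
    # precision == recall == p implies F1 == p
    for _ in range(100):
        tp = int(rng.integers(1, 100))
        err = int(rng.integers(0, 100))
        counts = ConfusionCounts(tp, err, 0, err)
        p = tp / (tp + err)
        assert f1(counts) == pytest.approx(p)


def test_f1_matches_oracle_on_random_tables(rng):
    for _ in range(500):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 200, 4))
        counts = ConfusionCounts(tp, fp, tn, fn)
        assert f1(counts) == pytest.approx(f1_oracle(tp, fp, tn, fn))


# ---------------------------------------------------------------------------
# Cleavage-site accuracy
# ---------------------------------------------------------------------------

def test_cleavage_accuracy_denominator_is_predictions():
    preds = {f"P{i}": 22 for i in range(7)}
    preds.update({f"Q{i}": 30 for i in range(3)})
    truths = {f"P{i}": 22 for i in range(7)}
    truths.update({f"Q{i}": 31 for i in range(3)})  # off by one: wrong
    assert cleavage_accuracy(preds, truths) == pytest.approx(0.7)


def test_cleavage_accuracy_not_applicable_when_never_predicted():
    assert cleavage_accuracy({"P1": None}, {"P1": 22}) is None


# ---------------------------------------------------------------------------
# SOV
# ---------------------------------------------------------------------------

def test_sov_spot_values():
    assert sov([(11, 20)], [(16, 25)]) == pytest.approx(0.5)
    assert sov([(1, 10)], [(1, 10)]) == 1.0
    assert sov([(1, 10)], [(50, 60)]) == 0.0
    assert sov([(5, 14), (30, 39)], [(5, 14), (30, 39)]) == 1.0


def test_sov_undefined_for_empty_observed():
    with pytest.raises(ValueError):
        sov([], [(1, 5)])


def test_sov_matches_bruteforce_oracle(rng):
    for _ in range(300):
        obs = random_segment_set(rng)
        pred = random_segment_set(rng)
        if not obs:
            continue
        assert sov(obs, pred) == pytest.approx(sov_oracle(obs, pred))
        assert 0.0 <= sov(obs, pred) <= 1.0


def test_sov_shift_invariance(rng):
    for _ in range(50):
        obs = random_segment_set(rng)
        pred = random_segment_set(rng)
        if not obs:
            continue
        shift = int(rng.integers(1, 100))
        obs_s = [(s + shift, e + shift) for s, e in obs]
        pred_s = [(s + shift, e + shift) for s, e in pred]
        assert sov(obs, pred) == pytest.approx(sov(obs_s, pred_s))


def test_sov99_mode_perfect_and_disjoint():
    assert sov([(1, 10)], [(1, 10)], mode="sov99") == 1.0
    assert sov([(1, 10)], [(50, 60)], mode="sov99") == 0.0
    with pytest.raises(ValueError):
        sov([(1, 10)], [(1, 10)], mode="bogus")


# ---------------------------------------------------------------------------
# Dataset-level evaluation
# ---------------------------------------------------------------------------

def _perfect_predictions(truths):
    return {
        pid: [Segment(pid, a.signal_class, a.start, a.end)
              for a in anns]
        for pid, anns in truths.items()
    }


def test_evaluate_dataset_perfect_predictions():
    truths = {
        "A": [SignalAnnotation("A", "SP", 1, 22)],
        "B": [SignalAnnotation("B", "CH", 1, 40),
              SignalAnnotation("B", "TH", 41, 60)],
        "C": [SignalAnnotation("C", "NLS", 10, 20),
              SignalAnnotation("C", "NLS", 50, 60)],
        "D": [SignalAnnotation("D", "ER", 97, 100)],
        "E": [],
    }
    lengths = {"A": 120, "B": 150, "C": 100, "D": 100, "E": 80}
    table = evaluate_dataset(_perfect_predictions(truths), truths, lengths)
    for cls in ("SP", "CH", "TH", "ER"):
        assert table.loc[cls, "mcc"] == 1.0
        assert table.loc[cls, "f1"] == 1.0
        assert table.loc[cls, "cleavage_accuracy"] == 1.0
    assert table.loc["NLS", "sov"] == 1.0


def test_evaluate_dataset_requires_aligned_proteins():
    truths = {"A": [SignalAnnotation("A", "SP", 1, 10)]}
    with pytest.raises(ValueError, match="missing"):
        evaluate_dataset({}, truths, {"A": 50})


def test_evaluate_dataset_shuffled_predictions_have_low_mcc(rng):
    # class-shuffled truths should score near chance on average
    classes = ["SP", "MT", "NLS", "ER"]
    truths = {}
    lengths = {}
    for i in range(80):
        pid = f"P{i}"
        cls = classes[i % 4]
        truths[pid] = [SignalAnnotation(pid, cls, 10, 30)]
        lengths[pid] = 120
    mccs = []
    for _ in range(20):
        perm = rng.permutation(80)
        preds = {}
        for i in range(80):
            src = f"P{perm[i]}"
            preds[f"P{i}"] = [
                Segment(f"P{i}", a.signal_class, a.start, a.end)
                for a in truths[src]
            ]
        table = evaluate_dataset(preds, truths, lengths)
        mccs.append(table.loc[classes, "mcc"].mean())
    assert abs(float(np.mean(mccs))) < 0.15


def test_sov_corpus_pooling_weights_by_segment_length():
    truths = {
        "A": [SignalAnnotation("A", "NLS", 1, 10)],     # len 10, missed
        "B": [SignalAnnotation("B", "NLS", 1, 40)],     # len 40, perfect
    }
    preds = {
        "A": [],
        "B": [Segment("B", "NLS", 1, 40)],
    }
    lengths = {"A": 50, "B": 60}
    per_protein = evaluate_dataset(preds, truths, lengths)
    pooled = evaluate_dataset(preds, truths, lengths, sov_pooling="corpus")
    assert per_protein.loc["NLS", "sov"] == pytest.approx(0.5)
    assert pooled.loc["NLS", "sov"] == pytest.approx(40 / 50)
    with pytest.raises(ValueError, match="sov_pooling"):
        evaluate_dataset(preds, truths, lengths, sov_pooling="bogus")
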