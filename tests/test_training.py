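"""Dual losses, loss weights, and the freezing training loop."""

import numpy as np
import pytest

from targetpep._autodiff import Tensor
from targetpep.alphabet import CLASS_INDEX, SIGNAL_CLASSES
from targetpep.augment import AugmentationConfig
from targetpep.labels import build_label_matrix, protein_label_vector
from targetpep.model import ModelConfig, SignalMatrix, SignalModel
from targetpep.seqio import ProteinRecord, SignalAnnotation
from targetpep.simulate import SyntheticConfig, generate_dataset
from targetpep.training import (
    LossWeights,
    TrainingConfig,
    _protein_loss_tensor,
    _residue_loss_tensor,
    compute_loss_weights,
    protein_loss,
    residue_loss,
    train,
)

TINY = ModelConfig(d_model=16, n_layers=1, n_heads=2, d_ff=32,
                   fragment_length=64, overlap=16, conv_channels=4,
                   conv_kernels=(3,), mlp_hidden=8, seed=0)


def _one_position_case(strengths):
    record = ProteinRecord("P1", "A")
    lm = build_label_matrix(record, [SignalAnnotation("P1", "SP", 1, 1)])
    matrix = np.array(strengths, dtype=float).reshape(8, 1)
    return SignalMatrix("P1", matrix), lm


def test_residue_loss_uniform_half_hand_value():
    # 8 strengths of 0.5 -> OTHER 0.5, renormalised p(SP) = 1/9
    sm, lm = _one_position_case([0.5] * 8)
    assert residue_loss(sm, lm) == pytest.approx(-np.log(1 / 9))


def test_residue_loss_vanishes_for_confident_truth():
    eps = 1e-6
    strengths = [eps] * 8
    strengths[CLASS_INDEX["SP"]] = 1 - eps
    sm, lm = _one_position_case(strengths)
    assert residue_loss(sm, lm) < 1e-4


def test_residue_loss_weight_scale_invariance(rng):
    sm, lm = _one_position_case(rng.uniform(0.05, 0.95, 8))
    w = rng.uniform(0.5, 2.0, 9)
    assert residue_loss(sm, lm, w) == pytest.approx(
        residue_loss(sm, lm, 2 * w)
    )


def test_protein_loss_hand_values():
    record = ProteinRecord("P1", "AAAA")
    lm = build_label_matrix(record, [SignalAnnotation("P1", "SP", 1, 2)])
    vec = protein_label_vector(lm)
    # all rows at 0.5 -> every score 0.5 -> weighted mean of -log 0.5
    sm = SignalMatrix("P1", np.full((8, 4), 0.5))
    assert protein_loss(sm, vec) == pytest.approx(-np.log(0.5))
    # a confident correct SP peak drives the loss near zero
    m = np.full((8, 4), 0.001)
    m[CLASS_INDEX["SP"], 1] = 0.999
    assert protein_loss(SignalMatrix("P1", m), vec) < 0.01


def test_protein_loss_multilabel_ch_th_feasible():
    record = ProteinRecord("P1", "A" * 10)
    anns = [SignalAnnotation("P1", "CH", 1, 5),
            SignalAnnotation("P1", "TH", 6, 8)]
    vec = protein_label_vector(build_label_matrix(record, anns))
    m = np.full((8, 10), 0.001)
    m[CLASS_INDEX["CH"], 2] = 0.999
    m[CLASS_INDEX["TH"], 6] = 0.999
    assert protein_loss(SignalMatrix("P1", m), vec) < 0.01


def test_losses_nonnegative_random(rng):
    for _ in range(50):
        L = int(rng.integers(1, 30))
        m = rng.uniform(0.01, 0.99, size=(8, L))
        record = ProteinRecord("P1", "A" * L)
        lm = build_label_matrix(record, [])
        sm = SignalMatrix("P1", m)
        assert residue_loss(sm, lm) >= 0
        assert protein_loss(sm, protein_label_vector(lm)) >= 0


def test_loss_gradients_match_finite_differences(rng):
    # 3-residue toy input, both losses, every strength entry
    labels = np.zeros((1, 3, 9))
    labels[0, 0, CLASS_INDEX["SP"]] = 1
    labels[0, 1, CLASS_INDEX["SP"]] = 1
    labels[0, 2, 8] = 1
    vec = np.zeros((1, 9))
    vec[0, CLASS_INDEX["SP"]] = 1
    mask = np.ones((1, 3), dtype=bool)
    wr = rng.uniform(0.5, 2, 9)
    wp = rng.uniform(0.5, 2, 9)
    s0 = rng.uniform(0.1, 0.9, size=(1, 3, 8))

    def loss_of(data):
        t = Tensor(data, requires_grad=True)
        loss = _residue_loss_tensor(t, labels, wr, mask) + \
            _protein_loss_tensor(t, vec, wp, mask)
        return t, loss

    t, loss = loss_of(s0.copy())
    loss.backward()
    analytic = t.grad
    numeric = np.zeros_like(s0)
    eps = 1e-7
    for idx in np.ndindex(*s0.shape):
        up = s0.copy(); up[idx] += eps
        dn = s0.copy(); dn[idx] -= eps
        numeric[idx] = (
            float(loss_of(up)[1].data) - float(loss_of(dn)[1].data)
        ) / (2 * eps)
    np.testing.assert_allclose(analytic, numeric, atol=1e-5, rtol=1e-4)


def test_compute_loss_weights_balance_and_monotonicity():
    records = [ProteinRecord(f"P{i}", "A" * 100) for i in range(20)]
    anns = []
    for i in range(18):
        anns.append(SignalAnnotation(f"P{i}", "SP", 1, 20))
    anns.append(SignalAnnotation("P18", "NES", 5, 24))
    lms = [build_label_matrix(r, [a for a in anns if a.protein_id == r.id])
           for r in records]
    with pytest.warns(UserWarning, match="absent"):
        weights = compute_loss_weights(lms)
    sp, nes = CLASS_INDEX["SP"], CLASS_INDEX["NES"]
    assert weights.class_weights[nes] > weights.class_weights[sp]
    assert weights.residue_weights[nes] > weights.residue_weights[sp]
    # absent classes sit at the clamp maximum
    assert weights.class_weights[CLASS_INDEX["ER"]] == 10.0
    # determinism
    with pytest.warns(UserWarning):
        again = compute_loss_weights(lms)
    np.testing.assert_array_equal(weights.class_weights,
                                  again.class_weights)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(np.ones(8), np.ones(9))
    with pytest.raises(ValueError):
        LossWeights(np.ones(9), -np.ones(9))


@pytest.fixture(scope="module")
def micro_dataset():
    config = SyntheticConfig(
        n_per_class={c: 3 for c in SIGNAL_CLASSES},
        long_fraction=0.0,
        seed=21,
    )
    records, annotations = generate_dataset(config)
    folds = {r.id: (i % 3) + 1 for i, r in enumerate(records)}
    return records, annotations, folds


def test_single_epoch_run_and_history(micro_dataset):
    records, annotations, folds = micro_dataset
    model = SignalModel(TINY)
    config = TrainingConfig(max_epochs=1, patience=5, val_fold=1, seed=0,
                            augmentation=None)
    model, history = train(model, records, annotations, folds, config)
    assert len(history) == 1
    assert {"epoch", "train_loss", "val_total_loss"} <= set(history.columns)


def test_zero_patience_freezes_every_head_quickly(micro_dataset):
    records, annotations, folds = micro_dataset
    model = SignalModel(TINY)
    # with zero learning rate nothing improves after epoch 1, so patience 0
    # freezes every head at its first non-improving epoch
    config = TrainingConfig(max_epochs=6, patience=0, val_fold=1, seed=0,
                            learning_rate=0.0, augmentation=None)
    model, history = train(model, records, annotations, folds, config)
    last = history.iloc[-1]
    assert all(last[f"frozen_{c}"] for c in SIGNAL_CLASSES)
    assert len(history) == 2


def test_frozen_heads_stay_bit_identical(micro_dataset):
    records, annotations, folds = micro_dataset
    model = SignalModel(TINY)
    config = TrainingConfig(max_epochs=3, patience=0, val_fold=1, seed=0,
                            augmentation=AugmentationConfig(seed=0))
    model, history = train(model, records, annotations, folds, config)
    frozen_cols = [c for c in SIGNAL_CLASSES
                   if history.iloc[-1][f"frozen_{c}"]]
    assert frozen_cols
    snapshots = {c: model.head(c).state_dict() for c in frozen_cols}
    # train five more epochs from the frozen state
    config2 = TrainingConfig(max_epochs=5, patience=5, val_fold=1, seed=1,
                             augmentation=None)
    for cls in frozen_cols:
        model.head(cls).freeze()
    model, _ = train(model, records, annotations, folds, config2)
    for cls, snap in snapshots.items():
        for name, value in model.head(cls).state_dict().items():
            np.testing.assert_array_equal(value, snap[name])


def test_train_requires_both_folds(micro_dataset):
    records, annotations, _ = micro_dataset
    model = SignalModel(TINY)
    folds = {r.id: 2 for r in records}
    with pytest.raises(ValueError, match="folds"):
        train(model, records, annotations, folds,
              TrainingConfig(val_fold=1))
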