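"""Dual-loss training with per-head early stopping and freezing.

The total loss is the sum of two terms:

* a residue-level weighted categorical cross-entropy over 9 categories,
  where the ninth (OTHER) prediction row is constructed as
  ``1 - max(class strengths)`` at each position and the 9-vector is
  renormalised to a proper categorical distribution; targets are hard
  one-hot labels, and each position is weighted by its true class's
  inverse-frequency weight (normalised by the summed weights);
* a protein-level weighted binary cross-entropy on the per-class horizontal
  maxima of the signal matrix (plus the OTHER score ``1 - max over
  classes``) against the multi-label protein vector — binary, not softmax,
  so CH+TH coexistence stays representable.

Each head is monitored separately on the validation fold (its residue-level
binary cross-entropy over proteins carrying its class plus signal-free
negatives, balanced between positive and negative positions); a head that
fails to improve for ``patience`` consecutive epochs is frozen.  At the
first head freeze the shared backbone freezes too (configurable, or on a
schedule via ``freeze_backbone_epoch``), and the remaining heads keep
training on the fixed encoder; training ends when every head is frozen or
``max_epochs`` is reached.  Head weights are restored to their best
validated states with care for coherence against the (possibly moving)
backbone — see the notes inside :func:`train`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .alphabet import N_CLASSES, OTHER_INDEX, SIGNAL_CLASSES
from .augment import AugmentationConfig, augment_epoch
from .labels import (
    LabelMatrix,
    ProteinLabelVector,
    build_label_matrix,
    protein_label_vector,
)
from .model import SignalMatrix, SignalModel
from .nnet import Adam
from .seqio import ProteinRecord, SignalAnnotation

__all__ = [
    "LossWeights",
    "TrainingConfig",
    "TrainState",
    "residue_loss",
    "protein_loss",
    "compute_loss_weights",
    "train",
]

_EPS = 1e-7
_MIN_DELTA = 1e-5


@dataclasses.dataclass(frozen=True)
class LossWeights:
    residue_weights: np.ndarray  # (9,)
    class_weights: np.ndarray  # (9,)

    def __post_init__(self):
        for w in (self.residue_weights, self.class_weights):
            w = np.asarray(w, dtype=float)
            if w.shape != (N_CLASSES + 1,) or (w <= 0).any():
                raise ValueError("loss weights must be 9 positive values")

    @staticmethod
    def unit() -> "LossWeights":
        return LossWeights(np.ones(9), np.ones(9))


# ---------------------------------------------------------------------------
# losses (batched tensor core + scalar numpy-facing wrappers)
# ---------------------------------------------------------------------------

def _residue_loss_tensor(
    strengths: Tensor,  # (B, L, 8)
    labels: np.ndarray,  # (B, L, 9) one-hot
    weights: np.ndarray,  # (9,)
    mask: np.ndarray,  # (B, L) bool
    weight_mode: str = "label",
) -> Tensor:
    """Weighted categorical cross-entropy over the 9-row prediction.

    ``weight_mode="label"`` weights each position by its true class's
    weight; ``"pred_max"`` weights it by the weight of the class currently
    selected as the maximum there — so a position where a rare class fires
    spuriously carries that class's full weight instead of the background
    weight, penalising false positives as strongly as misses.
    """
    other = 1.0 - strengths.max(axis=2, keepdims=True)
    from ._autodiff import concat

    pred9 = concat([strengths, other], axis=2).clamp(_EPS, 1.0)
    pred9 = pred9 / pred9.sum(axis=2, keepdims=True)
    logp = pred9.log()
    if weight_mode in ("pred_max", "max"):
        winners = np.argmax(pred9.data, axis=2)  # constant wrt the graph
        w_pos = weights[winners]
        if weight_mode == "max":
            # recall pressure from the true class, precision pressure from
            # the currently winning class — whichever weighs more
            w_label = (labels * weights[None, None, :]).sum(axis=2)
            w_pos = np.maximum(w_pos, w_label)
        wy = labels * (w_pos * mask)[:, :, None]
    elif weight_mode == "label":
        wy = labels * weights[None, None, :] * mask[:, :, None]
    else:
        raise ValueError(f"unknown residue weight mode {weight_mode!r}")
    total_weight = float(wy.sum())
    if total_weight == 0:
        raise ValueError("no labelled positions in batch")
    return -(logp * wy).sum() * (1.0 / total_weight)


def _protein_loss_tensor(
    strengths: Tensor,  # (B, L, 8)
    labels: np.ndarray,  # (B, 9) 0/1
    weights: np.ndarray,  # (9,)
    mask: np.ndarray,  # (B, L) bool
) -> Tensor:
    from ._autodiff import concat

    masked = strengths * mask[:, :, None]
    smax = masked.max(axis=1)  # (B, 8)
    other = 1.0 - smax.max(axis=1, keepdims=True)
    scores = concat([smax, other], axis=1).clamp(_EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    bce = -(y * scores.log() + (1.0 - y) * (1.0 - scores).log())
    B = y.shape[0]
    return (bce * weights[None, :]).sum() * (1.0 / (B * weights.sum()))


def _as_blh(matrix: np.ndarray) -> Tensor:
    """Lift an 8 x L signal matrix to a (1, L, 8) tensor."""
    m = matrix.matrix if isinstance(matrix, SignalMatrix) else np.asarray(matrix)
    return Tensor(m.T[None, :, :])


def residue_loss(
    signal_matrix,
    label_matrix: LabelMatrix,
    residue_weights: np.ndarray | None = None,
) -> float:
    """Residue-level weighted categorical cross-entropy for one protein."""
    t = _as_blh(signal_matrix)
    if residue_weights is None:
        residue_weights = np.ones(9)
    labels = label_matrix.matrix.T[None, :, :].astype(float)
    if labels.shape[1] != t.shape[1]:
        raise ValueError("signal matrix and label matrix lengths differ")
    mask = np.ones((1, t.shape[1]), dtype=bool)
    return float(
        _residue_loss_tensor(t, labels, np.asarray(residue_weights, float),
                             mask).data
    )


def protein_loss(
    signal_matrix,
    label_vector: ProteinLabelVector,
    class_weights: np.ndarray | None = None,
) -> float:
    """Protein-level weighted binary cross-entropy on horizontal maxima."""
    t = _as_blh(signal_matrix)
    if class_weights is None:
        class_weights = np.ones(9)
    mask = np.ones((1, t.shape[1]), dtype=bool)
    labels = np.asarray(label_vector.labels, dtype=float)[None, :]
    return float(
        _protein_loss_tensor(t, labels, np.asarray(class_weights, float),
                             mask).data
    )


def compute_loss_weights(
    training_labels: Sequence[LabelMatrix],
    clamp: tuple[float, float] = (0.1, 10.0),
) -> LossWeights:
    """Inverse-frequency weights from the training labels.

    Protein-level: weight_c = N_proteins / (9 * N_c) with OTHER counting the
    signal-free proteins; residue-level analogously over position counts.
    Both are clamped to [0.1, 10]; a class absent from training gets the
    clamp maximum with a warning.
    """
    if not training_labels:
        raise ValueError("no training labels")
    protein_counts = np.zeros(9)
    residue_counts = np.zeros(9)
    for lm in training_labels:
        vec = protein_label_vector(lm)
        protein_counts += vec.labels
        residue_counts += lm.matrix.sum(axis=1)

    def weights_from(counts: np.ndarray, total: float) -> np.ndarray:
        out = np.empty(9)
        for c in range(9):
            if counts[c] == 0:
                name = (SIGNAL_CLASSES + ("OTHER",))[c]
                warnings.warn(
                    f"class {name} absent from training labels; weight set "
                    f"to clamp maximum", stacklevel=3
                )
                out[c] = clamp[1]
            else:
                out[c] = total / (9.0 * counts[c])
        return np.clip(out, *clamp)

    return LossWeights(
        residue_weights=weights_from(residue_counts, residue_counts.sum()),
        class_weights=weights_from(protein_counts, len(training_labels)),
    )


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainingConfig:
    max_epochs: int = 200
    patience: int = 30
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay
    ema_decay: float = 0.995  # Polyak average of head weights; 1.0 disables
    batch_size: int = 16
    val_fold: int = 1
    seed: int = 0
    augmentation: AugmentationConfig | None = None  # None disables
    use_class_weights: bool = True
    residue_weight_mode: str = "label"  # or "pred_max" / "max"
    freeze_backbone_on_first: bool = True
    #: scheduled alternative to the freeze-on-first rule: freeze the
    #: backbone after this many epochs so the heads finish on a
    #: stationary encoder (None disables)
    freeze_backbone_epoch: int | None = None


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    best_val: dict = dataclasses.field(
        default_factory=lambda: {c: np.inf for c in SIGNAL_CLASSES}
    )
    patience_counter: dict = dataclasses.field(
        default_factory=lambda: {c: 0 for c in SIGNAL_CLASSES}
    )
    frozen: dict = dataclasses.field(
        default_factory=lambda: {c: False for c in SIGNAL_CLASSES}
    )
    backbone_frozen: bool = False
    best_head_state: dict = dataclasses.field(default_factory=dict)
    best_head_epoch: dict = dataclasses.field(default_factory=dict)
    best_f1: dict = dataclasses.field(default_factory=dict)
    best_f1_state: dict = dataclasses.field(default_factory=dict)
    best_f1_epoch: dict = dataclasses.field(default_factory=dict)
    backbone_frozen_epoch: int | None = None

    def all_frozen(self) -> bool:
        return all(self.frozen.values())


def _batches(items: list, batch_size: int, rng: np.random.Generator,
             max_tokens: int = 6144) -> list[list]:
    """Length-sorted batches in shuffled order.

    Sorting mixes classes while keeping padding waste low; the token budget
    keeps batches containing rare very long proteins small.
    """
    ordered = sorted(items, key=lambda r: len(r.sequence))
    chunks: list[list] = []
    current: list = []
    for item in ordered:
        L = len(item.sequence)
        if current and (
            len(current) >= batch_size
            or (len(current) + 1) * L > max_tokens
        ):
            chunks.append(current)
            current = []
        current.append(item)
    if current:
        chunks.append(current)
    rng.shuffle(chunks)
    return chunks


def _label_arrays(records, ann_by_protein):
    """(B, L, 9) one-hot labels, (B, 9) protein vectors, (B, L) mask."""
    lms = [build_label_matrix(r, ann_by_protein.get(r.id, []))
           for r in records]
    Lmax = max(lm.length for lm in lms)
    B = len(records)
    labels = np.zeros((B, Lmax, 9))
    vectors = np.zeros((B, 9))
    mask = np.zeros((B, Lmax), dtype=bool)
    for i, lm in enumerate(lms):
        labels[i, : lm.length] = lm.matrix.T
        vectors[i] = protein_label_vector(lm).labels
        mask[i, : lm.length] = True
    return labels, vectors, mask


def _head_val_metrics(model, val_records, ann_by_protein, batch_size):
    """Per-head residue BCE on the validation fold, plus total losses.

    Head c is scored on proteins that carry class c or carry no signal at
    all (the negatives every head must reject).  The BCE is balanced
    between positive and negative positions so that progress on a rare
    short signal is not drowned by the abundant background positions.
    """
    pos_num = {c: 0.0 for c in SIGNAL_CLASSES}
    pos_den = {c: 0 for c in SIGNAL_CLASSES}
    neg_num = {c: 0.0 for c in SIGNAL_CLASSES}
    neg_den = {c: 0 for c in SIGNAL_CLASSES}
    tp = {c: 0 for c in SIGNAL_CLASSES}
    fp = {c: 0 for c in SIGNAL_CLASSES}
    fn = {c: 0 for c in SIGNAL_CLASSES}
    total_res = 0.0
    total_prot = 0.0
    n_batches = 0
    rng = np.random.default_rng(0)
    for batch in _batches(list(val_records), batch_size, rng):
        seqs = [r.sequence for r in batch]
        strengths, mask = model.forward_batch(seqs)
        labels, vectors, lmask = _label_arrays(batch, ann_by_protein)
        s = np.clip(strengths.data, _EPS, 1 - _EPS)
        total_res += float(
            _residue_loss_tensor(Tensor(s), labels, np.ones(9), lmask).data
        )
        total_prot += float(
            _protein_loss_tensor(Tensor(s), vectors, np.ones(9), lmask).data
        )
        n_batches += 1
        for ci, cls in enumerate(SIGNAL_CLASSES):
            has_class = vectors[:, ci] == 1
            signal_free = vectors[:, OTHER_INDEX] == 1
            rows = has_class | signal_free
            if not rows.any():
                continue
            y = labels[rows, :, ci]
            p = s[rows, :, ci]
            m = lmask[rows]
            bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
            pos = (y == 1) & m
            neg = (y == 0) & m
            pos_num[cls] += float(bce[pos].sum())
            pos_den[cls] += int(pos.sum())
            neg_num[cls] += float(bce[neg].sum())
            neg_den[cls] += int(neg.sum())
            called = p > 0.5  # the inference rule's per-row condition
            tp[cls] += int((called & pos).sum())
            fp[cls] += int((called & neg).sum())
            fn[cls] += int((~called & pos).sum())
    metrics = {}
    total = (total_res + total_prot) / max(n_batches, 1)
    for cls in SIGNAL_CLASSES:
        if neg_den[cls] == 0 and pos_den[cls] == 0:
            metrics[cls] = total  # fallback; warned about by the caller
            continue
        parts = []
        if pos_den[cls]:
            parts.append(pos_num[cls] / pos_den[cls])
        if neg_den[cls]:
            parts.append(neg_num[cls] / neg_den[cls])
        metrics[cls] = float(np.mean(parts))
    fallback = [c for c in SIGNAL_CLASSES
                if neg_den[c] == 0 and pos_den[c] == 0]
    called_f1 = {}
    for cls in SIGNAL_CLASSES:
        denom = 2 * tp[cls] + fp[cls] + fn[cls]
        called_f1[cls] = 2 * tp[cls] / denom if denom else 0.0
    return metrics, total_res / max(n_batches, 1), \
        total_prot / max(n_batches, 1), fallback, called_f1


def train(
    model: SignalModel,
    records: Sequence[ProteinRecord],
    annotations: Sequence[SignalAnnotation],
    folds: dict[str, int],
    config: TrainingConfig,
) -> tuple[SignalModel, pd.DataFrame]:
    """Optimise the dual loss with per-head early stopping.

    Returns the trained model (heads rolled back to their best validation
    states) and a per-epoch history table.
    """
    rng = np.random.default_rng(config.seed)
    ann_by_protein: dict[str, list[SignalAnnotation]] = {}
    for ann in annotations:
        ann_by_protein.setdefault(ann.protein_id, []).append(ann)

    train_records = [r for r in records
                     if folds.get(r.id) != config.val_fold]
    val_records = [r for r in records if folds.get(r.id) == config.val_fold]
    if not train_records or not val_records:
        raise ValueError("need non-empty training and validation folds")

    if config.use_class_weights:
        train_lms = [build_label_matrix(r, ann_by_protein.get(r.id, []))
                     for r in train_records]
        loss_weights = compute_loss_weights(train_lms)
    else:
        loss_weights = LossWeights.unit()

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    state = TrainState()
    for cls in SIGNAL_CLASSES:  # respect heads frozen before this call
        params = model.head(cls).parameters()
        if params and all(not p.requires_grad for p in params):
            state.frozen[cls] = True
    warned_fallback: set[str] = set()
    history_rows = []

    # Polyak (EMA) shadow of each head's weights: an extra, smoother
    # candidate for the end-of-training validated restore
    use_ema = config.ema_decay < 1.0
    ema: dict[str, dict[str, np.ndarray]] = {
        cls: {name: p.data.copy()
              for name, p in model.head(cls).named_parameters()}
        for cls in SIGNAL_CLASSES
    } if use_ema else {}

    def ema_update():
        d = config.ema_decay
        for cls in SIGNAL_CLASSES:
            if state.frozen[cls]:
                continue
            shadow = ema[cls]
            for name, p in model.head(cls).named_parameters():
                shadow[name] = d * shadow[name] + (1.0 - d) * p.data

    for epoch in range(1, config.max_epochs + 1):
        state.epoch = epoch
        model.train()

        if config.augmentation is not None:
            aug_records, aug_annotations, _ = augment_epoch(
                train_records,
                [a for a in annotations
                 if folds.get(a.protein_id) != config.val_fold],
                {pid: f for pid, f in folds.items()
                 if f != config.val_fold},
                epoch,
                config.augmentation,
                val_folds=(),
            )
            epoch_records = aug_records
            epoch_anns: dict[str, list[SignalAnnotation]] = {}
            for ann in aug_annotations:
                epoch_anns.setdefault(ann.protein_id, []).append(ann)
        else:
            epoch_records = list(train_records)
            epoch_anns = ann_by_protein

        epoch_loss = 0.0
        n_batches = 0
        for batch in _batches(epoch_records, config.batch_size, rng):
            seqs = [r.sequence for r in batch]
            strengths, _ = model.forward_batch(seqs)
            labels, vectors, lmask = _label_arrays(batch, epoch_anns)
            loss = _residue_loss_tensor(
                strengths, labels, loss_weights.residue_weights, lmask,
                weight_mode=config.residue_weight_mode,
            ) + _protein_loss_tensor(
                strengths, vectors, loss_weights.class_weights, lmask
            )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            if use_ema:
                ema_update()
            epoch_loss += float(loss.data)
            n_batches += 1

        model.eval()
        head_metrics, val_res, val_prot, fallback, head_f1 = \
            _head_val_metrics(
                model, val_records, ann_by_protein, config.batch_size
            )
        for cls in fallback:
            if cls not in warned_fallback:
                warnings.warn(
                    f"validation fold has no proteins for head {cls}; "
                    "early stopping falls back to total validation loss",
                    stacklevel=2,
                )
                warned_fallback.add(cls)

        def restore_if_coherent(cls):
            # a head snapshot is only compatible with the encoder it was
            # taken against; with a still-moving backbone the snapshot is
            # stale, so the head keeps its current weights instead
            if cls not in state.best_head_state:
                return
            if (state.backbone_frozen_epoch is not None
                    and state.best_head_epoch[cls]
                    >= state.backbone_frozen_epoch):
                model.head(cls).load_state_dict(state.best_head_state[cls])

        first_freeze_this_epoch = False
        for cls in SIGNAL_CLASSES:
            if state.frozen[cls]:
                continue
            metric = head_metrics[cls]
            if head_f1[cls] > state.best_f1.get(cls, 0.0) + 1e-9:
                # rule-aligned snapshot: best residue F1 under the > 0.5
                # call condition
                state.best_f1[cls] = head_f1[cls]
                state.best_f1_state[cls] = model.head(cls).state_dict()
                state.best_f1_epoch[cls] = epoch
            if metric < state.best_val[cls] - _MIN_DELTA:
                state.best_val[cls] = metric
                state.patience_counter[cls] = 0
                state.best_head_state[cls] = model.head(cls).state_dict()
                state.best_head_epoch[cls] = epoch
            else:
                state.patience_counter[cls] += 1
                if state.patience_counter[cls] > config.patience:
                    restore_if_coherent(cls)
                    model.head(cls).freeze()
                    state.frozen[cls] = True
                    if not state.backbone_frozen:
                        first_freeze_this_epoch = True

        scheduled_freeze = (
            config.freeze_backbone_epoch is not None
            and epoch >= config.freeze_backbone_epoch
            and not state.backbone_frozen
        )
        if scheduled_freeze or (
            first_freeze_this_epoch and config.freeze_backbone_on_first
        ):
            model.backbone.freeze()
            state.backbone_frozen = True
            state.backbone_frozen_epoch = epoch
            # remaining heads restart their tracking on the fixed encoder,
            # so their future snapshots stay consistent with it
            for cls in SIGNAL_CLASSES:
                if not state.frozen[cls]:
                    state.best_val[cls] = np.inf
                    state.patience_counter[cls] = 0
                    state.best_head_state.pop(cls, None)
                    state.best_head_epoch.pop(cls, None)
                    state.best_f1.pop(cls, None)
                    state.best_f1_state.pop(cls, None)
                    state.best_f1_epoch.pop(cls, None)

        optimizer.lr = config.learning_rate * (config.lr_decay ** epoch)

        row = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_residue_loss": val_res,
            "val_protein_loss": val_prot,
            "val_total_loss": val_res + val_prot,
        }
        for cls in SIGNAL_CLASSES:
            row[f"val_{cls}"] = head_metrics[cls]
            row[f"frozen_{cls}"] = state.frozen[cls]
        history_rows.append(row)

        if state.all_frozen():
            break

    # Restore each still-unfrozen head to the better of (final state, best
    # snapshot), judged by re-validation against the final backbone: a
    # snapshot taken while the backbone was still moving is only worth
    # restoring if it actually validates better on the encoder we ended
    # up with.  Frozen heads were handled at freeze time and stay frozen.
    model.eval()
    open_heads = [cls for cls in SIGNAL_CLASSES if not state.frozen[cls]]
    if open_heads:
        candidate_states: dict[str, dict[str, dict]] = {
            cls: {"final": model.head(cls).state_dict()}
            for cls in open_heads
        }
        for cls in open_heads:
            if cls in state.best_head_state:
                candidate_states[cls]["snapshot"] = state.best_head_state[cls]
            if cls in state.best_f1_state:
                candidate_states[cls]["f1_snapshot"] = \
                    state.best_f1_state[cls]
            if use_ema:
                candidate_states[cls]["ema"] = dict(ema[cls])
        names = sorted({n for c in candidate_states.values() for n in c})
        # rank candidates by rule-aligned residue F1 (ties: lower BCE),
        # re-validated against the final backbone
        scores: dict[str, dict[str, tuple]] = {c: {} for c in open_heads}
        for name in names:
            for cls in open_heads:
                if name in candidate_states[cls]:
                    model.head(cls).load_state_dict(
                        candidate_states[cls][name]
                    )
            metrics, _, _, _, f1s = _head_val_metrics(
                model, val_records, ann_by_protein, config.batch_size
            )
            for cls in open_heads:
                if name in candidate_states[cls]:
                    scores[cls][name] = (-f1s[cls], metrics[cls])
        for cls in open_heads:
            best = min(scores[cls], key=scores[cls].get)
            model.head(cls).load_state_dict(candidate_states[cls][best])
    return model, pd.DataFrame(history_rows)
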