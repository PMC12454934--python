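"""Binomial-mutation data augmentation with class-weighted replication.

Every epoch the training folds are re-augmented from a fresh seeded random
process: each training protein is copied a number of times proportional to
its class's inverse-frequency weight, and each copy is independently point
mutated — positions inside annotated signal spans at ``rate_positive``
(default 0.1), background positions at ``rate_negative`` (default 0.3).
Replacement residues are drawn uniformly from the 20 standard amino acids,
so a selected position keeps its original residue with probability 1/20 and
the effective change rate is rate x 19/20.  Annotated spans never move:
mutation is substitution-only, and augmented copies inherit their parent's
fold so identity control across folds is preserved by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, OTHER_INDEX, SIGNAL_CLASSES, UNKNOWN
from .labels import LabelMatrix, build_label_matrix
from .seqio import ProteinRecord, SignalAnnotation

__all__ = [
    "AugmentationConfig",
    "mutate_sequence",
    "replication_counts",
    "augment_epoch",
]


@dataclasses.dataclass(frozen=True)
class AugmentationConfig:
    rate_positive: float = 0.1
    rate_negative: float = 0.3
    replication_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.rate_positive, self.rate_negative):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.replication_scale < 0:
            raise ValueError("replication_scale must be >= 0")


def mutate_sequence(
    record: ProteinRecord,
    label_matrix: LabelMatrix,
    config: AugmentationConfig,
    rng: np.random.Generator,
    alphabet: str = AMINO_ACIDS,
) -> ProteinRecord:
    """Binomially mutate one sequence; labels and spans are untouched."""
    L = len(record.sequence)
    if label_matrix.length != L:
        raise ValueError(
            f"label matrix length {label_matrix.length} != sequence length {L}"
        )
    is_signal = label_matrix.matrix[OTHER_INDEX] == 0
    rates = np.where(is_signal, config.rate_positive, config.rate_negative)
    selected = rng.random(L) < rates
    chars = np.array(list(record.sequence))
    selected &= chars != UNKNOWN  # UNKNOWN positions are never mutated
    n = int(selected.sum())
    if n:
        chars[selected] = rng.choice(np.array(list(alphabet)), size=n)
    return ProteinRecord(record.id, "".join(chars))


def replication_counts(
    class_counts: dict[str, int], config: AugmentationConfig
) -> dict[str, int]:
    """Copies per class from inverse-frequency weights.

    weight_c = N_total / (K_nonempty * N_c) over the non-empty classes;
    count_c = round(replication_scale * weight_c), half rounded up.
    """
    nonempty = {c: n for c, n in class_counts.items() if n > 0}
    if not nonempty:
        raise ValueError("replication_counts requires at least one non-empty class")
    total = sum(nonempty.values())
    k = len(nonempty)
    counts: dict[str, int] = {}
    for cls in class_counts:
        if cls not in nonempty:
            counts[cls] = 0
            continue
        weight = total / (k * nonempty[cls])
        counts[cls] = int(np.floor(config.replication_scale * weight + 0.5))
    return counts


def augment_epoch(
    records: Sequence[ProteinRecord],
    annotations: Sequence[SignalAnnotation],
    folds: dict[str, int],
    epoch: int,
    config: AugmentationConfig,
    val_folds: Iterable[int] = (),
) -> tuple[list[ProteinRecord], list[SignalAnnotation], dict[str, int]]:
    """One epoch's augmented dataset.

    Returns the originals plus freshly mutated copies of the training-fold
    proteins; validation folds pass through untouched.  A multi-label
    protein is copied max-over-its-classes times; signal-free proteins are
    not replicated.  The random stream is seeded by (config.seed, epoch), so
    the same epoch regenerates identically and different epochs differ.
    """
    val_folds = set(val_folds)
    rng = np.random.default_rng([config.seed, epoch])

    ann_by_protein: dict[str, list[SignalAnnotation]] = {}
    for ann in annotations:
        ann_by_protein.setdefault(ann.protein_id, []).append(ann)

    protein_counts = {c: 0 for c in SIGNAL_CLASSES}
    for pid, anns in ann_by_protein.items():
        if folds.get(pid) in val_folds:
            continue
        for cls in {a.signal_class for a in anns}:
            protein_counts[cls] += 1
    if all(n == 0 for n in protein_counts.values()):
        return list(records), list(annotations), dict(folds)
    per_class = replication_counts(protein_counts, config)

    out_records = list(records)
    out_annotations = list(annotations)
    out_folds = dict(folds)
    for record in records:
        fold = folds.get(record.id)
        if fold in val_folds:
            continue
        anns = ann_by_protein.get(record.id, [])
        if not anns:
            continue
        n_copies = max(per_class[c] for c in {a.signal_class for a in anns})
        label_matrix = build_label_matrix(record, anns)
        for i in range(n_copies):
            copy_id = f"{record.id}__aug{epoch}.{i}"
            mutated = mutate_sequence(
                ProteinRecord(copy_id, record.sequence),
                label_matrix,
                config,
                rng,
            )
            out_records.append(mutated)
            out_annotations.extend(
                SignalAnnotation(copy_id, a.signal_class, a.start, a.end)
                for a in anns
            )
            out_folds[copy_id] = fold
    return out_records, out_annotations, out_folds
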