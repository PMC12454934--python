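"""Per-residue label matrices and protein-level label vectors.

Span annotations are rasterised into a one-hot 9 x L matrix (8 signal
classes in canonical order plus OTHER at index 8); every column sums to 1
because one residue belongs to at most one targeting peptide.  The
protein-level view is a 9-dim multi-label 0/1 vector: a class bit is set iff
the protein carries at least one annotation of that class, and OTHER is set
iff no class bit is.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alphabet import CLASS_INDEX, N_CLASSES, OTHER_INDEX, SIGNAL_CLASSES
from .seqio import ProteinRecord, SignalAnnotation, validate_annotations

__all__ = [
    "LabelMatrix",
    "ProteinLabelVector",
    "build_label_matrix",
    "protein_label_vector",
    "spans_from_label_matrix",
]


@dataclasses.dataclass
class LabelMatrix:
    protein_id: str
    matrix: np.ndarray  # (9, L) one-hot

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != N_CLASSES + 1:
            raise ValueError(f"label matrix must be 9 x L, got {m.shape}")
        if not np.array_equal(m.sum(axis=0), np.ones(m.shape[1])):
            raise ValueError("every label column must sum to exactly 1")
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass(frozen=True)
class ProteinLabelVector:
    protein_id: str
    labels: np.ndarray  # (9,) 0/1


def build_label_matrix(
    record: ProteinRecord, annotations: list[SignalAnnotation]
) -> LabelMatrix:
    """Rasterise validated span annotations into a one-hot 9 x L matrix."""
    anns = [a for a in annotations if a.protein_id == record.id]
    validate_annotations(anns)
    L = len(record.sequence)
    matrix = np.zeros((N_CLASSES + 1, L), dtype=np.int8)
    for ann in anns:
        if ann.end > L:
            raise ValueError(
                f"annotation {ann.signal_class} {ann.start}-{ann.end} exceeds "
                f"length {L} of {record.id}"
            )
        matrix[CLASS_INDEX[ann.signal_class], ann.start - 1 : ann.end] = 1
    matrix[OTHER_INDEX] = 1 - matrix[:N_CLASSES].sum(axis=0)
    return LabelMatrix(record.id, matrix)


def protein_label_vector(label_matrix: LabelMatrix) -> ProteinLabelVector:
    """Collapse a label matrix to the multi-label protein vector."""
    class_bits = (label_matrix.matrix[:N_CLASSES].sum(axis=1) > 0).astype(np.int8)
    other = np.int8(0 if class_bits.any() else 1)
    return ProteinLabelVector(
        label_matrix.protein_id, np.concatenate([class_bits, [other]])
    )


def spans_from_label_matrix(label_matrix: LabelMatrix) -> list[SignalAnnotation]:
    """Recover the annotation set from a one-hot label matrix.

    Inverse of :func:`build_label_matrix` on valid inputs, except that
    annotations touching each other with the same class merge into one span
    (such inputs cannot arise from distinct non-adjacent annotations).
    """
    m = label_matrix.matrix
    out: list[SignalAnnotation] = []
    for ci, cls in enumerate(SIGNAL_CLASSES):
        row = m[ci]
        in_run = False
        start = 0
        for pos in range(len(row) + 1):
            val = row[pos] if pos < len(row) else 0
            if val and not in_run:
                in_run, start = True, pos
            elif not val and in_run:
                in_run = False
                out.append(
                    SignalAnnotation(label_matrix.protein_id, cls, start + 1, pos)
                )
    out.sort(key=lambda a: a.start)
    return out
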