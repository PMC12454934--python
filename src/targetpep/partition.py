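"""Identity-controlled k-fold assignment.

Sequences above the identity threshold are connected in a similarity graph;
single-linkage connected components are kept intact and distributed over
folds greedily (largest component first, into the currently smallest fold,
with per-class counts as a soft secondary balance objective).  Single
linkage is the one clustering that makes the cross-fold guarantee exact: if
two proteins in different folds were >= threshold identical they would, by
construction, be in one component and hence one fold.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np

from .align import global_identity
from .seqio import ProteinRecord, SignalAnnotation

__all__ = [
    "FoldAssignment",
    "pairwise_identity",
    "identity_matrix",
    "cluster_and_partition",
    "audit_partition",
]


@dataclasses.dataclass
class FoldAssignment:
    folds: dict[str, int]  # protein_id -> fold in 1..k
    k: int = 5
    threshold: float = 0.30

    def fold_sizes(self) -> dict[int, int]:
        sizes = {f: 0 for f in range(1, self.k + 1)}
        for f in self.folds.values():
            sizes[f] += 1
        return sizes


def pairwise_identity(a: str, b: str, **scoring) -> float:
    """Global-alignment identity in [0, 1] (symmetric)."""
    return global_identity(a, b, **scoring).identity


def identity_matrix(records: Sequence[ProteinRecord], **scoring) -> np.ndarray:
    """Dense symmetric matrix of pairwise identities (diagonal = 1)."""
    n = len(records)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(
                records[i].sequence, records[j].sequence, **scoring
            )
    return mat


def _components(adjacency: np.ndarray) -> list[list[int]]:
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            node = stack.pop()
            comp.append(node)
            for nb in np.nonzero(adjacency[node])[0]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(int(nb))
        comps.append(sorted(comp))
    return comps


def cluster_and_partition(
    records: Sequence[ProteinRecord],
    threshold: float = 0.30,
    k: int = 5,
    rng: np.random.Generator | int | None = 0,
    annotations: Iterable[SignalAnnotation] = (),
    identities: np.ndarray | None = None,
) -> FoldAssignment:
    """Assign proteins to k folds with no cross-fold pair >= threshold.

    ``identities`` may carry a precomputed matrix (reused by the audit);
    otherwise all pairs are aligned here.  The rng only breaks ordering ties
    between equal-sized components, so assignment is deterministic per seed.
    """
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if identities is None:
        identities = identity_matrix(records)
    adjacency = identities >= threshold
    np.fill_diagonal(adjacency, False)
    comps = _components(adjacency)

    # per-protein class sets for the soft balance objective
    class_of: dict[str, set[str]] = {}
    for ann in annotations:
        class_of.setdefault(ann.protein_id, set()).add(ann.signal_class)

    max_fold = max(len(c) for c in comps)
    if max_fold > len(records) - (k - 1):
        warnings.warn(
            "one similarity component is so large that some folds may be empty",
            stacklevel=2,
        )

    order = sorted(
        range(len(comps)),
        key=lambda ci: (-len(comps[ci]), rng.random()),
    )
    fold_sizes = np.zeros(k, dtype=int)
    fold_class_counts = [dict() for _ in range(k)]  # type: list[dict[str, int]]
    folds: dict[str, int] = {}
    for ci in order:
        comp = comps[ci]
        comp_classes: dict[str, int] = {}
        for idx in comp:
            for cls in class_of.get(records[idx].id, ()):
                comp_classes[cls] = comp_classes.get(cls, 0) + 1
        # primary: smallest fold; secondary: least overlap with the
        # component's class profile
        def key(f: int):
            overlap = sum(
                fold_class_counts[f].get(cls, 0) * cnt
                for cls, cnt in comp_classes.items()
            )
            return (fold_sizes[f], overlap, f)

        target = min(range(k), key=key)
        for idx in comp:
            folds[records[idx].id] = target + 1
        fold_sizes[target] += len(comp)
        for cls, cnt in comp_classes.items():
            fold_class_counts[target][cls] = (
                fold_class_counts[target].get(cls, 0) + cnt
            )
    return FoldAssignment(folds, k=k, threshold=threshold)


def audit_partition(
    records: Sequence[ProteinRecord],
    assignment: FoldAssignment,
    identities: np.ndarray | None = None,
) -> list[tuple[str, str, float]]:
    """Exhaustively list cross-fold pairs at or above the threshold.

    An empty list certifies the leakage guarantee.
    """
    if identities is None:
        identities = identity_matrix(records)
    violations = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if assignment.folds[records[i].id] == assignment.folds[records[j].id]:
                continue
            if identities[i, j] >= assignment.threshold:
                violations.append(
                    (records[i].id, records[j].id, float(identities[i, j]))
                )
    return violations
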