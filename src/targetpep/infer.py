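"""Threshold-free inference from signal-strength matrices.

Per-residue calls use vertical max-pooling: at each position the class with
the highest strength wins, provided it beats its own implicit OTHER
complement (strength > 1 - strength, i.e. > 0.5; the rule introduces no
free threshold beyond the 1 - max construction of the OTHER class).  Runs
of identical calls become segments, segments yield protein-level
multi-label calls, and terminus-anchored segments yield cleavage sites.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alphabet import (
    C_ANCHORED,
    INTERNAL_CLASSES,
    N_ANCHORED,
    OTHER_INDEX,
    SIGNAL_CLASSES,
)
from .model import SignalMatrix

__all__ = [
    "Segment",
    "call_residues",
    "extract_segments",
    "cleavage_site",
    "protein_calls",
    "rasterize_segments",
]


@dataclasses.dataclass(frozen=True)
class Segment:
    protein_id: str
    signal_class: str
    start: int  # 1-based inclusive
    end: int
    mean_strength: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_residues(signal_matrix: SignalMatrix,
                  other_rule: bool = True) -> np.ndarray:
    """Per-position class indices (0..7) or OTHER_INDEX (8).

    Vertical max-pooling with ties broken toward the lowest class index in
    canonical order.  With ``other_rule`` (default) a class is called only
    if its strength strictly exceeds 0.5, i.e. beats OTHER = 1 - max;
    ``other_rule=False`` gives the unconditional argmax reading.
    """
    m = signal_matrix.matrix
    winners = m.argmax(axis=0)  # argmax takes the lowest index on ties
    calls = winners.copy()
    if other_rule:
        best = m.max(axis=0)
        calls[best <= 0.5] = OTHER_INDEX
    return calls


def extract_segments(
    calls: np.ndarray,
    signal_matrix: SignalMatrix,
    min_len: int = 1,
) -> list[Segment]:
    """Maximal runs of identical non-OTHER calls, with mean strengths."""
    segments: list[Segment] = []
    calls = np.asarray(calls)
    L = calls.size
    pos = 0
    while pos < L:
        cls_idx = calls[pos]
        run_start = pos
        while pos < L and calls[pos] == cls_idx:
            pos += 1
        if cls_idx == OTHER_INDEX:
            continue
        run_len = pos - run_start
        if run_len < min_len:
            continue
        strength = float(
            signal_matrix.matrix[cls_idx, run_start:pos].mean()
        )
        segments.append(
            Segment(
                signal_matrix.protein_id,
                SIGNAL_CLASSES[cls_idx],
                run_start + 1,
                pos,
                strength,
            )
        )
    return segments


def rasterize_segments(segments: list[Segment], length: int) -> np.ndarray:
    """Inverse of extract_segments: per-position calls from segments."""
    calls = np.full(length, OTHER_INDEX, dtype=int)
    for seg in segments:
        calls[seg.start - 1 : seg.end] = SIGNAL_CLASSES.index(seg.signal_class)
    return calls


def cleavage_site(
    segments: list[Segment], signal_class: str, length: int
) -> int | None:
    """Cleavage-site position for a terminus-anchored class.

    N-anchored classes (MT, SP, CH, and TH at the CH boundary) cleave at the
    segment's far end; C-anchored classes (ER; PTS when C-terminal) cleave
    at the segment's start.  With several candidate segments, the one
    touching its anchor terminus wins; PTS anchors to whichever terminus its
    segment touches, defaulting to C-terminal behaviour.
    """
    if signal_class in INTERNAL_CLASSES:
        raise ValueError(
            f"cleavage sites are undefined for {signal_class}; use SOV"
        )
    if signal_class not in N_ANCHORED | C_ANCHORED:
        raise ValueError(f"unknown signal class {signal_class!r}")
    candidates = [s for s in segments if s.signal_class == signal_class]
    if not candidates:
        return None

    if signal_class in N_ANCHORED and signal_class != "TH":
        anchored = [s for s in candidates if s.start == 1]
        seg = anchored[0] if anchored else candidates[0]
        return seg.end
    if signal_class == "TH":
        # anchored at the CH boundary: take the first (most N-terminal)
        seg = min(candidates, key=lambda s: s.start)
        return seg.end
    if signal_class == "ER":
        anchored = [s for s in candidates if s.end == length]
        seg = anchored[0] if anchored else candidates[-1]
        return seg.start
    # PTS: anchor by whichever terminus the segment touches; C-terminal wins
    c_anchored = [s for s in candidates if s.end == length]
    if c_anchored:
        return c_anchored[0].start
    n_anchored = [s for s in candidates if s.start == 1]
    if n_anchored:
        return n_anchored[0].end
    return candidates[-1].start


def protein_calls(segments: list[Segment]) -> set[str]:
    """Protein-level multi-label call: the set of segment classes."""
    return {s.signal_class for s in segments}


def predict_dataset(
    model,
    records,
    batch_size: int = 16,
    other_rule: bool = True,
    min_len: int = 1,
) -> tuple[dict[str, SignalMatrix], dict[str, list[Segment]]]:
    """Batched inference over many proteins.

    Returns per-protein signal matrices and called segments; batches are
    grouped by length to keep padding waste low.
    """
    was_training = model.training
    model.eval()
    matrices: dict[str, SignalMatrix] = {}
    segments: dict[str, list[Segment]] = {}
    try:
        ordered = sorted(records, key=lambda r: len(r.sequence))
        for i in range(0, len(ordered), batch_size):
            batch = ordered[i : i + batch_size]
            strengths, mask = model.forward_batch(
                [r.sequence for r in batch]
            )
            for j, record in enumerate(batch):
                L = len(record.sequence)
                sm = SignalMatrix(record.id, strengths.data[j, :L, :].T.copy())
                matrices[record.id] = sm
                calls = call_residues(sm, other_rule=other_rule)
                segments[record.id] = extract_segments(calls, sm,
                                                       min_len=min_len)
    finally:
        model.train(was_training)
    return matrices, segments
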