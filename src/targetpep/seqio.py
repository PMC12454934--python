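"""Reading and writing the formats the toolkit touches.

Sequences travel as FASTA (via Biopython), span annotations as a headered
TSV (``protein_id  class  start  end``, 1-based inclusive, '#' comments),
called segments as a BED-like TSV (0-based half-open, convention declared in
a header comment) and signal-strength matrices as TSV dumps.

Internal coordinates are 1-based inclusive throughout, matching curated
protein feature spans; only the BED-like segment files use 0-based
half-open coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import N_CLASSES, SIGNAL_CLASSES, sanitize_sequence

__all__ = [
    "ProteinRecord",
    "SignalAnnotation",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "write_segments",
    "read_segments",
    "write_signal_matrix",
    "read_signal_matrix",
    "write_fold_assignment",
    "read_fold_assignment",
]


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus an uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.id!r}")

    def __len__(self):
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class SignalAnnotation:
    """A targeting-peptide span: class plus 1-based inclusive coordinates."""

    protein_id: str
    signal_class: str
    start: int
    end: int

    def __post_init__(self):
        if self.signal_class not in SIGNAL_CLASSES:
            raise ValueError(
                f"unknown signal class {self.signal_class!r}; "
                f"valid classes: {', '.join(SIGNAL_CLASSES)}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid span {self.start}-{self.end} on {self.protein_id} "
                "(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "SignalAnnotation") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.start <= other.end
            and other.start <= self.end
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and non-standard letters are mapped to the
    UNKNOWN token; duplicate ids raise.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        # reject sequence data before the first header with a useful message
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq))))
    return records


def write_fasta(path, records: Iterable[ProteinRecord]) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations (headered TSV, 1-based inclusive)
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ("protein_id", "class", "start", "end")


def validate_annotations(annotations: Sequence[SignalAnnotation]) -> None:
    """Reject overlapping spans on the same protein."""
    by_protein: dict[str, list[SignalAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    for pid, anns in by_protein.items():
        anns = sorted(anns, key=lambda a: a.start)
        for a, b in zip(anns, anns[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping annotations on {pid}: "
                    f"{a.signal_class} {a.start}-{a.end} and "
                    f"{b.signal_class} {b.start}-{b.end}"
                )


def read_annotations(path) -> list[SignalAnnotation]:
    path = Path(path)
    annotations: list[SignalAnnotation] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields[:4]) != _ANNOTATION_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        f"{'	'.join(_ANNOTATION_COLUMNS)!r}, got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pid, cls, start_s, end_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            annotations.append(SignalAnnotation(pid, cls, start, end))
    validate_annotations(annotations)
    return annotations


def write_annotations(path, annotations: Iterable[SignalAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for ann in annotations:
            fh.write(
                f"{ann.protein_id}\t{ann.signal_class}\t{ann.start}\t{ann.end}\n"
            )


# ---------------------------------------------------------------------------
# Segments (BED-like, 0-based half-open on disk)
# ---------------------------------------------------------------------------

_SEGMENT_HEADER = (
    "# targetpep segments: 0-based half-open coordinates "
    "(columns: protein_id, start, end, class, mean_strength)"
)


def write_segments(path, segments) -> None:
    """Write called segments in a BED-like dialect.

    Internal 1-based inclusive spans [s, e] map to external [s-1, e).
    """
    with open(path, "w") as fh:
        fh.write(_SEGMENT_HEADER + "\n")
        for seg in segments:
            strength = getattr(seg, "mean_strength", None)
            strength_s = "." if strength is None else f"{strength:.6f}"
            fh.write(
                f"{seg.protein_id}\t{seg.start - 1}\t{seg.end}\t"
                f"{seg.signal_class}\t{strength_s}\n"
            )


def read_segments(path):
    from .infer import Segment  # local import to avoid a cycle

    segments = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            pid, start_s, end_s, cls, strength_s = line.split("\t")[:5]
            strength = None if strength_s == "." else float(strength_s)
            segments.append(
                Segment(pid, cls, int(start_s) + 1, int(end_s), strength)
            )
    return segments


# ---------------------------------------------------------------------------
# Signal-strength matrices
# ---------------------------------------------------------------------------

def write_signal_matrix(path, protein_id: str, matrix: np.ndarray) -> None:
    """Dump an 8 x L signal-strength matrix as TSV with 6 decimals."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != N_CLASSES:
        raise ValueError(
            f"signal matrix must have {N_CLASSES} rows, got shape {matrix.shape}"
        )
    if matrix.size and (matrix.min() < 0.0 or matrix.max() > 1.0):
        raise ValueError("signal strengths must lie in [0, 1]")
    L = matrix.shape[1]
    with open(path, "w") as fh:
        fh.write(f"# protein_id: {protein_id}\n")
        fh.write("class\t" + "\t".join(str(i) for i in range(1, L + 1)) + "\n")
        for cls, row in zip(SIGNAL_CLASSES, matrix):
            fh.write(cls + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_signal_matrix(path) -> tuple[str, np.ndarray]:
    protein_id = ""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# protein_id:"):
                protein_id = line.split(":", 1)[1].strip()
                continue
            if not line.strip() or line.startswith("class\t") or line.startswith("#"):
                continue
            fields = line.split("\t")
            rows.append([float(v) for v in fields[1:]])
    matrix = np.array(rows, dtype=float)
    if matrix.shape[0] != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} class rows in {path}")
    return protein_id, matrix


# ---------------------------------------------------------------------------
# Fold assignments
# ---------------------------------------------------------------------------

def write_fold_assignment(path, assignment: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfold\n")
        for pid, fold in assignment.items():
            fh.write(f"{pid}\t{fold}\n")


def read_fold_assignment(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id\tfold"):
            raise ValueError(f"unexpected fold-assignment header in {path}")
        for line in fh:
            if not line.strip():
                continue
            pid, fold = line.rstrip("\n").split("\t")[:2]
            out[pid] = int(fold)
    return out
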