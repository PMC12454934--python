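"""Synthetic proteins with planted targeting peptides.

The generator emulates the positional grammar of the eight targeting-peptide
classes so that every downstream stage — labelling, partitioning,
augmentation, training, inference, evaluation — is exercisable without any
external data:

* ER retention signal: fixed 4-mer at the C-terminus (KDEL-like: a charged
  position, two acidic positions, terminal L).
* PTS: fixed C-terminal tripeptide from {S,A,C} x {K,R,H} x {L,M} (the PTS1
  grammar).
* MT: N-terminal 20-40mer, arginine-enriched and net positively charged,
  ending in an R-x-x-R processing-site flavour.
* SP: N-terminal 15-30mer with positive n-region, leucine-rich hydrophobic
  h-region, small/neutral c-region.
* CH: N-terminal 30-55mer starting M-A, enriched in S/T/A.
* TH: 12-25mer placed immediately after a CH span (thylakoid signals always
  follow the chloroplast transit peptide), twin-arginine flavoured.
* NLS: 1-3 internal 5-20mer blocks of K/R.
* NES: internal 10-22mer, leucine-rich with acidic spacers.

Compositions are coarse category mixtures, not estimates of real motif
frequencies; they give a learner a recoverable planted signal.  Background
residues are uniform over the 20 standard amino acids by default.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple

import numpy as np

from .alphabet import AMINO_ACIDS, SIGNAL_CLASSES
from .seqio import ProteinRecord, SignalAnnotation, validate_annotations

__all__ = [
    "MotifModel",
    "SyntheticConfig",
    "MOTIF_MODELS",
    "plant_signal",
    "generate_dataset",
    "class_count_report",
    "ClassCounts",
]

N_TERMINAL = "N_TERMINAL"
C_TERMINAL = "C_TERMINAL"
AFTER_CH = "AFTER_CH"
INTERNAL = "INTERNAL"


def _weights(table: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(table.keys()))
    w = np.array(list(table.values()), dtype=float)
    return letters, w / w.sum()


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """Positional grammar and composition for one signal class.

    ``fixed_start``/``fixed_end`` pin the first/last motif positions to
    explicit choice sets; interior positions are drawn from ``composition``.
    """

    signal_class: str
    length_range: tuple[int, int]
    placement: str
    composition: dict[str, float]
    fixed_start: tuple[str, ...] = ()
    fixed_end: tuple[str, ...] = ()

    def __post_init__(self):
        lo, hi = self.length_range
        if self.signal_class == "ER" and (lo, hi) != (4, 4):
            raise ValueError("ER retention signals are exactly 4 residues")
        if self.signal_class == "PTS" and (lo, hi) != (3, 3):
            raise ValueError("PTS tripeptides are exactly 3 residues")
        if self.placement == AFTER_CH and self.signal_class != "TH":
            raise ValueError("AFTER_CH placement is reserved for TH")

    def min_extent(self) -> int:
        return self.length_range[0]

    def sample(self, rng: np.random.Generator) -> str:
        lo, hi = self.length_range
        length = int(rng.integers(lo, hi + 1))
        n_start, n_end = len(self.fixed_start), len(self.fixed_end)
        if length < n_start + n_end:
            raise ValueError("motif length below fixed-position count")
        out = [rng.choice(list(choices)) for choices in self.fixed_start]
        interior = length - n_start - n_end
        if interior > 0:
            letters, w = _weights(self.composition)
            out.extend(rng.choice(letters, size=interior, p=w))
        out.extend(rng.choice(list(choices)) for choices in self.fixed_end)
        return "".join(out)


MOTIF_MODELS: dict[str, MotifModel] = {
    "ER": MotifModel(
        "ER", (4, 4), C_TERMINAL, {},
        fixed_start=("KHR", "DE", "DE", "L"),
    ),
    "PTS": MotifModel(
        "PTS", (3, 3), C_TERMINAL, {},
        fixed_start=("SAC", "KRH", "LM"),
    ),
    "MT": MotifModel(
        "MT", (20, 40), N_TERMINAL,
        {"R": 0.24, "K": 0.04, "A": 0.16, "S": 0.14, "L": 0.18,
         "T": 0.06, "G": 0.05, "F": 0.04, "P": 0.03, "Q": 0.03,
         "V": 0.02, "D": 0.005, "E": 0.005},
        fixed_end=("R", "ASL", "ASL", "R"),
    ),
    "SP": MotifModel(
        "SP", (15, 30), N_TERMINAL,
        {"L": 0.42, "I": 0.14, "V": 0.14, "A": 0.14, "F": 0.10,
         "W": 0.03, "M": 0.03},
        fixed_start=("M", "KR", "KR"),
        fixed_end=("A", "SG", "A"),
    ),
    "CH": MotifModel(
        "CH", (30, 55), N_TERMINAL,
        {"S": 0.26, "T": 0.15, "A": 0.24, "P": 0.06, "R": 0.05,
         "L": 0.06, "V": 0.05, "G": 0.05, "N": 0.04, "K": 0.02,
         "F": 0.02},
        fixed_start=("M", "A"),
    ),
    "TH": MotifModel(
        "TH", (12, 25), AFTER_CH,
        {"A": 0.22, "L": 0.16, "V": 0.10, "S": 0.14, "T": 0.05,
         "K": 0.08, "R": 0.05, "G": 0.07, "P": 0.05, "Q": 0.04,
         "F": 0.04},
        fixed_start=("ST", "R", "R"),
        fixed_end=("S", "A"),
    ),
    "NLS": MotifModel(
        "NLS", (5, 20), INTERNAL,
        {"K": 0.45, "R": 0.35, "S": 0.05, "Q": 0.04, "A": 0.04,
         "P": 0.04, "V": 0.03},
    ),
    "NES": MotifModel(
        "NES", (10, 22), INTERNAL,
        {"L": 0.35, "I": 0.08, "V": 0.08, "F": 0.05, "D": 0.12,
         "E": 0.12, "S": 0.08, "A": 0.07, "K": 0.05},
    ),
}


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 40 proteins per class, 20% signal-free proteins, protein
    lengths uniform on [100, 180] with a 2% tail of long (>= 1100 residue)
    proteins so the fragment/merge path is exercised.
    """

    n_per_class: dict[str, int] = dataclasses.field(
        default_factory=lambda: {c: 40 for c in SIGNAL_CLASSES}
    )
    length_range: tuple[int, int] = (100, 180)
    fraction_no_signal: float = 0.2
    background: dict[str, float] | None = None  # None = uniform over 20
    long_fraction: float = 0.02
    long_length_range: tuple[int, int] = (1100, 1400)
    max_nls_segments: int = 3
    n_duplicate_clusters: int = 0
    duplicate_cluster_size: int = 3
    duplicate_mutation_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for cls, n in self.n_per_class.items():
            if cls not in SIGNAL_CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if n < 0:
                raise ValueError("per-class counts must be >= 0")
        if not 0.0 <= self.fraction_no_signal <= 1.0:
            raise ValueError("fraction_no_signal must lie in [0, 1]")

    @staticmethod
    def from_file(path) -> "SyntheticConfig":
        """Load a config from a YAML/JSON key-value file.

        Unknown keys are rejected with an error naming them.
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: "
                f"{sorted(valid)}"
            )
        for key in ("length_range", "long_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return SyntheticConfig(**data)


def _background_sequence(length: int, config: SyntheticConfig,
                         rng: np.random.Generator) -> str:
    if config.background is None:
        letters = np.array(list(AMINO_ACIDS))
        return "".join(rng.choice(letters, size=length))
    letters, w = _weights(config.background)
    return "".join(rng.choice(letters, size=length, p=w))


def plant_signal(
    record: ProteinRecord,
    motif_model: MotifModel,
    rng: np.random.Generator,
    existing: Iterable[SignalAnnotation] = (),
) -> tuple[ProteinRecord, SignalAnnotation]:
    """Overwrite a placement region with motif residues and return the span.

    ``existing`` annotations constrain placement: AFTER_CH anchors at the CH
    end, INTERNAL placement avoids occupied positions.
    """
    existing = list(existing)
    L = len(record.sequence)
    motif = motif_model.sample(rng)
    m = len(motif)
    placement = motif_model.placement
    if placement == N_TERMINAL:
        if m > L:
            raise ValueError("sequence shorter than motif")
        start = 1
    elif placement == C_TERMINAL:
        if m > L:
            raise ValueError("sequence shorter than motif")
        start = L - m + 1
    elif placement == AFTER_CH:
        ch = [a for a in existing if a.signal_class == "CH"]
        if not ch:
            raise ValueError("AFTER_CH placement requires an existing CH span")
        start = ch[0].end + 1
        if start + m - 1 > L:
            raise ValueError("sequence too short to host TH after CH")
    elif placement == INTERNAL:
        # start >= 2 and end <= L-1: internal signals never touch a terminus
        occupied = np.zeros(L + 2, dtype=bool)
        for a in existing:
            lo = max(1, a.start - 1)
            hi = min(L, a.end + 1)
            occupied[lo : hi + 1] = True  # 1 position of slack on each side
        candidates = [
            s
            for s in range(2, L - m + 1)
            if not occupied[s : s + m].any()
        ]
        if not candidates:
            raise ValueError("no internal placement available for motif")
        start = int(rng.choice(candidates))
    else:
        raise ValueError(f"unknown placement {placement!r}")
    end = start + m - 1
    seq = record.sequence[: start - 1] + motif + record.sequence[end:]
    annotation = SignalAnnotation(record.id, motif_model.signal_class, start, end)
    for a in existing:
        if a.overlaps(annotation):
            raise ValueError("planted motif overlaps an existing annotation")
    return ProteinRecord(record.id, seq), annotation


def _protein_length(config: SyntheticConfig, rng: np.random.Generator,
                    min_length: int) -> int:
    if config.long_fraction > 0 and rng.random() < config.long_fraction:
        lo, hi = config.long_length_range
    else:
        lo, hi = config.length_range
    lo = max(lo, min_length)
    if hi < lo:
        raise ValueError(
            f"protein length range {config.length_range} cannot host motifs "
            f"requiring {min_length} residues"
        )
    return int(rng.integers(lo, hi + 1))


def _make_signal_protein(pid: str, cls: str, config: SyntheticConfig,
                         rng: np.random.Generator
                         ) -> tuple[ProteinRecord, list[SignalAnnotation]]:
    annotations: list[SignalAnnotation] = []
    if cls == "TH":
        # thylakoid signals always follow a chloroplast transit peptide
        min_len = MOTIF_MODELS["CH"].length_range[1] + \
            MOTIF_MODELS["TH"].length_range[1] + 10
        L = _protein_length(config, rng, min_len)
        record = ProteinRecord(pid, _background_sequence(L, config, rng))
        record, ch = plant_signal(record, MOTIF_MODELS["CH"], rng)
        annotations.append(ch)
        record, th = plant_signal(record, MOTIF_MODELS["TH"], rng, annotations)
        annotations.append(th)
    elif cls == "NLS":
        L = _protein_length(config, rng,
                            MOTIF_MODELS["NLS"].length_range[1] * 3 + 20)
        record = ProteinRecord(pid, _background_sequence(L, config, rng))
        n_seg = int(rng.integers(1, config.max_nls_segments + 1))
        for _ in range(n_seg):
            record, ann = plant_signal(record, MOTIF_MODELS["NLS"], rng,
                                       annotations)
            annotations.append(ann)
    else:
        model = MOTIF_MODELS[cls]
        L = _protein_length(config, rng, model.length_range[1] + 10)
        record = ProteinRecord(pid, _background_sequence(L, config, rng))
        record, ann = plant_signal(record, model, rng)
        annotations.append(ann)
    return record, annotations


def _mutate_copy(seq: str, rate: float, rng: np.random.Generator) -> str:
    letters = np.array(list(AMINO_ACIDS))
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < rate
    chars[hits] = rng.choice(letters, size=int(hits.sum()))
    return "".join(chars)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], list[SignalAnnotation]]:
    """Generate a deterministic synthetic dataset for the given config."""
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    annotations: list[SignalAnnotation] = []

    for cls in SIGNAL_CLASSES:  # canonical order keeps output deterministic
        for i in range(config.n_per_class.get(cls, 0)):
            pid = f"{cls}{i:04d}"
            record, anns = _make_signal_protein(pid, cls, config, rng)
            records.append(record)
            annotations.extend(anns)

    n_signal = len(records)
    f = config.fraction_no_signal
    if n_signal == 0:
        n_free = 0 if f == 0 else max(0, int(round(20 * f)))  # degenerate case
    else:
        n_free = int(round(n_signal * f / (1.0 - f))) if f < 1.0 else 0
    for i in range(n_free):
        L = _protein_length(config, rng, config.length_range[0])
        records.append(ProteinRecord(f"NEG{i:04d}",
                                     _background_sequence(L, config, rng)))

    # optional planted near-duplicate clusters (for identity-controlled
    # partitioning tests); copies inherit the parent's annotations
    if config.n_duplicate_clusters > 0:
        eligible = [r for r in records]
        idx = rng.choice(len(eligible), size=min(config.n_duplicate_clusters,
                                                 len(eligible)), replace=False)
        for ci in sorted(int(j) for j in idx):
            parent = eligible[ci]
            parent_anns = [a for a in annotations
                           if a.protein_id == parent.id]
            for j in range(config.duplicate_cluster_size - 1):
                dup_id = f"{parent.id}dup{j}"
                seq = _mutate_copy(parent.sequence,
                                   config.duplicate_mutation_rate, rng)
                records.append(ProteinRecord(dup_id, seq))
                annotations.extend(
                    SignalAnnotation(dup_id, a.signal_class, a.start, a.end)
                    for a in parent_anns
                )

    validate_annotations(annotations)
    return records, annotations


class ClassCounts(NamedTuple):
    protein: dict[str, int]
    segment: dict[str, int]


def class_count_report(annotations: Iterable[SignalAnnotation]) -> ClassCounts:
    """Exact per-class counts at protein level and segment level."""
    protein: dict[str, int] = {c: 0 for c in SIGNAL_CLASSES}
    segment: dict[str, int] = {c: 0 for c in SIGNAL_CLASSES}
    seen: set[tuple[str, str]] = set()
    for ann in annotations:
        segment[ann.signal_class] += 1
        key = (ann.protein_id, ann.signal_class)
        if key not in seen:
            seen.add(key)
            protein[ann.signal_class] += 1
    return ClassCounts(protein, segment)
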