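"""Canonical alphabets and class order for the toolkit.

The eight targeting-peptide classes are kept in one fixed order everywhere
(matrices, files, tie-breaking): ER, PTS, MT, SP, CH, TH, NLS, NES, with the
implicit OTHER category always at index 8.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)

#: non-standard letters collapsed onto a dedicated UNKNOWN token
UNKNOWN = "X"
NONSTANDARD = frozenset("XBZUO")

#: residue charge convention: K, R, H positive; D, E negative
POSITIVE_RESIDUES = frozenset("KRH")
NEGATIVE_RESIDUES = frozenset("DE")

SIGNAL_CLASSES = ("ER", "PTS", "MT", "SP", "CH", "TH", "NLS", "NES")
OTHER = "OTHER"
CLASS_INDEX = {c: i for i, c in enumerate(SIGNAL_CLASSES)}
OTHER_INDEX = len(SIGNAL_CLASSES)  # 8
N_CLASSES = len(SIGNAL_CLASSES)

#: classes anchored at the N-terminus (cleavage site = segment end);
#: TH is anchored at the CH boundary and behaves like an N-anchored class.
N_ANCHORED = frozenset({"MT", "SP", "CH", "TH"})
#: classes anchored at the C-terminus (cleavage site = segment start)
C_ANCHORED = frozenset({"ER", "PTS"})
#: classes evaluated by segment overlap rather than cleavage sites
INTERNAL_CLASSES = frozenset({"NLS", "NES"})

# token vocabulary for the sequence encoder
TOKEN_PAD = "<pad>"
TOKEN_CLS = "<cls>"
TOKEN_EOS = "<eos>"
VOCAB = [TOKEN_PAD, TOKEN_CLS, TOKEN_EOS] + list(AMINO_ACIDS) + [UNKNOWN]
TOKEN_INDEX = {t: i for i, t in enumerate(VOCAB)}
PAD_ID = TOKEN_INDEX[TOKEN_PAD]
CLS_ID = TOKEN_INDEX[TOKEN_CLS]
EOS_ID = TOKEN_INDEX[TOKEN_EOS]


def sanitize_sequence(seq: str) -> str:
    """Uppercase and map non-standard letters onto the UNKNOWN token.

    Raises ``ValueError`` for characters that are neither standard amino
    acids nor recognised non-standard codes.
    """
    seq = seq.upper()
    out = []
    for ch in seq:
        if ch in AA_SET:
            out.append(ch)
        elif ch in NONSTANDARD:
            out.append(UNKNOWN)
        else:
            raise ValueError(f"invalid residue character {ch!r}")
    return "".join(out)


def encode_tokens(seq: str):
    """Map a sanitised sequence to integer token ids (no special tokens)."""
    import numpy as np

    return np.array([TOKEN_INDEX[ch] for ch in seq], dtype=np.int64)


def net_charge(seq: str) -> int:
    """Net charge under the +1 (K/R/H), −1 (D/E) convention; others 0."""
    return sum((c in POSITIVE_RESIDUES) - (c in NEGATIVE_RESIDUES) for c in seq)
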