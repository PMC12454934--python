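"""Structural validation utilities.

Inter-chain residue contacts from a complex structure in PDB format (two
residues interact when *any* pair of their atoms lies strictly below the
distance cutoff, default 5 Å), net-charge summaries of motif segments under
the K/R/H = +1, D/E = −1 convention, and FASTA export of detected segments
for external motif-discovery tools.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .alphabet import net_charge
from .infer import Segment
from .seqio import ProteinRecord

__all__ = [
    "ContactPair",
    "interchain_contacts",
    "net_charge",
    "export_segments_fasta",
]


@dataclasses.dataclass(frozen=True)
class ContactPair:
    residue_a: int  # author numbering in chain A
    residue_b: int
    min_distance: float  # Å


def _chain_atoms(chain, include_hetero: bool):
    """Per-residue atom coordinate arrays, author numbering."""
    residues = []
    for res in chain:
        hetflag = res.id[0].strip()
        if hetflag and not include_hetero:
            continue
        coords = np.array([atom.coord for atom in res.get_atoms()],
                          dtype=float)
        if coords.size == 0:
            warnings.warn(
                f"residue {res.id[1]} in chain {chain.id} has no atoms; "
                "skipped", stacklevel=3
            )
            continue
        residues.append((res.id[1], coords))
    return residues


def interchain_contacts(
    structure_path,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
    include_hetero: bool = False,
) -> list[ContactPair]:
    """All residue pairs between two chains with any-atom distance < cutoff.

    Output is sorted by (residue_a, residue_b); distances are the minimal
    inter-atom Euclidean distance in Å and the inequality is strict.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(structure_path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    for cid in (chain_a, chain_b):
        if cid not in chains:
            raise ValueError(
                f"chain {cid!r} not in structure (has {sorted(chains)})"
            )
    res_a = _chain_atoms(chains[chain_a], include_hetero)
    res_b = _chain_atoms(chains[chain_b], include_hetero)
    if not res_a or not res_b:
        return []

    coords_b = np.concatenate([c for _, c in res_b])
    owner_b = np.concatenate(
        [np.full(len(c), i) for i, (_, c) in enumerate(res_b)]
    )
    tree = cKDTree(coords_b)
    best: dict[tuple[int, int], float] = {}
    for ia, (num_a, coords) in enumerate(res_a):
        neighbour_lists = tree.query_ball_point(coords, cutoff)
        for atom_xyz, neighbours in zip(coords, neighbour_lists):
            if not neighbours:
                continue
            d = np.linalg.norm(coords_b[neighbours] - atom_xyz, axis=1)
            for j, dist in zip(neighbours, d):
                if dist >= cutoff:  # query_ball_point includes the boundary
                    continue
                key = (ia, int(owner_b[j]))
                if dist < best.get(key, np.inf):
                    best[key] = float(dist)
    contacts = [
        ContactPair(res_a[ia][0], res_b[ib][0], dist)
        for (ia, ib), dist in best.items()
    ]
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b))
    return contacts


def binding_residues(contacts: Sequence[ContactPair]) -> tuple[list, list]:
    """Sorted unique binding residue indices for each chain."""
    return (
        sorted({c.residue_a for c in contacts}),
        sorted({c.residue_b for c in contacts}),
    )


def write_contacts(path, contacts: Sequence[ContactPair]) -> None:
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\tmin_distance\n")
        for c in contacts:
            fh.write(f"{c.residue_a}\t{c.residue_b}\t{c.min_distance:.3f}\n")


def export_segments_fasta(
    records: Sequence[ProteinRecord],
    segments: Iterable[Segment],
    path,
) -> None:
    """FASTA of detected subsequences, headers ``proteinid|class|start-end``."""
    by_id = {r.id: r for r in records}
    with open(path, "w") as fh:
        for seg in segments:
            record = by_id.get(seg.protein_id)
            if record is None:
                raise ValueError(f"segment references unknown protein "
                                 f"{seg.protein_id!r}")
            if seg.end > len(record.sequence):
                raise ValueError(
                    f"segment {seg.start}-{seg.end} out of range for "
                    f"{seg.protein_id} (length {len(record.sequence)})"
                )
            sub = record.sequence[seg.start - 1 : seg.end]
            fh.write(f">{seg.protein_id}|{seg.signal_class}|"
                     f"{seg.start}-{seg.end}\n{sub}\n")
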