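"""Receptor-antigen interface geometry.

Contacts use the 4 A heavy-atom convention: two residues are in contact
when any pair of their heavy atoms lies within the cutoff (inclusive).
Epitopes are the antigen residues contacting the receptor; core-epitopes
are the contiguous antigen-chain span from the first to the last residue
within the cutoff of TCR/MHC atoms, interior non-contacting residues
included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .structures import ComplexRecord, ComplexType

__all__ = [
    "ContactPair",
    "EpitopeSite",
    "CoreEpitope",
    "CONTACT_CUTOFF",
    "atom_records",
    "compute_contacts",
    "epitope_site",
    "core_epitope",
    "contacts_to_tsv",
]

CONTACT_CUTOFF = 4.0  # Angstrom, inclusive

ResidueKey = tuple[str, int]  # (chain_id, seq_index)


@dataclass(frozen=True)
class ContactPair:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float


@dataclass
class EpitopeSite:
    """Antigen residues in contact with the receptor, plus their heavy atoms."""

    residues: list[ResidueKey]
    coords: np.ndarray  # (n_atoms, 3) heavy-atom coordinates
    complex_ref: str

    @property
    def n_atoms(self) -> int:
        return 0 if self.coords is None else len(self.coords)

    @property
    def is_empty(self) -> bool:
        return not self.residues


@dataclass
class CoreEpitope:
    chain_id: str
    start_index: int
    end_index: int
    sequence: str

    @property
    def length(self) -> int:
        if self.end_index < self.start_index:
            return 0
        return self.end_index - self.start_index + 1


def atom_records(record: ComplexRecord, chain_ids: Iterable[str]):
    """Flatten heavy atoms of the given chains to (residue_key, xyz) pairs."""
    out = []
    for cid in chain_ids:
        chain = record.structure.chain(cid)
        for res in chain.residues:
            for atom in res.atoms:
                out.append(((cid, res.seq_index), atom.position))
    return out


def compute_contacts(atoms_a, atoms_b, cutoff: float = CONTACT_CUTOFF
                     ) -> list[ContactPair]:
    """Residue-residue contacts between two atom sets.

    A residue pair is a contact iff the minimum over atom pairs of the
    Euclidean distance is <= cutoff; the minimal distance is recorded.
    Either set empty gives an empty result.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not atoms_a or not atoms_b:
        return []
    keys_a = [k for k, _ in atoms_a]
    keys_b = [k for k, _ in atoms_b]
    xyz_a = np.asarray([p for _, p in atoms_a], dtype=float)
    xyz_b = np.asarray([p for _, p in atoms_b], dtype=float)
    tree_b = cKDTree(xyz_b)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ia, neighbours in enumerate(tree_b.query_ball_point(xyz_a, r=cutoff)):
        if not neighbours:
            continue
        d = np.linalg.norm(xyz_b[neighbours] - xyz_a[ia], axis=1)
        for ib, dist in zip(neighbours, d):
            if dist <= cutoff:
                pair = (keys_a[ia], keys_b[ib])
                if dist < best.get(pair, np.inf):
                    best[pair] = float(dist)
    return [ContactPair(a, b, dist)
            for (a, b), dist in sorted(best.items())]


def _contacting_antigen_residues(record: ComplexRecord, receptor_chains,
                                 antigen_chain: Optional[str] = None,
                                 cutoff: float = CONTACT_CUTOFF) -> list[ResidueKey]:
    antigen_chains = ([antigen_chain] if antigen_chain
                      else record.antigen_chain_ids)
    contacts = compute_contacts(
        atom_records(record, antigen_chains),
        atom_records(record, receptor_chains),
        cutoff=cutoff,
    )
    return sorted({c.residue_a for c in contacts})


def epitope_site(record: ComplexRecord, cutoff: float = CONTACT_CUTOFF
                 ) -> EpitopeSite:
    """Epitope of an Ab-Ag complex: antigen residues within cutoff of the
    antibody, with all their heavy atoms.  No contacts -> empty site (the
    caller reports and skips it in conformational clustering).
    """
    if record.complex_type != ComplexType.AB_AG:
        raise ValueError("epitope_site is defined for Ab-Ag complexes")
    receptor = record.chains_with_roles({"heavy", "light"})
    residues = _contacting_antigen_residues(record, receptor, cutoff=cutoff)
    coords = []
    for cid, idx in residues:
        for atom in record.structure.chain(cid).residues[idx].atoms:
            coords.append(atom.position)
    return EpitopeSite(
        residues=residues,
        coords=np.asarray(coords, dtype=float) if coords else np.empty((0, 3)),
        complex_ref=record.structure_id,
    )


def core_epitope(record: ComplexRecord, cutoff: float = CONTACT_CUTOFF
                 ) -> CoreEpitope:
    """Core-epitope / core-peptide of a TCR-pMHC or MHC-ligand complex.

    All residues between the first and the last antigen-chain residue
    within cutoff of any TCR/MHC atom (TCR-pMHC) or MHC atom (MHC-ligand);
    interior residues count even when they do not contact.  With several
    antigen chains the longest per-chain core wins.  No contacts at all
    give a zero-length core, which downstream length filters reject.
    """
    if record.complex_type == ComplexType.TCR_PMHC:
        env_roles = {"alpha", "beta", "mhc_a", "mhc_b"}
    elif record.complex_type == ComplexType.MHC_LIGAND:
        env_roles = {"mhc_a", "mhc_b"}
    else:
        raise ValueError("core_epitope is defined for TCR-pMHC / MHC-ligand")
    env_chains = record.chains_with_roles(env_roles)

    best = CoreEpitope(chain_id=record.antigen_chain_ids[0],
                       start_index=0, end_index=-1, sequence="")
    for cid in record.antigen_chain_ids:
        touched = _contacting_antigen_residues(record, env_chains,
                                               antigen_chain=cid, cutoff=cutoff)
        if not touched:
            continue
        indices = [idx for _, idx in touched]
        lo, hi = min(indices), max(indices)
        chain = record.structure.chain(cid)
        seq = "".join(r.one_letter for r in chain.residues[lo:hi + 1])
        core = CoreEpitope(chain_id=cid, start_index=lo, end_index=hi,
                           sequence=seq)
        if core.length > best.length:
            best = core
    return best


def contacts_to_tsv(structure_id: str, contacts: list[ContactPair]) -> str:
    lines = ["structure_id\tchain_a\tres_a\tchain_b\tres_b\tmin_distance"]
    for c in contacts:
        lines.append(f"{structure_id}\t{c.residue_a[0]}\t{c.residue_a[1]}\t"
                     f"{c.residue_b[0]}\t{c.residue_b[1]}\t{c.min_distance:.3f}")
    return "\n".join(lines) + "\n"
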