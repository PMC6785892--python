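"""CDR extraction from IMGT-numbered receptor chains.

Antibody and TCR variable domains carry three hypervariable loops (CDR1-3)
whose positions are fixed under IMGT numbering: 27-38, 56-65 and 105-117.
Numbering is an input produced offline (e.g. by ANARCI) or written by the
fixture generator; it is never computed here.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

from .structures import ComplexRecord

__all__ = [
    "NumberedChain",
    "CDRSet",
    "CDR_RANGES",
    "extract_cdrs",
    "cdr_key",
    "has_missing_cdr_backbone",
    "NumberingError",
]

# IMGT CDR position ranges, inclusive
CDR_RANGES: dict[str, tuple[int, int]] = {
    "cdr1": (27, 38),
    "cdr2": (56, 65),
    "cdr3": (105, 117),
}

BACKBONE_ATOMS = ("N", "CA", "C")


class NumberingError(ValueError):
    """Invalid numbering or numbering that cannot be mapped to coordinates."""


@dataclass
class NumberedChain:
    """IMGT numbering for one receptor chain, in structural residue order."""

    chain_id: str
    receptor_role: str  # heavy | light | alpha | beta
    positions: list[tuple[int, str, str]]  # (imgt_number, insertion, one_letter)

    def letters(self) -> str:
        return "".join(p[2] for p in self.positions)


@dataclass
class CDRSet:
    cdr1: str
    cdr2: str
    cdr3: str
    cdr_positions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    chain_role: str = ""


def extract_cdrs(numbered: NumberedChain) -> CDRSet:
    """Pull CDR1/2/3 out of an IMGT-numbered chain.

    Positions are consumed in the order given (which IMGT keeps consistent
    with the structural residue order, including the descending insertion
    convention on the 112 side of CDR3); gaps are simply absent.
    """
    if not numbered.positions:
        raise NumberingError(f"chain {numbered.chain_id}: empty numbering")
    seen = set()
    for num, ins, _ in numbered.positions:
        if (num, ins) in seen:
            raise NumberingError(
                f"chain {numbered.chain_id}: duplicate IMGT position {num}{ins}")
        seen.add((num, ins))

    seqs = {name: [] for name in CDR_RANGES}
    pos = {name: [] for name in CDR_RANGES}
    for num, ins, letter in numbered.positions:
        for name, (lo, hi) in CDR_RANGES.items():
            if lo <= num <= hi:
                seqs[name].append(letter.upper())
                pos[name].append((num, ins))
    return CDRSet(
        cdr1="".join(seqs["cdr1"]),
        cdr2="".join(seqs["cdr2"]),
        cdr3="".join(seqs["cdr3"]),
        cdr_positions=pos,
        chain_role=numbered.receptor_role,
    )


def cdr_key(cdrs: CDRSet) -> str:
    """Canonical grouping key: chains cluster together iff keys match."""
    return "|".join(s.upper() for s in (cdrs.cdr1, cdrs.cdr2, cdrs.cdr3))


def _map_numbering_to_residues(numbered: NumberedChain, chain) -> dict[int, int]:
    """Align numbering entries to chain residues by order.

    Returns {numbering_index: residue_index}; numbering entries with no
    image are residues absent from the coordinates.  A substitution
    (letters that disagree in place) means the two cannot be aligned by
    order and raises.
    """
    num_letters = numbered.letters().upper()
    res_letters = chain.sequence.upper()
    std_residues = [r.seq_index for r in chain.residues if r.is_standard_aa]
    matcher = difflib.SequenceMatcher(None, num_letters, res_letters, autojunk=False)
    mapping: dict[int, int] = {}
    for op, i1, i2, j1, j2 in matcher.get_opcodes():
        if op == "equal":
            for k in range(i2 - i1):
                mapping[i1 + k] = std_residues[j1 + k]
        elif op == "replace":
            raise NumberingError(
                f"chain {numbered.chain_id}: numbering cannot be aligned to "
                f"structure by order (mismatch {num_letters[i1:i2]!r} vs "
                f"{res_letters[j1:j2]!r})")
        # 'delete': numbering positions with no coordinates (missing residues)
        # 'insert': structure residues outside the numbering — ignored
    return mapping


def has_missing_cdr_backbone(record: ComplexRecord, chain_id: str,
                             cdrs: CDRSet) -> bool:
    """True iff any CDR residue is unresolved or lacks an N, CA or C atom.

    This is the structural reading of "missing residues in the CDR
    regions": chain-trace completeness over the three loops.
    """
    chain = record.structure.chain(chain_id)
    numbered = record.numbered_chains[chain_id]
    mapping = _map_numbering_to_residues(numbered, chain)
    cdr_pos = {p for positions in cdrs.cdr_positions.values() for p in positions}
    for idx, (num, ins, _) in enumerate(numbered.positions):
        if (num, ins) not in cdr_pos:
            continue
        res_idx = mapping.get(idx)
        if res_idx is None:
            return True  # residue absent from coordinates
        if not chain.residues[res_idx].has_atoms(BACKBONE_ATOMS):
            return True
    return False
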