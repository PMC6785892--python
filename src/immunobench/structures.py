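"""Structural data model and coordinate-file I/O.

Parses PDB / mmCIF coordinate files (via gemmi) into a small in-memory
model of chains, residues and heavy atoms, together with the quality
metadata (resolution, R-free) that the downstream filters need.

Conventions:

* coordinates are in Angstroms throughout;
* residue order is file order (``seq_index``, 0-based); author numbering
  is retained only for reporting;
* hydrogens and solvent/additive residues are discarded on parse;
* for alternate locations only the highest-occupancy conformer is kept
  (ties resolved in favour of altloc 'A').
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ComplexType",
    "ComplexRecord",
    "ParseError",
    "parse_structure",
    "write_pdb",
    "chain_sequence",
    "classify_antigen",
    "load_complex",
]

STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# waters, common ions and crystallization additives: never part of any
# contact or scoring atom set, so dropped at parse time
SOLVENT_RESIDUES = {
    "HOH", "DOD", "WAT", "NA", "CL", "K", "MG", "ZN", "MN", "CA2",
    "SO4", "PO4", "GOL", "EDO", "PEG", "ACT", "DMS", "FMT", "NO3",
}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    author_number: int
    insertion_code: str
    name3: str
    one_letter: str
    atoms: list[Atom]
    is_standard_aa: bool

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        """One letter per standard residue, in seq_index order."""
        return "".join(r.one_letter for r in self.residues if r.is_standard_aa)

    @property
    def n_standard(self) -> int:
        return sum(1 for r in self.residues if r.is_standard_aa)

    @property
    def molecule_kind(self) -> str:
        n = self.n_standard
        if n == 0:
            return "non-peptidic"
        return "peptide" if n <= 30 else "protein"


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain]
    resolution: Optional[float] = None
    r_free: Optional[float] = None
    method: str = ""

    def __post_init__(self):
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.structure_id}")
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in {self.structure_id}")


class ComplexType(str, Enum):
    AB_AG = "AB_AG"
    TCR_PMHC = "TCR_PMHC"
    MHC_LIGAND = "MHC_LIGAND"


RECEPTOR_ROLES = {"heavy", "light", "alpha", "beta"}
MHC_ROLES = {"mhc_a", "mhc_b"}


@dataclass
class ComplexRecord:
    """A structure plus its chain-role annotation.

    Chain roles come from the annotation record, never from sequence
    inference.  ``receptor_chain_roles`` maps chain id to one of
    heavy/light/alpha/beta/mhc_a/mhc_b.
    """

    structure: StructureModel
    complex_type: ComplexType
    receptor_chain_roles: dict[str, str]
    antigen_chain_ids: list[str]
    numbered_chains: dict = field(default_factory=dict)  # chain_id -> NumberedChain
    mhc_class_annotation: Optional[str] = None
    organism: Optional[str] = None

    def __post_init__(self):
        roles = set(self.receptor_chain_roles.values())
        ct = self.complex_type
        if ct == ComplexType.AB_AG and not roles & {"heavy", "light"}:
            raise ValueError("Ab-Ag complex needs a heavy or light chain")
        if ct == ComplexType.TCR_PMHC:
            if not roles & {"alpha", "beta"}:
                raise ValueError("TCR-pMHC complex needs a TCR alpha or beta chain")
            if not roles & MHC_ROLES:
                raise ValueError("TCR-pMHC complex needs an MHC chain")
        if ct == ComplexType.MHC_LIGAND:
            if not roles & MHC_ROLES:
                raise ValueError("MHC-ligand complex needs an MHC chain")
            if roles & RECEPTOR_ROLES:
                raise ValueError("MHC-ligand complex must not carry receptor chains")
        if not self.antigen_chain_ids:
            raise ValueError("antigen_chain_ids must be non-empty")
        if set(self.antigen_chain_ids) & set(self.receptor_chain_roles):
            raise ValueError("antigen chains overlap receptor/MHC chains")

    @property
    def structure_id(self) -> str:
        return self.structure.structure_id

    def chains_with_roles(self, roles) -> list[str]:
        return [cid for cid, r in self.receptor_chain_roles.items() if r in roles]

    @property
    def antigen_is_peptidic(self) -> bool:
        return classify_antigen(self) == "peptidic"


def _pick_conformers(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)

    def key(a: Atom):
        return (-a.occupancy, 0 if a.altloc in ("", "A") else 1, a.altloc)

    return [sorted(by_name[n], key=key)[0] for n in order]


def _residue_identity(name3: str, has_ca: bool) -> tuple[str, bool]:
    """(one_letter, is_standard_aa) for a residue name.

    Non-standard amino acids map to 'X' and count as standard only when
    they have a CA atom and a tabulated one-letter parent; anything else
    is non-peptidic content.
    """
    if name3 in STANDARD_AA:
        return STANDARD_AA[name3], True
    info = gemmi.find_tabulated_residue(name3)
    if info is not None and info.is_amino_acid() and has_ca:
        code = info.one_letter_code.upper().strip()
        if code and code.isalpha():
            return "X", True
    return "X", False


def _read_r_free_pdb(path: Path) -> Optional[float]:
    pat = re.compile(r"FREE R VALUE\s*(?:\(NO CUTOFF\))?\s*:\s*([0-9]*\.?[0-9]+)")
    for line in path.read_text().splitlines():
        if line.startswith("REMARK   3"):
            m = pat.search(line)
            if m:
                return float(m.group(1))
    return None


def _read_refine_mmcif(path: Path) -> tuple[Optional[float], Optional[float]]:
    """(resolution, r_free) from the refine category of an mmCIF file."""
    try:
        doc = gemmi.cif.read(str(path))
    except Exception:
        return None, None

    def lookup(tag):
        for block in doc:
            val = block.find_value(tag)
            if val not in (None, "?", "."):
                try:
                    return float(val)
                except ValueError:
                    continue
        return None

    return lookup("_refine.ls_d_res_high"), lookup("_refine.ls_R_factor_R_free")


def parse_structure(path, dialect: Optional[str] = None) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is read.  Hydrogens and solvent are dropped;
    alternate locations are collapsed to a single conformer.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such coordinate file: {path}")
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    fmt = gemmi.CoorFormat.Mmcif if dialect == "mmcif" else gemmi.CoorFormat.Pdb
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ParseError(f"{path.name}: no coordinates section")

    st.setup_entities()
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name in SOLVENT_RESIDUES:
                continue
            atoms = []
            for ga in gres:
                if ga.element.name in ("H", "D"):
                    continue
                atoms.append(Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    altloc=ga.altloc if ga.altloc != "\x00" else "",
                ))
            atoms = _pick_conformers(atoms)
            if not atoms:
                continue
            has_ca = any(a.name == "CA" for a in atoms)
            one, std = _residue_identity(gres.name, has_ca)
            residues.append(Residue(
                chain_id=gchain.name,
                seq_index=len(residues),
                author_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                name3=gres.name,
                one_letter=one,
                atoms=atoms,
                is_standard_aa=std,
            ))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise ParseError(f"{path.name}: no usable residues")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if dialect == "mmcif":
        cif_resolution, r_free = _read_refine_mmcif(path)
        resolution = resolution or cif_resolution
    else:
        r_free = _read_r_free_pdb(path)
    return StructureModel(
        structure_id=(st.name or path.stem).lower()[:20] or path.stem,
        chains=chains,
        resolution=resolution,
        r_free=r_free,
        method=(st.info["_exptl.method"] if "_exptl.method" in st.info else ""),
    )


def chain_sequence(chain: Chain) -> str:
    """One-letter sequence over standard residues; '' for non-peptidic."""
    return chain.sequence


def classify_antigen(record: ComplexRecord) -> str:
    """'peptidic' iff any antigen chain has at least one standard residue."""
    for cid in record.antigen_chain_ids:
        if record.structure.chain(cid).n_standard >= 1:
            return "peptidic"
    return "non_peptidic"


# ---------------------------------------------------------------------------
# PDB writing (fixture dialect)

def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file.

    Emits REMARK 2 (resolution) and REMARK 3 (R-free) when present so the
    metadata round-trips through :func:`parse_structure`.
    """
    lines = [f"HEADER    IMMUNE COMPLEX                          01-JAN-20   "
             f"{model.structure_id.upper()[:4]:<4}"]
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    if model.r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : {model.r_free:.3f}")
    lines.append("CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1")
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            record = "ATOM" if res.is_standard_aa else "HETATM"
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
                x, y, z = atom.position
                lines.append(
                    f"{record:<6}{serial:>5} {name}{'':1}{res.name3:>3} "
                    f"{chain.chain_id[:1]}{res.author_number:>4}"
                    f"{res.insertion_code or '':1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5}      {chain.residues[-1].name3:>3} "
                     f"{chain.chain_id[:1]}{chain.residues[-1].author_number:>4}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotation loading

def load_complex(annotation_path) -> ComplexRecord:
    """Load one complex from its JSON annotation record.

    The annotation names the coordinate file (relative paths resolve
    against the annotation's directory), assigns chain roles, and carries
    IMGT numbering for receptor chains.
    """
    from .annotation import NumberedChain  # local import to avoid a cycle

    annotation_path = Path(annotation_path)
    ann = json.loads(annotation_path.read_text())
    coord = Path(ann["coordinate_file"])
    if not coord.is_absolute():
        coord = annotation_path.parent / coord
    model = parse_structure(coord, dialect=ann.get("dialect"))
    model.structure_id = ann["structure_id"]

    numbered = {}
    for cid, entries in ann.get("numbering", {}).items():
        numbered[cid] = NumberedChain(
            chain_id=cid,
            receptor_role=ann["receptor_chain_roles"][cid],
            positions=[(int(n), str(ins), str(letter).upper())
                       for n, ins, letter in entries],
        )
    return ComplexRecord(
        structure=model,
        complex_type=ComplexType(ann["complex_type"]),
        receptor_chain_roles=dict(ann["receptor_chain_roles"]),
        antigen_chain_ids=list(ann["antigen_chain_ids"]),
        numbered_chains=numbered,
        mhc_class_annotation=ann.get("mhc_class"),
        organism=ann.get("organism"),
    )
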