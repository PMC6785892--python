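"""Synthetic complex generator with planted ground truth.

Builds toy receptor-antigen corpora (coordinates + annotations + G-domain
references) whose cluster structure, quality defects and interface
geometry are planted by construction, so the whole pipeline is testable
offline.  Expected counts are derived in closed form from the plant
tables — never by running the pipeline under test — and the generator
cross-checks the plant with the similarity kernels (pairwise identities,
site scores, G-domain mapping) plus a brute-force contact oracle,
raising if the plant is inconsistent.

Geometry is deliberately idealized: chains are laid out on a serpentine
grid (3.8 A CA-CA spacing, 4.5 A between rows) with an N/CA/C/O backbone
plus one CB side-chain atom per residue.  Receptor paratope residues and
MHC platform residues "hover" 5.3 A above/below their target antigen
residues so that exactly the planted residues fall within the 4 A
contact cutoff.  This validates logic, not biophysics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .annotation import CDR_RANGES
from .interface import EpitopeSite
from .similarity import (GDomainRef, map_g_domain, pairwise_identity,
                         pocketmatch_score, sites_similar)
from .structures import Atom, Chain, Residue, StructureModel, write_pdb

__all__ = ["PlannedComplex", "make_corpus", "make_site_pair",
           "standard_plan", "minimal_plan", "stress_plan"]

# no glycine: every synthetic residue carries the CB pseudo side chain
ALPHABET = "ACDEFHIKLMNPQRSTVWY"

ANTIGEN_LEN = 60
SHORT_ANTIGEN_LEN = 45
PEPTIDE_LEN = 11
CORE_TARGETS = tuple(range(1, 10))        # core span 1..9, length 9
SHORT_CORE_TARGETS = tuple(range(2, 8))   # span 2..7, length 6 (< 8)
CONFORMER_ANCHORS = {"A": (24, 25, 26, 27), "B": (17, 21, 25, 29)}
TCR_HOVER = (4, 5, 6)

CDR_LENGTHS = {"heavy": (7, 6, 7), "light": (6, 3, 8),
               "alpha": (6, 5, 7), "beta": (7, 6, 8)}
FW_RANGES = ((20, 26), (39, 45), (66, 72), (118, 124))

FAR_Y = {"heavy": 20.0, "light": 32.0, "alpha": 20.0, "beta": 32.0,
         "mhc_a": -20.0, "mhc_b": -38.0}
CHAIN_ID = {"heavy": "H", "light": "L", "alpha": "A", "beta": "B",
            "mhc_a": "M", "mhc_b": "N"}

GDOMAIN_SPECS = (  # ref_id, class, domain, length
    ("GD1", "I", "a", 180),
    ("GD2", "I", "a", 180),
    ("GD3", "I", "a", 180),   # decoy, never planted
    ("GDA1", "II", "a", 90),
    ("GDB1", "II", "b", 90),
)
PLATFORM_START = 50  # MHC chain residue index where the platform begins


@dataclass(frozen=True)
class PlannedComplex:
    """One row of the plant table."""

    structure_id: str
    branch: str                       # ab_ag | tcr_pmhc | mhc_ligand
    peptidic: bool = True
    defect: Optional[str] = None      # resolution | no_resolution |
    #                                   missing_cdr | short_antigen | short_core
    family: Optional[int] = None      # antigen family id (Ab-Ag)
    family_variant: int = 0           # 0 = family base sequence
    receptor_group: Optional[str] = None
    conformer: Optional[str] = None   # epitope conformer template id (Ab-Ag)
    core: Optional[tuple[int, int]] = None  # (core cluster id, variant)
    mhc_group: Optional[str] = None   # m1 | m2 | m3 (class II) | mn
    transform: bool = False           # apply a rigid-body transform


# ---------------------------------------------------------------------------
# Plans

def standard_plan() -> list[PlannedComplex]:
    """The standard corpus: every filter, clustering and nomenclature rule
    is exercised, with planted counts stated in the expected-counts record."""
    P = PlannedComplex
    plan: list[PlannedComplex] = []
    # Ab-Ag peptidic: receptor groups R1..R8 sized (3,3,2,2,2,2,1,1),
    # antigen families F1..F6 sized (4,3,3,2,2,2), conformers chosen so the
    # per-receptor-cluster epitope clusters sum to 11 distinct pairs.
    ab = [  # (family, variant, receptor, conformer, transform)
        (1, 0, "R1", "A", False), (2, 0, "R1", "A", True),
        (3, 0, "R1", "B", False), (4, 0, "R2", "A", False),
        (1, 1, "R2", "B", False), (2, 1, "R2", "B", True),
        (3, 1, "R3", "A", False), (5, 0, "R3", "B", False),
        (1, 2, "R4", "A", False), (2, 2, "R4", "A", False),
        (4, 1, "R5", "A", False), (6, 0, "R5", "A", True),
        (1, 3, "R6", "B", False), (3, 2, "R6", "B", False),
        (5, 1, "R7", "A", False), (6, 1, "R8", "B", False),
    ]
    for i, (fam, var, rg, conf, tr) in enumerate(ab):
        plan.append(P(f"abag{i:02d}", "ab_ag", family=fam, family_variant=var,
                      receptor_group=rg, conformer=conf, transform=tr))
    plan += [
        P("abag16", "ab_ag", defect="resolution", family=1,
          receptor_group="R1", conformer="A"),
        P("abag17", "ab_ag", defect="no_resolution", family=1,
          receptor_group="R1", conformer="A"),
        P("abag18", "ab_ag", defect="missing_cdr", family=1,
          receptor_group="R1", conformer="A"),
        P("abag19", "ab_ag", defect="short_antigen", family=1,
          receptor_group="R1", conformer="A"),
    ]
    # non-peptidic Ab-Ag: 2 CDR groups among the 4 kept
    for i, (rg, defect) in enumerate([("Q1", None), ("Q1", None),
                                      ("Q2", None), ("Q2", None),
                                      ("Q1", "resolution")]):
        plan.append(P(f"abnp{i:02d}", "ab_ag", peptidic=False,
                      defect=defect, receptor_group=rg))
    # TCR-pMHC: 3 core clusters, 4 TCR groups, 3 MHC groups;
    # 6 full clusters vs 5 TCR-epitope groups
    tcr = [  # (core cluster, variant, receptor, mhc, transform)
        ((1, 0), "T1", "m1", False), ((1, 0), "T1", "m2", False),
        ((1, 1), "T1", "m1", False), ((2, 0), "T2", "m1", False),
        ((2, 1), "T2", "m1", True), ((2, 0), "T3", "m3", False),
        ((3, 0), "T3", "m3", False), ((3, 0), "T4", "m2", False),
        ((3, 0), "T4", "m2", True),
    ]
    for i, (core, rg, mhc, tr) in enumerate(tcr):
        plan.append(P(f"tcr{i:02d}", "tcr_pmhc", core=core,
                      receptor_group=rg, mhc_group=mhc, transform=tr))
    plan += [
        P("tcr09", "tcr_pmhc", defect="resolution", core=(1, 0),
          receptor_group="T1", mhc_group="m1"),
        P("tcr10", "tcr_pmhc", defect="short_core", core=(1, 0),
          receptor_group="T1", mhc_group="m1"),
        P("tcr11", "tcr_pmhc", defect="missing_cdr", core=(1, 0),
          receptor_group="T1", mhc_group="m1"),
    ]
    for i, (rg, mhc, defect) in enumerate([("U1", "m1", None),
                                           ("U2", "m1", None),
                                           ("U1", "m1", "resolution")]):
        plan.append(P(f"tnp{i:02d}", "tcr_pmhc", peptidic=False, defect=defect,
                      receptor_group=rg, mhc_group=mhc))
    # MHC-ligand: 4 core clusters, 3 MHC groups, 5 distinct pairs
    mhl = [((1, 0), "m1"), ((1, 1), "m1"), ((2, 0), "m1"), ((2, 0), "m2"),
           ((3, 0), "m2"), ((3, 0), "m2"), ((4, 0), "mn"), ((4, 0), "mn")]
    for i, (core, mhc) in enumerate(mhl):
        plan.append(P(f"mhl{i:02d}", "mhc_ligand", core=core, mhc_group=mhc,
                      transform=(i == 5)))
    plan += [
        P("mhl08", "mhc_ligand", defect="resolution", core=(1, 0),
          mhc_group="m1"),
        P("mhl09", "mhc_ligand", defect="short_core", core=(1, 0),
          mhc_group="m1"),
    ]
    for i, mhc in enumerate(["m1", "m1", "m2", "m2"]):
        plan.append(P(f"mnp{i:02d}", "mhc_ligand", peptidic=False,
                      mhc_group=mhc))
    return plan


def minimal_plan() -> list[PlannedComplex]:
    P = PlannedComplex
    return [
        P("abag00", "ab_ag", family=1, receptor_group="R1", conformer="A"),
        P("abag01", "ab_ag", family=1, receptor_group="R1", conformer="A",
          transform=True),
        P("abag02", "ab_ag", defect="resolution", family=1,
          receptor_group="R1", conformer="A"),
        P("abnp00", "ab_ag", peptidic=False, receptor_group="Q1"),
        P("tcr00", "tcr_pmhc", core=(1, 0), receptor_group="T1",
          mhc_group="m1"),
        P("tcr01", "tcr_pmhc", core=(1, 0), receptor_group="T1",
          mhc_group="m1", transform=True),
        P("mhl00", "mhc_ligand", core=(1, 0), mhc_group="m1"),
    ]


def stress_plan() -> list[PlannedComplex]:
    """Standard plus transformed duplicates that join existing clusters."""
    P = PlannedComplex
    plan = standard_plan()
    for i in range(2):
        plan.append(P(f"abagx{i}", "ab_ag", family=1, family_variant=0,
                      receptor_group="R1", conformer="A", transform=True))
        plan.append(P(f"tcrx{i}", "tcr_pmhc", core=(1, 0),
                      receptor_group="T1", mhc_group="m1", transform=True))
        plan.append(P(f"mhlx{i}", "mhc_ligand", core=(1, 0), mhc_group="m1",
                      transform=True))
    return plan


PLANS: dict[str, Callable[[], list[PlannedComplex]]] = {
    "minimal": minimal_plan,
    "standard": standard_plan,
    "stress": stress_plan,
}


# ---------------------------------------------------------------------------
# Geometry primitives

def _path(i: int, y: float, ncol: int = 15, dx: float = 3.8,
          dz: float = 4.5) -> np.ndarray:
    """Serpentine grid position of residue i (keeps chains in a 100 A box)."""
    row, col = divmod(i, ncol)
    x = dx * col if row % 2 == 0 else dx * (ncol - 1 - col)
    return np.array([x, y, dz * row])


def _residue_atoms(ca: np.ndarray, hover: int = 0) -> list[tuple[str, str, np.ndarray]]:
    """Backbone + CB offsets.  hover=+1/-1 points CB at the antigen so the
    CB-CA contact distance is exactly 3.8 A."""
    s = hover if hover else 1
    if hover:
        offs = [("N", "N", (-1.2, 0.6 * s, 0.0)), ("CA", "C", (0, 0, 0)),
                ("C", "C", (1.2, 0.6 * s, 0.0)), ("O", "O", (1.4, 0.6 * s, 1.4)),
                ("CB", "C", (0.0, -1.5 * s, 0.0))]
    else:
        offs = [("N", "N", (-1.2, 0.6, 0.0)), ("CA", "C", (0, 0, 0)),
                ("C", "C", (1.2, 0.6, 0.0)), ("O", "O", (1.4, 0.6, 1.4)),
                ("CB", "C", (0.0, 0.0, -1.4))]
    return [(name, el, ca + np.array(off)) for name, el, off in offs]


ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET",
    "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER",
    "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR", "G": "GLY",
}


def _make_residue(chain_id: str, idx: int, letter: str, ca: np.ndarray,
                  hover: int = 0) -> Residue:
    atoms = [Atom(name=n, element=el, position=p)
             for n, el, p in _residue_atoms(ca, hover)]
    return Residue(chain_id=chain_id, seq_index=idx, author_number=idx + 1,
                   insertion_code="", name3=ONE_TO_THREE[letter],
                   one_letter=letter, atoms=atoms, is_standard_aa=True)


def _antigen_chain(chain_id: str, seq: str) -> Chain:
    residues = [_make_residue(chain_id, i, aa, _path(i, 0.0))
                for i, aa in enumerate(seq)]
    return Chain(chain_id=chain_id, residues=residues)


def _ligand_chain(chain_id: str = "X") -> Chain:
    atoms = [Atom(name=f"C{j+1}", element="C",
                  position=np.array([45.0 + 1.5 * j, 0.0, -8.0]))
             for j in range(5)]
    res = Residue(chain_id=chain_id, seq_index=0, author_number=1,
                  insertion_code="", name3="LIG", one_letter="X",
                  atoms=atoms, is_standard_aa=False)
    return Chain(chain_id=chain_id, residues=[res])


def _receptor_chain(role: str, cdrs: tuple[str, str, str], rng,
                    hover_targets: Sequence[int] = (),
                    antigen_ca=None) -> tuple[Chain, list[tuple[int, str, str]]]:
    """A receptor chain: framework segments + three CDRs, with the leading
    CDR3 residues hovering over the planted antigen anchors.  Returns the
    chain and its IMGT numbering."""
    cdr1, cdr2, cdr3 = cdrs
    segments: list[tuple[int, str]] = []  # (imgt start, letters)
    fw = ["".join(rng.choice(list(ALPHABET), hi - lo + 1))
          for lo, hi in FW_RANGES]
    segments = [(FW_RANGES[0][0], fw[0]), (CDR_RANGES["cdr1"][0], cdr1),
                (FW_RANGES[1][0], fw[1]), (CDR_RANGES["cdr2"][0], cdr2),
                (FW_RANGES[2][0], fw[2]), (CDR_RANGES["cdr3"][0], cdr3),
                (FW_RANGES[3][0], fw[3])]
    numbering: list[tuple[int, str, str]] = []
    letters: list[str] = []
    cdr3_chain_idx: list[int] = []
    idx = 0
    for start, seg in segments:
        for k, aa in enumerate(seg):
            numbering.append((start + k, "", aa))
            letters.append(aa)
            if start == CDR_RANGES["cdr3"][0]:
                cdr3_chain_idx.append(idx)
            idx += 1

    hover_of: dict[int, int] = {}
    if hover_targets:
        if len(cdr3_chain_idx) < len(hover_targets):
            raise ValueError("CDR3 too short for the planted anchors")
        for j, target in enumerate(hover_targets):
            hover_of[cdr3_chain_idx[j]] = target

    chain_id = CHAIN_ID[role]
    residues = []
    far_i = 0
    extra_i = 0
    anchor0_x = antigen_ca(hover_targets[0])[0] if hover_targets else 0.0
    anchor_z = antigen_ca(hover_targets[0])[2] if hover_targets else 0.0
    for i, aa in enumerate(letters):
        if i in hover_of:
            t = antigen_ca(hover_of[i])
            ca = np.array([t[0], 5.3, t[2]])
            residues.append(_make_residue(chain_id, i, aa, ca, hover=+1))
        elif hover_targets and i in cdr3_chain_idx:
            # spare CDR3 residues: elevated above the anchor area, no contact
            ca = np.array([anchor0_x + 3.8 * extra_i, 12.0, anchor_z])
            extra_i += 1
            residues.append(_make_residue(chain_id, i, aa, ca))
        else:
            residues.append(_make_residue(chain_id, i, aa,
                                          _path(far_i, FAR_Y[role])))
            far_i += 1
    return Chain(chain_id=chain_id, residues=residues), numbering


def _mhc_chain(role: str, sequence: str,
               platform_targets: Sequence[int] = (),
               antigen_ca=None) -> Chain:
    """An MHC chain; ``platform_targets`` are antigen residue indices that
    its platform residues hover below (contact plant)."""
    chain_id = CHAIN_ID[role]
    platform = {PLATFORM_START + j: t for j, t in enumerate(platform_targets)}
    residues = []
    far_i = 0
    for i, aa in enumerate(sequence):
        if i in platform:
            t = antigen_ca(platform[i])
            ca = np.array([t[0], -5.3, t[2]])
            residues.append(_make_residue(chain_id, i, aa, ca, hover=-1))
        else:
            residues.append(_make_residue(chain_id, i, aa,
                                          _path(far_i, FAR_Y[role])))
            far_i += 1
    return Chain(chain_id=chain_id, residues=residues)


def _rigid_transform(coords: np.ndarray, angle_z: float = 0.31,
                     angle_x: float = 0.14,
                     translation=(3.0, 2.0, 1.0)) -> np.ndarray:
    """Modest rotation about the centroid plus a translation (keeps the
    structure inside the 100 A box)."""
    cz, sz = np.cos(angle_z), np.sin(angle_z)
    cx, sx = np.cos(angle_x), np.sin(angle_x)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    centroid = coords.mean(axis=0)
    return (coords - centroid) @ (rz @ rx).T + centroid + np.array(translation)


def _apply_transform(model: StructureModel) -> None:
    coords = np.array([a.position for c in model.chains
                       for r in c.residues for a in r.atoms])
    moved = _rigid_transform(coords)
    k = 0
    for chain in model.chains:
        for res in chain.residues:
            res.atoms = [Atom(name=a.name, element=a.element,
                              position=moved[k + j], occupancy=a.occupancy,
                              altloc=a.altloc)
                         for j, a in enumerate(res.atoms)]
            k += len(res.atoms)


def make_site_pair(template: np.ndarray, jitter: float = 0.0,
                   rng=None) -> tuple[np.ndarray, np.ndarray]:
    """A site and its rigid transform plus optional per-atom Gaussian
    jitter; jitter 0 guarantees PMax = PMin = 1."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = rng or np.random.default_rng(0)
    moved = _rigid_transform(np.asarray(template, dtype=float))
    if jitter > 0:
        moved = moved + rng.normal(0.0, jitter, size=moved.shape)
    return np.asarray(template, dtype=float), moved


# ---------------------------------------------------------------------------
# Sequence materials

def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(ALPHABET), n))


def _mutate(rng, seq: str, k: int) -> str:
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in positions:
        choices = [c for c in ALPHABET if c != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


class _Materials:
    """All planted sequences, derived deterministically from the seed."""

    def __init__(self, plan: Sequence[PlannedComplex], rng):
        self.rng = rng
        fams = sorted({(p.family, p.family_variant) for p in plan
                       if p.family is not None})
        bases: dict[int, str] = {}
        self.antigens: dict[tuple[int, int], str] = {}
        for fam, var in fams:
            if fam not in bases:
                bases[fam] = _random_seq(rng, ANTIGEN_LEN)
            self.antigens[(fam, var)] = (bases[fam] if var == 0
                                         else _mutate(rng, bases[fam], 8))
        self.family_bases = bases

        groups = sorted({p.receptor_group for p in plan if p.receptor_group})
        self.cdrs: dict[str, dict[str, tuple[str, str, str]]] = {}
        for g in groups:
            roles = (("alpha", "beta") if g[0] in "TU" else ("heavy", "light"))
            self.cdrs[g] = {
                role: tuple(_random_seq(rng, n) for n in CDR_LENGTHS[role])
                for role in roles
            }

        core_ids = sorted({p.core for p in plan if p.core})
        core_bases: dict[int, str] = {}
        self.cores: dict[tuple[int, int], str] = {}
        for cid, var in core_ids:
            if cid not in core_bases:
                core_bases[cid] = _random_seq(rng, 9)
            self.cores[(cid, var)] = (core_bases[cid] if var == 0
                                      else _mutate(rng, core_bases[cid], 1))
        self.core_bases = core_bases

        self.refs = [GDomainRef(rid, cls, dom, _random_seq(rng, n))
                     for rid, cls, dom, n in GDOMAIN_SPECS]
        self.ref_by_id = {r.ref_id: r for r in self.refs}
        self.nonclassical_seq = _random_seq(rng, 200)

    def mhc_sequences(self, group: str) -> dict[str, str]:
        """role -> full chain sequence for one planted MHC group; flanks
        vary per call (per complex) while the embedded G-domain stays
        byte-identical, so clustering keys agree across flank variation."""
        rng = self.rng

        def embed(ref_id):
            return (_random_seq(rng, 15) + self.ref_by_id[ref_id].sequence
                    + _random_seq(rng, 15))

        if group == "m1":
            return {"mhc_a": embed("GD1")}
        if group == "m2":
            return {"mhc_a": embed("GD2")}
        if group == "m3":
            return {"mhc_a": embed("GDA1"), "mhc_b": embed("GDB1")}
        if group == "mn":
            return {"mhc_a": self.nonclassical_seq}
        raise ValueError(f"unknown MHC group {group}")


# ---------------------------------------------------------------------------
# Closed-form expected counts

_DEFECT_FILTER = {"resolution": "resolution", "no_resolution": "resolution",
                  "missing_cdr": "missing_cdr", "short_antigen": "length",
                  "short_core": "length"}


def _attrition(planned: Sequence[PlannedComplex]) -> dict[str, int]:
    att = {"mhc_filter": 0, "resolution": 0, "r_free": 0,
           "missing_cdr": 0, "length": 0}
    for p in planned:
        if p.defect:
            att[_DEFECT_FILTER[p.defect]] += 1
    return att


def expected_counts(plan: Sequence[PlannedComplex]) -> dict:
    """Expected pipeline output, computed from the plant tables alone."""
    out: dict = {}
    for branch in ("ab_ag", "tcr_pmhc", "mhc_ligand"):
        rows = [p for p in plan if p.branch == branch]
        pep = [p for p in rows if p.peptidic]
        kept = [p for p in pep if p.defect is None]
        entry = {"total": len(rows), "peptidic": len(pep),
                 "post_filter": len(kept), "attrition": _attrition(pep)}
        if branch == "ab_ag":
            entry["antigen_clusters"] = len({p.family for p in kept})
            entry["receptor_clusters"] = len({p.receptor_group for p in kept})
            entry["distinct_pairs"] = len({(p.receptor_group, p.conformer)
                                           for p in kept})
        elif branch == "tcr_pmhc":
            entry["core_clusters"] = len({p.core[0] for p in kept})
            entry["receptor_clusters"] = len({p.receptor_group for p in kept})
            entry["mhc_clusters"] = len({p.mhc_group for p in kept})
            entry["full_clusters"] = len({(p.core[0], p.receptor_group,
                                           p.mhc_group) for p in kept})
            entry["receptor_epitope_groups"] = len({(p.core[0],
                                                     p.receptor_group)
                                                    for p in kept})
        else:
            entry["core_clusters"] = len({p.core[0] for p in kept})
            entry["mhc_clusters"] = len({p.mhc_group for p in kept})
            entry["distinct_pairs"] = len({(p.core[0], p.mhc_group)
                                           for p in kept})
        out[branch] = entry

    np_entry: dict = {}
    for branch in ("ab_ag", "tcr_pmhc", "mhc_ligand"):
        rows = [p for p in plan if p.branch == branch and not p.peptidic]
        kept = [p for p in rows if p.defect is None]
        att = _attrition(rows)
        att.pop("length")
        att.pop("r_free")
        entry = {"total": len(rows), "post_filter": len(kept),
                 "attrition": {"mhc_filter": att["mhc_filter"],
                               "resolution": att["resolution"], "r_free": 0,
                               "missing_cdr": att["missing_cdr"], "length": 0}}
        if kept and branch in ("ab_ag", "tcr_pmhc"):
            entry["receptor_clusters"] = len({p.receptor_group for p in kept})
        if kept and branch in ("tcr_pmhc", "mhc_ligand"):
            entry["mhc_clusters"] = len({p.mhc_group for p in kept})
        np_entry[branch] = entry
    out["non_peptidic"] = np_entry
    return out


# ---------------------------------------------------------------------------
# Corpus assembly

def _build_complex(p: PlannedComplex, mat: _Materials) -> tuple[StructureModel, dict]:
    rng = mat.rng
    chains: list[Chain] = []
    ann: dict = {"structure_id": p.structure_id,
                 "coordinate_file": f"{p.structure_id}.pdb",
                 "receptor_chain_roles": {}, "antigen_chain_ids": [],
                 "numbering": {}, "organism": "synthetic"}

    if p.branch == "ab_ag":
        ann["complex_type"] = "AB_AG"
        if p.peptidic:
            seq = mat.antigens[(p.family, p.family_variant)]
            if p.defect == "short_antigen":
                seq = seq[:SHORT_ANTIGEN_LEN]
            antigen = _antigen_chain("G", seq)
            anchors = CONFORMER_ANCHORS[p.conformer]
            ann["antigen_chain_ids"] = ["G"]
        else:
            antigen = _ligand_chain("X")
            anchors = ()
            ann["antigen_chain_ids"] = ["X"]
        chains.append(antigen)
        antigen_ca = (lambda i: _path(i, 0.0))
        for role in ("heavy", "light"):
            cdrs = mat.cdrs[p.receptor_group][role]
            hover = anchors if role == "heavy" else ()
            chain, numbering = _receptor_chain(role, cdrs, rng,
                                               hover_targets=hover,
                                               antigen_ca=antigen_ca)
            chains.append(chain)
            ann["receptor_chain_roles"][chain.chain_id] = role
            ann["numbering"][chain.chain_id] = [list(t) for t in numbering]
    else:
        is_tcr = p.branch == "tcr_pmhc"
        ann["complex_type"] = "TCR_PMHC" if is_tcr else "MHC_LIGAND"
        antigen_ca = (lambda i: _path(i, 0.0))
        targets: Sequence[int] = ()
        if p.peptidic:
            core = mat.cores[p.core]
            pep = _random_seq(rng, 1) + core + _random_seq(rng, 1)
            chains.append(_antigen_chain("P", pep))
            ann["antigen_chain_ids"] = ["P"]
            targets = (SHORT_CORE_TARGETS if p.defect == "short_core"
                       else CORE_TARGETS)
        else:
            chains.append(_ligand_chain("X"))
            ann["antigen_chain_ids"] = ["X"]
        if is_tcr:
            for role in ("alpha", "beta"):
                cdrs = mat.cdrs[p.receptor_group][role]
                hover = TCR_HOVER if (role == "alpha" and p.peptidic) else ()
                chain, numbering = _receptor_chain(role, cdrs, rng,
                                                   hover_targets=hover,
                                                   antigen_ca=antigen_ca)
                chains.append(chain)
                ann["receptor_chain_roles"][chain.chain_id] = role
                ann["numbering"][chain.chain_id] = [list(t) for t in numbering]
        for role, seq in mat.mhc_sequences(p.mhc_group).items():
            platform = targets if role == "mhc_a" else ()
            chain = _mhc_chain(role, seq, platform_targets=platform,
                               antigen_ca=antigen_ca)
            chains.append(chain)
            ann["receptor_chain_roles"][chain.chain_id] = role
        ann["mhc_class"] = {"m1": "I", "m2": "I", "m3": "II",
                            "mn": "non_classical"}[p.mhc_group]

    resolution: Optional[float] = round(1.8 + 0.1 * (rng.integers(0, 9)), 2)
    if p.defect == "resolution":
        resolution = 3.4
    elif p.defect == "no_resolution":
        resolution = None
    r_free = round(0.20 + 0.01 * int(rng.integers(0, 9)), 3)

    model = StructureModel(structure_id=p.structure_id, chains=chains,
                           resolution=resolution, r_free=r_free)
    if p.defect == "missing_cdr":
        # delete N and C from the first CDR1 residue of the first receptor chain
        chain = model.chain("H" if p.branch == "ab_ag" else "A")
        entries = ann["numbering"][chain.chain_id]
        idx = next(i for i, (num, _, _) in enumerate(entries)
                   if CDR_RANGES["cdr1"][0] <= num <= CDR_RANGES["cdr1"][1])
        res = chain.residues[idx]
        res.atoms = [a for a in res.atoms if a.name not in ("N", "C")]
    if p.transform:
        _apply_transform(model)
    return model, ann


def _brute_force_contact_residues(model: StructureModel, antigen_id: str,
                                  other_ids: Sequence[str],
                                  cutoff: float = 4.0) -> set[int]:
    """Independent all-pairs oracle used only to validate the plant."""
    ag = model.chain(antigen_id)
    other = np.array([a.position for cid in other_ids
                      for r in model.chain(cid).residues for a in r.atoms])
    touched = set()
    for res in ag.residues:
        pos = np.array([a.position for a in res.atoms])
        d = np.linalg.norm(pos[:, None, :] - other[None, :, :], axis=2)
        if d.min() <= cutoff:
            touched.add(res.seq_index)
    return touched


def _verify_plant(plan, mat: _Materials, models: dict[str, StructureModel]):
    """Cross-check the plant against the similarity kernels and a
    brute-force contact oracle; raise on any inconsistency."""
    # antigen family identities
    kept_ab = [p for p in plan if p.branch == "ab_ag" and p.peptidic
               and p.defect is None]
    for p in kept_ab:
        base = mat.family_bases[p.family]
        seq = mat.antigens[(p.family, p.family_variant)]
        if pairwise_identity(base, seq) < 70.0:
            raise ValueError(f"{p.structure_id}: family variant below 70%")
    fams = sorted(mat.family_bases)
    for i, fa in enumerate(fams):
        for fb in fams[i + 1:]:
            if pairwise_identity(mat.family_bases[fa],
                                 mat.family_bases[fb]) >= 70.0:
                raise ValueError(f"families {fa}/{fb} not separable at 70%")
    # core cluster identities
    cids = sorted(mat.core_bases)
    for (cid, var), seq in mat.cores.items():
        if pairwise_identity(mat.core_bases[cid], seq) < 85.0:
            raise ValueError(f"core {cid}.{var} below 85%")
    for i, ca in enumerate(cids):
        for cb in cids[i + 1:]:
            if pairwise_identity(mat.core_bases[ca],
                                 mat.core_bases[cb]) >= 85.0:
                raise ValueError(f"cores {ca}/{cb} not separable at 85%")
    # receptor groups pairwise distinct
    keys = {g: tuple(v for role in sorted(d) for v in d[role])
            for g, d in mat.cdrs.items()}
    if len(set(keys.values())) != len(keys):
        raise ValueError("planted CDR groups collide")
    # epitope conformers: self vs transform = identity; cross not similar
    sites = {}
    for conf, anchors in CONFORMER_ANCHORS.items():
        coords = np.concatenate([
            [pos for _, _, pos in _residue_atoms(_path(i, 0.0))]
            for i in anchors])
        sites[conf] = EpitopeSite(residues=[("G", i) for i in anchors],
                                  coords=coords, complex_ref=f"conf{conf}")
    for conf, site in sites.items():
        a, b = make_site_pair(site.coords, jitter=0.0)
        score = pocketmatch_score(site,
                                  EpitopeSite(site.residues, b, "t"))
        if not (score.pmax == score.pmin == 1.0):
            raise ValueError(f"conformer {conf} not rigid-invariant")
    cross = pocketmatch_score(sites["A"], sites["B"])
    if sites_similar(cross):
        raise ValueError("planted conformers A/B are not separable")
    # G-domain mapping recovers each planted reference exactly
    for group in sorted({p.mhc_group for p in plan if p.mhc_group}):
        for role, seq in mat.mhc_sequences(group).items():
            hit = map_g_domain(seq, mat.refs)
            if group == "mn":
                if hit is not None:
                    raise ValueError("non-classical sequence mapped to a ref")
            else:
                if hit is None or hit.mapped_sequence not in seq:
                    raise ValueError(f"G-domain mapping failed for {group}")
                if hit.mapped_sequence != mat.ref_by_id[hit.ref_id].sequence:
                    raise ValueError(f"G-domain boundaries wrong for {group}")
    # planted contacts match the brute-force oracle; geometry bounded
    for p in plan:
        model = models[p.structure_id]
        coords = np.array([a.position for c in model.chains
                           for r in c.residues for a in r.atoms])
        if (coords.max(axis=0) - coords.min(axis=0)).max() > 100.0:
            raise ValueError(f"{p.structure_id}: outside the 100 A box")
        if not p.peptidic:
            continue
        if p.branch == "ab_ag":
            expected = set(CONFORMER_ANCHORS[p.conformer])
            touched = _brute_force_contact_residues(model, "G", ["H", "L"])
        else:
            targets = (SHORT_CORE_TARGETS if p.defect == "short_core"
                       else CORE_TARGETS)
            expected = set(targets)
            others = [c.chain_id for c in model.chains
                      if c.chain_id not in ("P",)]
            touched = _brute_force_contact_residues(model, "P", others)
        if touched != expected:
            raise ValueError(
                f"{p.structure_id}: planted contacts {sorted(expected)} != "
                f"realized {sorted(touched)}")


def make_corpus(out_dir, profile: str = "standard", seed: int = 42) -> Path:
    """Generate a corpus; returns the manifest path.

    Writes one PDB + one annotation JSON per complex, the G-domain
    reference FASTA, the expected-counts record derived from the plant,
    and a manifest listing everything.  Identical seed and profile give
    byte-identical output.
    """
    if profile not in PLANS:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PLANS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = PLANS[profile]()
    rng = np.random.default_rng(seed)
    mat = _Materials(plan, rng)

    models: dict[str, StructureModel] = {}
    annotations: dict[str, dict] = {}
    for p in plan:
        model, ann = _build_complex(p, mat)
        models[p.structure_id] = model
        annotations[p.structure_id] = ann

    _verify_plant(plan, mat, models)

    for p in plan:
        write_pdb(models[p.structure_id], out_dir / f"{p.structure_id}.pdb")
        (out_dir / f"{p.structure_id}.json").write_text(
            json.dumps(annotations[p.structure_id], indent=1, sort_keys=True)
            + "\n")
    fasta = "".join(f">{r.ref_id} class={r.mhc_class} domain={r.domain_tag}\n"
                    f"{r.sequence}\n" for r in mat.refs)
    (out_dir / "gdomain_refs.fasta").write_text(fasta)
    (out_dir / "expected_counts.json").write_text(
        json.dumps(expected_counts(plan), indent=1, sort_keys=True) + "\n")

    manifest = {
        "seed": seed,
        "profile": profile,
        "complexes": [{"structure_id": p.structure_id,
                       "annotation": f"{p.structure_id}.json"}
                      for p in plan],
        "g_domain_refs": "gdomain_refs.fasta",
        "expected_counts": "expected_counts.json",
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True)
                             + "\n")
    return manifest_path
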