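"""Coordinate parsing, metadata extraction and the fixture PDB dialect."""

import numpy as np
import pytest

from immunobench import (chain_sequence, classify_antigen, parse_structure,
                         write_pdb)
from immunobench.structures import ParseError

from conftest import ca_chain, make_record


def _pdb_atom(serial, name, altloc, resname, chain, resnum, x, y, z,
              occ=1.0, element=None, record="ATOM"):
    element = element or name[0]
    name_f = name if len(name) >= 4 else f" {name:<3}"
    return (f"{record:<6}{serial:>5} {name_f}{altloc:1}{resname:>3} "
            f"{chain}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{0.0:6.2f}          {element:>2}")


def test_parse_pdb_header_and_chains(tmp_path):
    lines = ["REMARK   2 RESOLUTION.    2.50 ANGSTROMS."]
    serial = 1
    for chain in "AB":
        for i in range(5):
            lines.append(_pdb_atom(serial, "CA", " ", "ALA", chain, i + 1,
                                   3.8 * i, 0.0, 0.0 if chain == "A" else 20.0))
            serial += 1
    path = tmp_path / "two_chains.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    model = parse_structure(path)
    assert len(model.chains) == 2
    assert [len(c.residues) for c in model.chains] == [5, 5]
    assert model.resolution == pytest.approx(2.5)


def test_parse_pdb_without_resolution(tmp_path):
    path = tmp_path / "nores.pdb"
    path.write_text(_pdb_atom(1, "CA", " ", "GLY", "A", 1, 0, 0, 0) + "\nEND\n")
    model = parse_structure(path)
    assert model.resolution is None
    assert model.r_free is None


def test_parse_mmcif_resolution_and_rfree(tmp_path):
    cif = """data_test
_refine.ls_d_res_high 1.90
_refine.ls_R_factor_R_free 0.28
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 ? 0.0 0.0 0.0 1.0 10.0 1 A 1
ATOM 2 C CA . GLY A 1 2 ? 3.8 0.0 0.0 1.0 10.0 2 A 1
"""
    path = tmp_path / "rfree.cif"
    path.write_text(cif)
    model = parse_structure(path, dialect="mmcif")
    assert model.r_free == pytest.approx(0.28)
    assert model.resolution == pytest.approx(1.9)
    assert model.chains[0].sequence == "AG"


def test_altloc_keeps_highest_occupancy_and_prefers_a_on_tie(tmp_path):
    lines = [
        _pdb_atom(1, "CA", "A", "ALA", "A", 1, 0, 0, 0, occ=0.4),
        _pdb_atom(2, "CA", "B", "ALA", "A", 1, 5, 0, 0, occ=0.6),
        _pdb_atom(3, "CB", "A", "ALA", "A", 1, 1, 1, 1, occ=0.5),
        _pdb_atom(4, "CB", "B", "ALA", "A", 1, 9, 9, 9, occ=0.5),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    res = parse_structure(path).chains[0].residues[0]
    assert len(res.atoms) == 2  # collapse never increases atom count
    assert res.atom("CA").position[0] == pytest.approx(5.0)  # occ 0.6 wins
    assert res.atom("CB").position[0] == pytest.approx(1.0)  # tie -> altloc A


def test_hydrogens_and_waters_discarded(tmp_path):
    lines = [
        _pdb_atom(1, "CA", " ", "ALA", "A", 1, 0, 0, 0),
        _pdb_atom(2, "HA", " ", "ALA", "A", 1, 0.5, 0.5, 0, element="H"),
        _pdb_atom(3, "O", " ", "HOH", "A", 2, 30, 0, 0, record="HETATM"),
    ]
    path = tmp_path / "hyd.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    model = parse_structure(path)
    assert len(model.chains[0].residues) == 1
    assert [a.name for a in model.chains[0].residues[0].atoms] == ["CA"]


def test_pdb_round_trip(tmp_path, standard_corpus):
    source = standard_corpus["records"][0].structure
    out = tmp_path / "rt.pdb"
    write_pdb(source, out)
    reparsed = parse_structure(out)
    assert [c.chain_id for c in reparsed.chains] == \
        [c.chain_id for c in source.chains]
    assert reparsed.resolution == pytest.approx(source.resolution)
    assert reparsed.r_free == pytest.approx(source.r_free, abs=1e-3)
    for c_in, c_out in zip(source.chains, reparsed.chains):
        assert len(c_in.residues) == len(c_out.residues)
        for r_in, r_out in zip(c_in.residues, c_out.residues):
            assert r_in.name3 == r_out.name3
            for a_in, a_out in zip(r_in.atoms, r_out.atoms):
                assert a_in.name == a_out.name
                assert np.allclose(a_in.position, a_out.position, atol=1e-3)


def test_parse_is_deterministic(standard_corpus):
    path = standard_corpus["dir"] / "abag00.pdb"
    m1, m2 = parse_structure(path), parse_structure(path)
    pos1 = [a.position.tolist() for c in m1.chains
            for r in c.residues for a in r.atoms]
    pos2 = [a.position.tolist() for c in m2.chains
            for r in c.residues for a in r.atoms]
    assert pos1 == pos2


def test_parse_errors(tmp_path):
    with pytest.raises(ParseError):
        parse_structure(tmp_path / "missing.pdb")
    bad = tmp_path / "empty.pdb"
    bad.write_text("HEADER    ONLY A HEADER\nEND\n")
    with pytest.raises(ParseError):
        parse_structure(bad)


def test_chain_sequence_skips_nonstandard(tmp_path):
    lines = [
        _pdb_atom(1, "CA", " ", "ALA", "A", 1, 0, 0, 0),
        _pdb_atom(2, "FE", " ", "HEM", "A", 2, 10, 0, 0, element="FE",
                  record="HETATM"),
        _pdb_atom(3, "CA", " ", "GLY", "A", 3, 20, 0, 0),
    ]
    path = tmp_path / "het.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    chain = parse_structure(path).chains[0]
    assert chain_sequence(chain) == "AG"


def test_classify_antigen_rules():
    peptide = ca_chain("P", [(i * 10.0, 0, 0) for i in range(9)])
    mhc = ca_chain("M", [(0, -30.0, 0)])
    rec = make_record([peptide, mhc], "MHC_LIGAND", {"M": "mhc_a"}, ["P"])
    assert classify_antigen(rec) == "peptidic"

    glycan = ca_chain("X", [(0, 0, 0)])
    glycan.residues[0].is_standard_aa = False
    glycan.residues[0].name3 = "NAG"
    rec2 = make_record([glycan, mhc], "MHC_LIGAND", {"M": "mhc_a"}, ["X"])
    assert classify_antigen(rec2) == "non_peptidic"

    # hybrid chain: three amino acids plus a sugar -> still peptidic
    hybrid = ca_chain("H", [(i * 10.0, 0, 0) for i in range(4)])
    hybrid.chain_id = "Y"
    for r in hybrid.residues:
        r.chain_id = "Y"
    hybrid.residues[3].is_standard_aa = False
    hybrid.residues[3].name3 = "NAG"
    rec3 = make_record([hybrid, mhc], "MHC_LIGAND", {"M": "mhc_a"}, ["Y"])
    assert classify_antigen(rec3) == "peptidic"


def test_non_peptidic_chain_has_empty_sequence():
    lig = ca_chain("X", [(0, 0, 0), (2, 0, 0)])
    for r in lig.residues:
        r.is_standard_aa = False
        r.name3 = "LIG"
    assert chain_sequence(lig) == ""
    assert lig.molecule_kind == "non-peptidic"
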