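"""Shared fixtures: a session-scoped synthetic corpus and small builders
for hand-placed toy complexes used in interface/filter tests."""

from __future__ import annotations

import json

import numpy as np
import pytest

from immunobench import FilterConfig, load_manifest, make_corpus
from immunobench.annotation import NumberedChain
from immunobench.structures import (Atom, Chain, ComplexRecord, ComplexType,
                                    Residue, StructureModel)


@pytest.fixture(scope="session")
def standard_corpus(tmp_path_factory):
    """Standard fixture corpus (seed 42) plus loaded records/refs/expected."""
    out = tmp_path_factory.mktemp("corpus")
    manifest_path = make_corpus(out, profile="standard", seed=42)
    records, refs, manifest = load_manifest(manifest_path)
    expected = json.loads((out / "expected_counts.json").read_text())
    return {"dir": out, "manifest_path": manifest_path, "records": records,
            "refs": refs, "expected": expected, "manifest": manifest}


@pytest.fixture()
def default_config():
    return FilterConfig()


# ---------------------------------------------------------------------------
# Toy-structure builders


def make_residue(chain_id, idx, letter="A", atoms=None, name3=None,
                 standard=True):
    """A residue from (atom_name, xyz) pairs; defaults to a lone CA."""
    if atoms is None:
        atoms = [("CA", (0.0, 0.0, 0.0))]
    return Residue(
        chain_id=chain_id, seq_index=idx, author_number=idx + 1,
        insertion_code="", name3=name3 or "ALA", one_letter=letter,
        atoms=[Atom(name=n, element=n[0], position=np.asarray(p, dtype=float))
               for n, p in atoms],
        is_standard_aa=standard,
    )


def ca_chain(chain_id, positions, letters=None):
    """A chain of CA-only residues at the given coordinates."""
    letters = letters or "A" * len(positions)
    return Chain(chain_id=chain_id, residues=[
        make_residue(chain_id, i, letters[i], [("CA", pos)])
        for i, pos in enumerate(positions)])


def backbone_chain(chain_id, letters, origin=(0.0, 0.0, 0.0), spacing=10.0):
    """A chain whose residues carry full N/CA/C/O backbones, spaced widely
    so contact sets are unambiguous."""
    ox, oy, oz = origin
    residues = []
    for i, aa in enumerate(letters):
        base = np.array([ox + spacing * i, oy, oz])
        atoms = [("N", base + (-1.0, 0.5, 0)), ("CA", base),
                 ("C", base + (1.0, 0.5, 0)), ("O", base + (1.2, 1.5, 0))]
        residues.append(make_residue(chain_id, i, aa, atoms))
    return Chain(chain_id=chain_id, residues=residues)


def simple_numbering(chain, start_imgt=27):
    """IMGT numbering that walks the chain in order from a start position
    (default: inside CDR1)."""
    return NumberedChain(
        chain_id=chain.chain_id, receptor_role="heavy",
        positions=[(start_imgt + i, "", r.one_letter)
                   for i, r in enumerate(chain.residues)])


def make_record(chains, complex_type, roles, antigen_ids, numbering=None,
                structure_id="toy", resolution=2.0, r_free=None):
    model = StructureModel(structure_id=structure_id, chains=list(chains),
                           resolution=resolution, r_free=r_free)
    return ComplexRecord(
        structure=model, complex_type=ComplexType(complex_type),
        receptor_chain_roles=dict(roles), antigen_chain_ids=list(antigen_ids),
        numbered_chains=numbering or {},
    )


def abag_record(antigen_chain, receptor_chains, structure_id="toy",
                resolution=2.0, numbering=None, roles=None):
    roles = roles or {c.chain_id: role for c, role in receptor_chains}
    chains = [antigen_chain] + [c for c, _ in receptor_chains]
    return make_record(chains, "AB_AG", roles, [antigen_chain.chain_id],
                       numbering=numbering, structure_id=structure_id,
                       resolution=resolution)
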