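"""Contacts, epitope sites and core-epitopes on a tiny built complex.

Builds an MHC-peptide toy complex in which only peptide residues 1 and 9
touch the MHC platform (4 A heavy-atom cutoff), then shows that the
core-peptide is the full contiguous span 1..9 — the non-contacting
interior residues count, only the dangling termini are trimmed.
"""

import numpy as np

from immunobench import core_epitope, compute_contacts
from immunobench.interface import atom_records
from immunobench.structures import (Atom, Chain, ComplexRecord, ComplexType,
                                    Residue, StructureModel)


def ca_residue(chain_id, idx, xyz, letter="A"):
    return Residue(chain_id=chain_id, seq_index=idx, author_number=idx + 1,
                   insertion_code="", name3="ALA", one_letter=letter,
                   atoms=[Atom("CA", "C", np.asarray(xyz, float))],
                   is_standard_aa=True)


peptide = Chain("P", [ca_residue("P", i, (10.0 * i, 0, 0), "ILKEPVHGV"[i % 9])
                      for i in range(11)])
platform = Chain("M", [ca_residue("M", i, (xyz, -3.5, 0))
                       for i, xyz in enumerate((10.0, 90.0))])
record = ComplexRecord(
    structure=StructureModel("demo", [peptide, platform], resolution=2.1),
    complex_type=ComplexType.MHC_LIGAND,
    receptor_chain_roles={"M": "mhc_a"},
    antigen_chain_ids=["P"],
)

contacts = compute_contacts(atom_records(record, ["P"]),
                            atom_records(record, ["M"]))
print("contacting peptide residues:",
      sorted(idx for (_, idx), _ in [(c.residue_a, c) for c in contacts]))

core = core_epitope(record)
print(f"core-peptide: residues {core.start_index}..{core.end_index} "
      f"(length {core.length}), sequence {core.sequence!r}")
print("-> residues 0 and 10 are dangling overhangs; the interior residues"
      " 2..8 are inside the span even though they do not contact the MHC.")
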