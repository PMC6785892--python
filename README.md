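# immunobench

Non-redundant structural benchmark datasets of immune receptor–epitope
complexes.

Receptor-specific B- and T-cell epitope prediction methods need
high-quality, non-redundant sets of antibody–antigen (Ab–Ag), TCR–pMHC
and MHC–ligand 3D complexes to train and benchmark on. Deposited
structures are heavily redundant (the same antibody re-solved at several
resolutions, the same peptide on several MHC alleles), and grouping
receptors by full-chain sequence splits receptors with identical binding
loops into different clusters. `immunobench` curates coordinate files
plus chain-role annotations into benchmark tables in which near-duplicate
receptor–epitope pairs are collapsed to cluster representatives.

## What it computes

**Quality filters** (fixed order, attrition reported per filter):
resolution ≤ 3 Å (inclusive; structures without a resolution are
dropped), optional R-free cut, removal of complexes with missing backbone
atoms (N, CA, C) in the CDR loops, antigen ≥ 50 residues (Ab–Ag), and
core ≥ 8 residues (TCR–pMHC, MHC–ligand).

**Interfaces.** Two residues are in contact when any pair of their heavy
atoms is within 4 Å. The *epitope* of an Ab–Ag complex is the set of
antigen residues contacting the antibody. The *core-epitope* of a
TCR–pMHC (or core-peptide of an MHC–ligand) complex is the contiguous
antigen-chain span from the first to the last residue within 4 Å of any
TCR/MHC (or MHC) atom — non-interacting overhangs are trimmed, interior
residues are kept.

**Clusterings.** All threshold-based groupings are single-linkage
(connected components of the pairwise-similarity graph):

* antigen sequences at ≥ 70% identity (BLOSUM62 global alignment,
  gap 10/0.5, identity over the shorter sequence) → labels `Ag<i>`;
* receptor chains by exact CDR identity (IMGT positions 27–38, 56–65,
  105–117), heavy/light and α/β grouped independently → labels `H1_L1`,
  `A2_B1`, …;
* epitope 3D conformations, within each receptor cluster, by PMax/PMin
  scores over sorted intra-site heavy-atom distance lists:

  PMax = matched distance pairs / pairs of the larger site,
  PMin = matched / pairs of the smaller site,

  two epitopes cluster when PMax = 1 or PMin = 1, or PMin ≥ 0.9 and
  PMax ≥ 0.6 → labels `E<i>`;
* core-epitopes/core-peptides at ≥ 85% identity;
* MHC molecules by groove-domain (G-domain) sequence: chains are locally
  aligned against reference G-domains (class I α1–α2; class II α1, β1)
  with e-value ≤ 1e-10 and 90%/85% query/subject coverage; identical
  mapped domains share a label (`a<i>`, `a<i>_b<j>`), unmappable chains
  group on their full sequence as non-classical `n<i>`.

Distinct receptor–epitope pairs are unique label tuples per branch
(e.g. `(receptor, epitope)` for Ab–Ag; `(core, TCR, MHC)` full clusters
and `(core, TCR)` receptor–epitope groups for TCR–pMHC), each with one
best-resolution representative.

A seeded synthetic-corpus generator (`immunobench.fixtures`) builds toy
complexes with planted families, CDR groups, conformers, G-domains and
quality defects, so the whole pipeline runs and is testable with no
downloads.

## Worked example

```sh
immunobench fixtures --profile standard --seed 42 --out-dir corpus
immunobench ab-ag --in corpus/manifest.json --out results/
```

or equivalently from Python (`python examples/03_benchmark_pipeline.py`),
which prints:

```
{
 "antigen_clusters": 6,
 "attrition": {"length": 1, "mhc_filter": 0, "missing_cdr": 1,
               "r_free": 0, "resolution": 2},
 "distinct_pairs": 11,
 "peptidic": 20,
 "post_filter": 16,
 "receptor_clusters": 8,
 "total": 25
}
```

Of 25 Ab–Ag complexes, 20 have peptidic antigens; 2 fail the resolution
filter, 1 has a broken CDR backbone and 1 antigen is shorter than 50
residues, leaving 16. These group into 6 antigen families and 8 receptor
(CDR) clusters, and collapse to 11 distinct receptor–epitope pairs — the
benchmark TSV lists every kept complex with its `Ag`/`H_L`/`E` labels,
its pair id and an `is_representative` flag (best resolution per pair).

The other examples show the interface primitives
(`examples/01_interface_core_epitope.py`), PMax/PMin scoring and the
clustering rule (`examples/02_site_similarity.py`), and G-domain mapping
(`examples/04_mhc_gdomain.py`).

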