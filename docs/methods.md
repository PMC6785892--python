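# Methods

## Scope and data model

`immunobench` turns coordinate files (PDB or mmCIF) plus per-complex
chain-role annotations into non-redundant benchmark tables for three
complex types: antibody–antigen (Ab–Ag), TCR–pMHC and MHC–ligand.
Chain roles (heavy/light, α/β, MHC a/b, antigen) and IMGT numbering of
receptor chains are inputs — roles come from curation and numbering from
an external tool such as ANARCI (or from the fixture generator); the
package never infers them from sequence. Parsing (via gemmi) keeps heavy
atoms only, drops waters/ions/additives, and collapses alternate
locations to the highest-occupancy conformer (ties prefer altloc `A`).
Residue order is file order (0-based `seq_index`); author numbering is
kept only for reporting. Resolution comes from the header, R-free from
the mmCIF `refine` category or the PDB REMARK 3 `FREE R VALUE` line.

## Filters

Evaluation order is fixed — optional MHC class/organism selection, then
resolution, R-free, missing CDR backbone, length — so attrition
accounting is reproducible; the order does not change the kept set.

* **Resolution** ≤ `max_resolution` (default 3.0 Å), boundary inclusive:
  a 3.0 Å structure is kept. Structures without a resolution value
  (e.g. NMR) are excluded while the filter is active — the conservative
  choice for a crystallographic-quality filter.
* **R-free** ≤ `max_r_free`, disabled by default (no recommended value
  is established; the filter exists for users who want it).
* **Missing CDR backbone** (default: drop): a complex is removed when
  any CDR position (IMGT 27–38, 56–65, 105–117) has no resolved residue
  or its residue lacks any of N, CA, C. Backbone means chain trace;
  a missing carbonyl O alone does not trigger the filter. Numbering is
  mapped to structure residues by order (a sequence-matcher alignment of
  the one-letter strings); a substitution-style mismatch cannot be
  aligned and raises.
* **Length**: Ab–Ag antigens need ≥ `min_antigen_len` (default 50)
  resolved standard residues; TCR–pMHC and MHC–ligand complexes need a
  core of ≥ `min_core_len` (default 8) residues. Resolved residues are
  counted, not database sequence length, because the pipeline only sees
  coordinates.

## Interfaces

Contacts use a 4 Å heavy-atom cutoff, inclusive (≤ 4.0); the comparison
convention matters only on a measure-zero boundary but is pinned for
reproducibility. The k-d-tree implementation is property-tested against
an exhaustive all-pairs oracle. The core-epitope is the contiguous span
between the first and last contacting residue on the antigen chain;
interior residues belong to the core whether or not they contact. With
several antigen chains the longest per-chain core wins (the definition
presumes a single peptide). No contacts give a zero-length core, which
the length filter then rejects.

## Binding-site similarity (PMax/PMin)

A binding site is the set of all heavy atoms of the epitope residues.
All n·(n−1)/2 intra-site distances are sorted ascending and two sites'
lists are matched greedily with a two-pointer sweep: advance both on
|da − db| ≤ tol (counting a match), else advance the smaller. For this
interval-overlap matching on sorted lists the greedy is an exact maximum
matching (exchange argument: matching the two current heads is always
safe, and an unmatched smaller head can never match later); the suite
verifies equality with an exhaustive assignment-based oracle. Then

    PMax = matched / max(pairs_a, pairs_b)
    PMin = matched / min(pairs_a, pairs_b)

and two epitopes are conformationally similar iff PMax = 1, or PMin = 1,
or (PMin ≥ 0.9 and PMax ≥ 0.6). Scores depend only on internal
distances, hence are exactly invariant under rigid-body motion.

The distance-match tolerance defaults to **0.5 Å** and is configurable.
This is a deliberate design choice: the tolerance inside PocketMatch
version 2 is not published, and the scheme here follows the
sorted-single-list description rather than PocketMatch's internal
atom-type-binned 90-list algorithm. Sites with fewer than two atoms have
no distance pairs, are unscorable, and become singleton clusters.

## Sequence identity

Pairwise identity uses global alignment (BLOSUM62, gap open 10, extend
0.5) with identity = identical aligned positions / length of the shorter
sequence. The shorter-sequence denominator keeps fragments of an antigen
in the same cluster as the full-length protein, which is what benchmark
curation wants; an alignment-length denominator would split them.
Thresholds: 70% for antigen clustering, 85% for core-epitope/core-peptide
clustering (both configurable).

## MHC G-domain mapping

The groove (G-) domains — α1–α2 for class I, α1 + β1 for class II —
determine peptide-binding specificity, so MHC molecules are classified by
groove sequence rather than by reported allele names. Each MHC chain is
locally aligned (BLOSUM62, 10/0.5) against a reference G-domain set
(FASTA with `class=` / `domain=` header tags; a synthetic reference set
ships with the fixtures, a real one can be supplied). A hit must satisfy

* e-value ≤ 1e-10, computed from the raw score with Karlin–Altschul
  statistics (gapped BLOSUM62 parameters λ = 0.267, K = 0.041; database
  size = total reference length). Coverage thresholds alone are not
  selective: with extension at 0.5 a random query can produce a
  low-score, gap-riddled alignment spanning most of a 90-residue
  reference, and the e-value term is what rejects it.
* subject coverage ≥ 85% of the reference and a query span ≥ 90% of the
  reference length.

The best-scoring hit wins. Class I keys on the mapped α1–α2 sequence
(`a<i>`); class II requires an α1 and a β1 hit across the complex's MHC
chains and keys on the pair (`a<i>_b<j>`, counters independent of class
I); anything unmappable is non-classical and keys on the full chain
sequence(s) (`n<i>`). Byte-identical mapped domains cluster together
even when the flanking sequence (e.g. α3, β2m partner) differs.

## Clustering and nomenclature

Every threshold-based clustering is single-linkage: items are nodes,
"similar" pairs are edges, clusters are connected components. Components
are order-independent, and the cluster count is monotone non-decreasing
in the identity threshold — a property the tests sweep. Items are always
processed in sorted structure-id order and clusters numbered by first
appearance, so labels are stable under input reordering. Receptor
clusters use exact per-chain CDR-key grouping (`CDR1|CDR2|CDR3`, upper-
cased); a missing chain simply omits its component (a nanobody is `H3`).
Epitope-conformation clusters are scoped *within* each receptor cluster
(`E<i>` restarts per receptor cluster); no global epitope clustering is
computed. Distinct pairs are unique label tuples; the representative per
pair is the member with the numerically smallest (best) resolution,
ties broken by lexicographically smallest structure id.

Non-peptidic complexes run a reduced branch: resolution and missing-CDR
filters only, then receptor CDR grouping (Ab–Ag, TCR–pMHC) and MHC
clustering (TCR–pMHC, MHC–ligand); no antigen, epitope or core
clustering is meaningful for small-molecule ligands.

## Synthetic corpus generator

The generator emulates the upstream extraction step: coordinate files
plus annotations with planted ground truth. Peptide chains are idealized
serpentine traces (3.8 Å CA–CA, 4.5 Å row spacing) with N/CA/C/O plus
one CB-like side-chain atom; paratope and MHC-platform residues hover
5.3 Å above/below their targets so that exactly the planted antigen
residues fall inside the 4 Å cutoff (the CB–CA contact distance is
3.8 Å; the nearest non-target atom sits at ≥ 4.1 Å). Epitope conformers
are anchor-index templates — identical templates give byte-identical
site geometry (PMax = PMin = 1 even across rigid transforms), and the
compact vs dispersed templates are verified unsimilar at generation
time. Antigen families are a random 60-mer base plus ≤ 8-point mutants
(≥ 86% to the base, so single linkage connects through the base);
core-peptide clusters are 9-mers with 1-point variants (88.9% ≥ 85%).
MHC chains embed a reference G-domain verbatim between random flanks.
Quality defects (resolution 3.4 Å, absent resolution, a CDR residue
stripped of N and C, a 45-residue antigen, a 6-residue core) plant the
per-filter attrition.

Expected counts are computed in closed form from the plant tables —
counting distinct planted family/CDR/conformer/core/G-domain labels
among non-defective complexes — never by running the pipeline, so the
end-to-end test is non-circular. At generation time the plant is
cross-checked with the similarity kernels (pairwise identities within
and across families, conformer scores, G-domain recovery) and a
brute-force all-pairs contact oracle; any inconsistency raises instead
of silently shipping a bad corpus. All geometry stays inside a 100 Å box
with ≥ 1 Å atom spacing. Everything derives from one seeded
`numpy` generator: the same seed and profile give byte-identical output.

Profiles: `minimal` (7 complexes, one cluster everywhere — smoke tests),
`standard` (54 complexes; every rule exercised; the default for tests
and the acceptance script), `stress` (standard plus rigid-transformed
duplicates that must join existing clusters without creating new ones).

What the fixtures do *not* emulate: real antibody/TCR/MHC folds, side
chains beyond CB, crystallographic noise, engineered-construct contacts
(which upstream curation removes by hand), or real sequence families.
Passing tests therefore demonstrate the correctness of the filtering,
interface and clustering logic under controlled geometry — not
biophysical realism on deposited structures.

## Problem sizes and determinism

The standard corpus (54 complexes, largest chains ~210 residues) runs
end-to-end in about two seconds; the acceptance script's oracle rates
use 100 random sites and 50 random contact fixtures. These sizes were
chosen so every planted rule is exercised at least twice while the whole
suite stays interactive. There is no randomness anywhere in the pipeline
itself; reruns on identical inputs are bit-identical, and all sampling
(fixtures, acceptance checks) flows from explicit seeds.

## Known limitations

* The PMax/PMin tolerance (0.5 Å) and the single-sorted-list site
  descriptor are an interpretation of a scheme whose reference
  implementation details are unpublished; absolute score values may
  differ from PocketMatch's, though the fixed points (identity, rigid
  invariance, the decision rule's thresholds) do not.
* "First G-domain hit" is resolved as best raw score.
* The antigen-length filter counts resolved residues, not construct
  length.
* Engineered-construct contact curation and VDJ gene annotation are out
  of scope; so is fetching structures or assemblies.
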