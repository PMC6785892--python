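"""Cluster assignment and nomenclature.

All threshold-based clusterings are single-linkage: items are nodes, a
pairwise "similar" relation gives edges, clusters are connected
components.  Components make the partition order-independent and give the
monotonicity property (raising an identity threshold never decreases the
cluster count).  Items are always processed in sorted structure-id order
so cluster numbering is deterministic.

Labels follow the receptor/antigen/MHC nomenclature: heavy/light chain
groups H<i>/L<j> (combined "H1_L1"), TCR alpha/beta A<i>/B<j>, antigen
sequence clusters Ag<i>, epitope conformations E<i> (scoped within their
receptor cluster), MHC class I groove domains a<i>, class II a<i>_b<j>,
non-classical n<i>.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import networkx as nx

from .annotation import cdr_key, extract_cdrs
from .interface import EpitopeSite
from .similarity import (GDomainRef, PM_TOL, SIMILARITY_RULE, map_g_domain,
                         pairwise_identity, pocketmatch_score, sites_similar,
                         UnscorableSiteError)
from .structures import ComplexRecord

__all__ = [
    "Partition",
    "single_linkage_clusters",
    "cluster_antigens",
    "cluster_receptors",
    "cluster_epitope_conformations",
    "cluster_core_epitopes",
    "cluster_mhc",
    "distinct_pairs",
]

ROLE_PREFIX = {"heavy": "H", "light": "L", "alpha": "A", "beta": "B"}
ROLE_ORDER = {"heavy": 0, "light": 1, "alpha": 0, "beta": 1}


@dataclass
class Partition:
    """A true partition of item ids into 0-based contiguous clusters."""

    members: list[str]
    cluster_of: dict[str, int]

    def __post_init__(self):
        if set(self.members) != set(self.cluster_of):
            raise ValueError("cluster_of must cover exactly the members")
        indices = sorted(set(self.cluster_of.values()))
        if indices != list(range(len(indices))):
            raise ValueError("cluster indices must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values())) if self.members else 0

    def clusters(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_clusters)]
        for item in self.members:
            out[self.cluster_of[item]].append(item)
        return out

    def labels(self, prefix: str) -> dict[str, str]:
        return {item: f"{prefix}{idx + 1}" for item, idx in self.cluster_of.items()}


def single_linkage_clusters(items: Sequence[str],
                            similar: Callable[[str, str], bool]) -> Partition:
    """Connected components of the similarity graph, numbered by first
    appearance in item order."""
    items = list(items)
    graph = nx.Graph()
    graph.add_nodes_from(items)
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            if similar(a, b):
                graph.add_edge(a, b)
    cluster_of: dict[str, int] = {}
    next_idx = 0
    for item in items:
        if item in cluster_of:
            continue
        for member in nx.node_connected_component(graph, item):
            cluster_of[member] = next_idx
        next_idx += 1
    return Partition(members=items, cluster_of=cluster_of)


def _group_exact(items: Sequence[str], key_of: dict[str, object]) -> Partition:
    """Exact-key grouping, indexed by first appearance in item order."""
    cluster_of: dict[str, int] = {}
    index_of_key: dict[object, int] = {}
    for item in items:
        key = key_of[item]
        if key not in index_of_key:
            index_of_key[key] = len(index_of_key)
        cluster_of[item] = index_of_key[key]
    return Partition(members=list(items), cluster_of=cluster_of)


def _sorted_records(records: Sequence[ComplexRecord]) -> list[ComplexRecord]:
    return sorted(records, key=lambda r: r.structure_id)


def antigen_sequence(record: ComplexRecord) -> str:
    """Concatenated one-letter sequence of the peptidic antigen chains."""
    return "".join(record.structure.chain(cid).sequence
                   for cid in record.antigen_chain_ids)


def cluster_antigens(records: Sequence[ComplexRecord],
                     threshold: float = 70.0) -> tuple[Partition, dict[str, str]]:
    """Single-linkage clustering of antigen sequences at an identity
    threshold (default 70%); labels ``Ag<i>``."""
    records = _sorted_records(records)
    seqs = {r.structure_id: antigen_sequence(r) for r in records}

    def similar(a: str, b: str) -> bool:
        return pairwise_identity(seqs[a], seqs[b]) >= threshold

    part = single_linkage_clusters([r.structure_id for r in records], similar)
    return part, part.labels("Ag")


def receptor_cdr_keys(record: ComplexRecord) -> dict[str, str]:
    """role -> CDR key for the receptor chains of one complex."""
    keys = {}
    for cid, role in record.receptor_chain_roles.items():
        if role not in ROLE_PREFIX:
            continue
        keys[role] = cdr_key(extract_cdrs(record.numbered_chains[cid]))
    return keys


def cluster_receptors(records: Sequence[ComplexRecord]
                      ) -> tuple[Partition, dict[str, str]]:
    """Group receptors by exact per-chain CDR identity.

    Heavy and light chains (or TCR alpha/beta) are grouped independently;
    a complex's label concatenates its per-chain cluster indices, e.g.
    ``H1_L2`` or ``A3_B1``; single-chain receptors keep only the present
    chain's component.
    """
    records = _sorted_records(records)
    per_role_keys: dict[str, dict[str, str]] = {}
    for rec in records:
        keys = receptor_cdr_keys(rec)
        if not keys:
            raise ValueError(f"{rec.structure_id}: no annotated receptor chains")
        per_role_keys[rec.structure_id] = keys

    role_index: dict[str, dict[str, int]] = {}
    labels: dict[str, str] = {}
    for rec in records:
        parts = []
        for role in sorted(per_role_keys[rec.structure_id],
                           key=lambda r: ROLE_ORDER[r]):
            key = per_role_keys[rec.structure_id][role]
            table = role_index.setdefault(role, {})
            if key not in table:
                table[key] = len(table) + 1
            parts.append(f"{ROLE_PREFIX[role]}{table[key]}")
        labels[rec.structure_id] = "_".join(parts)
    part = _group_exact([r.structure_id for r in records],
                        {sid: lab for sid, lab in labels.items()})
    return part, labels


def cluster_epitope_conformations(records: Sequence[ComplexRecord],
                                  sites: dict[str, EpitopeSite],
                                  tol: float = PM_TOL,
                                  rule=SIMILARITY_RULE
                                  ) -> tuple[Partition, dict[str, str]]:
    """Single-linkage clustering of epitope 3D conformations for records
    sharing one receptor cluster; labels ``E<i>`` scoped to that cluster.
    Empty or single-atom sites are unscorable and become singletons.
    """
    records = _sorted_records(records)
    ids = [r.structure_id for r in records]

    def similar(a: str, b: str) -> bool:
        sa, sb = sites[a], sites[b]
        if sa.n_atoms < 2 or sb.n_atoms < 2:
            return False
        try:
            return sites_similar(pocketmatch_score(sa, sb, tol=tol), rule=rule)
        except UnscorableSiteError:
            return False

    part = single_linkage_clusters(ids, similar)
    return part, part.labels("E")


def cluster_core_epitopes(records: Sequence[ComplexRecord],
                          cores: dict[str, str],
                          threshold: float = 85.0
                          ) -> tuple[Partition, dict[str, str]]:
    """Single-linkage clustering of core-epitope / core-peptide sequences
    at an identity threshold (default 85%)."""
    records = _sorted_records(records)

    def similar(a: str, b: str) -> bool:
        return pairwise_identity(cores[a], cores[b]) >= threshold

    part = single_linkage_clusters([r.structure_id for r in records], similar)
    return part, part.labels("C")


def _mhc_key(record: ComplexRecord, refs: Sequence[GDomainRef],
             min_qcov: float, min_scov: float):
    """(kind, key) for MHC clustering of one complex.

    Class I: the mapped a1-a2 sequence.  Class II: the (a1, b1) mapped
    pair — both chains must map.  Anything else is non-classical and keyed
    by the full chain sequence(s).
    """
    chain_ids = record.chains_with_roles({"mhc_a", "mhc_b"})
    chain_ids.sort(key=lambda cid: (record.receptor_chain_roles[cid], cid))
    hits = {}
    seqs = {}
    for cid in chain_ids:
        seq = record.structure.chain(cid).sequence
        seqs[cid] = seq
        hits[cid] = map_g_domain(seq, refs, min_qcov=min_qcov,
                                 min_scov=min_scov) if seq else None

    class1 = [h for h in hits.values() if h and h.mhc_class == "I"]
    if class1:
        return "I", class1[0].mapped_sequence
    a_hits = [h for h in hits.values()
              if h and h.mhc_class == "II" and h.domain_tag == "a"]
    b_hits = [h for h in hits.values()
              if h and h.mhc_class == "II" and h.domain_tag == "b"]
    if a_hits and b_hits:
        return "II", (a_hits[0].mapped_sequence, b_hits[0].mapped_sequence)
    return "non_classical", tuple(seqs[cid] for cid in chain_ids)


def cluster_mhc(records: Sequence[ComplexRecord], refs: Sequence[GDomainRef],
                min_qcov: float = 90.0, min_scov: float = 85.0
                ) -> tuple[Partition, dict[str, str]]:
    """Group MHC molecules by G-domain sequence.

    Class I molecules with identical a1-a2 domains share a label ``a<i>``;
    class II molecules with identical a1 and b1 domains share
    ``a<i>_b<j>``; unmappable (non-classical) molecules are grouped on
    their complete chain sequences as ``n<i>``.  Class I, class II and
    non-classical labels use independent counters.
    """
    records = _sorted_records(records)
    keys = {r.structure_id: _mhc_key(r, refs, min_qcov, min_scov)
            for r in records}

    counters = {"I": {}, "II_a": {}, "II_b": {}, "n": {}}
    labels: dict[str, str] = {}
    for rec in records:
        kind, key = keys[rec.structure_id]
        if kind == "I":
            table = counters["I"]
            if key not in table:
                table[key] = len(table) + 1
            labels[rec.structure_id] = f"a{table[key]}"
        elif kind == "II":
            a_key, b_key = key
            ta, tb = counters["II_a"], counters["II_b"]
            if a_key not in ta:
                ta[a_key] = len(ta) + 1
            if b_key not in tb:
                tb[b_key] = len(tb) + 1
            labels[rec.structure_id] = f"a{ta[a_key]}_b{tb[b_key]}"
        else:
            table = counters["n"]
            if key not in table:
                table[key] = len(table) + 1
            labels[rec.structure_id] = f"n{table[key]}"
    part = _group_exact([r.structure_id for r in records],
                        {sid: (keys[sid][0], labels[sid]) for sid in labels})
    return part, labels


def distinct_pairs(rows: Sequence[dict], key_fields: Sequence[str],
                   resolution_of: dict[str, Optional[float]]
                   ) -> tuple[dict[str, str], dict[str, str], int]:
    """Assign pair-cluster ids from component cluster labels.

    The pair id is the '+'-joined tuple of the given label fields.  One
    representative per pair cluster: lowest resolution, ties broken by
    lexicographically smallest structure id.  Returns (pair_id per
    structure, representative per pair id, distinct count).
    """
    pair_of: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for row in rows:
        sid = row["structure_id"]
        pair_id = "+".join(str(row[f]) for f in key_fields)
        pair_of[sid] = pair_id
        groups.setdefault(pair_id, []).append(sid)
    reps = {}
    for pair_id, sids in groups.items():
        reps[pair_id] = min(
            sids, key=lambda s: (resolution_of.get(s) is None,
                                 resolution_of.get(s, float("inf")), s))
    return pair_of, reps, len(groups)
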