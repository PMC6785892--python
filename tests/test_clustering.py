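"""Partition semantics, the per-feature clusterings and the cluster
nomenclature."""

import itertools

import numpy as np
import pytest

from immunobench import (ComplexType, cluster_antigens, cluster_core_epitopes,
                         cluster_epitope_conformations, cluster_mhc,
                         cluster_receptors, distinct_pairs,
                         single_linkage_clusters)
from immunobench.annotation import NumberedChain
from immunobench.clustering import Partition

from conftest import backbone_chain, ca_chain, make_record


def brute_force_components(items, adjacency):
    """Transitive closure by repeated sweeps."""
    comp = {x: {x} for x in items}
    changed = True
    while changed:
        changed = False
        for a, b in adjacency:
            if comp[a] is not comp[b]:
                merged = comp[a] | comp[b]
                for x in merged:
                    comp[x] = merged
                changed = True
    seen, groups = set(), []
    for x in items:
        if x not in seen:
            groups.append(frozenset(comp[x]))
            seen |= comp[x]
    return set(groups)


class TestSingleLinkage:
    def test_no_edges_gives_singletons(self):
        part = single_linkage_clusters(list("abcd"), lambda x, y: False)
        assert part.n_clusters == 4

    def test_transitive_closure(self):
        edges = {("a", "b"), ("b", "c")}
        part = single_linkage_clusters(
            list("abcd"), lambda x, y: (x, y) in edges or (y, x) in edges)
        assert part.cluster_of["a"] == part.cluster_of["c"]
        assert part.cluster_of["d"] != part.cluster_of["a"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"i{k}" for k in range(12)]
        edges = {tuple(sorted(p)) for p in itertools.combinations(items, 2)
                 if rng.random() < 0.15}
        part = single_linkage_clusters(
            items, lambda a, b: tuple(sorted((a, b))) in edges)
        got = {frozenset(members) for members in part.clusters()}
        assert got == brute_force_components(items, edges)

    def test_partition_is_disjoint_and_exhaustive(self):
        part = single_linkage_clusters(list("abcdef"),
                                       lambda x, y: x in "abc" and y in "abc")
        members = [m for cluster in part.clusters() for m in cluster]
        assert sorted(members) == list("abcdef")

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            Partition(members=["a", "b"], cluster_of={"a": 0, "b": 2})


def _fake_antigen_record(sid, seq, resolution=2.0):
    chain = ca_chain("G", [(i * 10.0, 0, 0) for i in range(len(seq))],
                     letters=seq)
    heavy = backbone_chain("H", "ACD", origin=(0, 50.0, 0))
    rec = make_record([chain, heavy], "AB_AG", {"H": "heavy"}, ["G"],
                      structure_id=sid, resolution=resolution)
    return rec


class TestClusterAntigens:
    def test_family_structure_at_70_percent(self, standard_corpus):
        rng = np.random.default_rng(11)
        base = "".join(rng.choice(list("ACDEFHIKLMNPQRSTVWY"), 60))
        mutant = list(base)
        for p in rng.choice(60, size=9, replace=False):  # 85% identical
            mutant[p] = "W" if mutant[p] != "W" else "Y"
        far = list(base)
        for p in rng.choice(60, size=36, replace=False):  # 40% identical
            far[p] = "W" if far[p] != "W" else "Y"
        records = [_fake_antigen_record("s1", base),
                   _fake_antigen_record("s2", "".join(mutant)),
                   _fake_antigen_record("s3", "".join(far))]
        part, labels = cluster_antigens(records, threshold=70.0)
        assert part.cluster_of["s1"] == part.cluster_of["s2"]
        assert part.cluster_of["s3"] != part.cluster_of["s1"]
        assert labels["s1"].startswith("Ag")

    def test_identical_sequences_cluster(self):
        records = [_fake_antigen_record("a", "ACDEF" * 4),
                   _fake_antigen_record("b", "ACDEF" * 4)]
        part, _ = cluster_antigens(records)
        assert part.n_clusters == 1

    def test_threshold_100_separates_any_mismatch(self):
        records = [_fake_antigen_record("a", "ACDEF"),
                   _fake_antigen_record("b", "ACDEW")]
        part, _ = cluster_antigens(records, threshold=100.0)
        assert part.n_clusters == 2

    def test_cluster_count_monotone_in_threshold(self, standard_corpus):
        records = [r for r in standard_corpus["records"]
                   if r.complex_type == ComplexType.AB_AG
                   and r.antigen_is_peptidic][:12]
        counts = [cluster_antigens(records, threshold=t)[0].n_clusters
                  for t in (50, 60, 70, 80, 90, 100)]
        assert counts == sorted(counts)


def _receptor_record(sid, cdr3s, roles=("heavy", "light")):
    """A record whose chains carry the given CDR3 sequences."""
    chains, numbering, role_map = [], {}, {}
    antigen = ca_chain("G", [(0, 100.0, 0)])
    chains.append(antigen)
    for role, cdr3 in zip(roles, cdr3s):
        cid = {"heavy": "H", "light": "L", "alpha": "A", "beta": "B"}[role]
        chain = backbone_chain(cid, cdr3, origin=(0, 50.0 + 20 * len(chains), 0))
        chains.append(chain)
        numbering[cid] = NumberedChain(
            chain_id=cid, receptor_role=role,
            positions=[(105 + i, "", aa) for i, aa in enumerate(cdr3)])
        role_map[cid] = role
    ctype = "AB_AG" if "heavy" in roles or "light" in roles else "TCR_PMHC"
    if ctype == "TCR_PMHC":
        mhc = ca_chain("M", [(0, -50.0, 0)])
        chains.append(mhc)
        role_map["M"] = "mhc_a"
    return make_record(chains, ctype, role_map, ["G"], numbering=numbering,
                       structure_id=sid)


class TestClusterReceptors:
    def test_shared_cdrs_share_label(self):
        recs = [_receptor_record("a", ("WGQG", "QQSY")),
                _receptor_record("b", ("WGQG", "QQSY"))]
        _, labels = cluster_receptors(recs)
        assert labels["a"] == labels["b"] == "H1_L1"

    def test_heavy_shared_light_differs(self):
        recs = [_receptor_record("a", ("WGQG", "QQSY")),
                _receptor_record("b", ("WGQG", "QQTF"))]
        _, labels = cluster_receptors(recs)
        assert labels["a"] == "H1_L1"
        assert labels["b"] == "H1_L2"

    def test_nanobody_label_omits_light(self):
        recs = [_receptor_record("a", ("WGQG",), roles=("heavy",))]
        _, labels = cluster_receptors(recs)
        assert labels["a"] == "H1"

    def test_tcr_prefixes(self):
        recs = [_receptor_record("a", ("CAVR", "CASS"), roles=("alpha", "beta")),
                _receptor_record("b", ("CAVR", "CATT"), roles=("alpha", "beta"))]
        _, labels = cluster_receptors(recs)
        assert labels["a"] == "A1_B1"
        assert labels["b"] == "A1_B2"

    def test_labels_stable_under_reordering(self):
        recs = [_receptor_record(s, (c, "QQSY"))
                for s, c in (("a", "WGQG"), ("b", "FFFF"), ("c", "WGQG"))]
        _, fwd = cluster_receptors(recs)
        _, rev = cluster_receptors(list(reversed(recs)))
        assert fwd == rev


class TestEpitopeConformationClustering:
    def _sites(self, standard_corpus):
        from immunobench import epitope_site
        recs = sorted((r for r in standard_corpus["records"]
                       if r.complex_type == ComplexType.AB_AG
                       and r.antigen_is_peptidic),
                      key=lambda r: r.structure_id)
        return recs, {r.structure_id: epitope_site(r) for r in recs}

    def test_duplicate_and_transformed_sites_cluster(self, standard_corpus):
        recs, sites = self._sites(standard_corpus)
        # abag00/abag01 share conformer A (abag01 rigidly transformed)
        pair = [r for r in recs if r.structure_id in ("abag00", "abag01")]
        part, labels = cluster_epitope_conformations(pair, sites)
        assert part.n_clusters == 1
        assert set(labels.values()) == {"E1"}

    def test_distinct_conformers_separate(self, standard_corpus):
        recs, sites = self._sites(standard_corpus)
        # abag00 carries conformer A, abag02 conformer B
        pair = [r for r in recs if r.structure_id in ("abag00", "abag02")]
        part, _ = cluster_epitope_conformations(pair, sites)
        assert part.n_clusters == 2


class TestClusterCoreEpitopes:
    def _records(self, sids):
        return [_fake_antigen_record(s, "A" * 9) for s in sids]

    def test_identity_arithmetic_on_9mers(self):
        recs = self._records(["a", "b", "c"])
        cores = {"a": "ALAKAAAAM", "b": "ALAKAAAAW",   # 1 diff: 88.9%
                 "c": "ALWKAAFAM"}                     # 2 diffs from a: 77.8%
        part, _ = cluster_core_epitopes(recs, cores, threshold=85.0)
        assert part.cluster_of["a"] == part.cluster_of["b"]
        assert part.cluster_of["c"] != part.cluster_of["a"]


class TestClusterMhc:
    def test_gdomain_and_fallback_labels(self, standard_corpus):
        records = [r for r in standard_corpus["records"]
                   if r.structure_id in ("mhl00", "mhl03", "mhl06", "mhl07")]
        part, labels = cluster_mhc(records, standard_corpus["refs"])
        assert labels["mhl00"] == "a1"       # class I G-domain GD1
        assert labels["mhl03"] == "a2"       # class I G-domain GD2
        assert labels["mhl06"] == labels["mhl07"] == "n1"  # non-classical
        assert part.n_clusters == 3

    def test_identical_gdomain_different_flanks_cluster(self, standard_corpus):
        # same planted class I domain, different flanking sequence
        records = [r for r in standard_corpus["records"]
                   if r.structure_id in ("mhl00", "mhl02")]
        seqs = [r.structure.chain("M").sequence for r in records]
        assert seqs[0] != seqs[1]  # full chains differ (flanks vary)
        _, labels = cluster_mhc(records, standard_corpus["refs"])
        assert labels["mhl00"] == labels["mhl02"]

    def test_class_ii_shares_a_index_differs_by_b(self, standard_corpus):
        records = [r for r in standard_corpus["records"]
                   if r.structure_id in ("tcr05", "tcr06")]
        _, labels = cluster_mhc(records, standard_corpus["refs"])
        assert labels["tcr05"] == labels["tcr06"] == "a1_b1"


class TestDistinctPairs:
    def test_counts_and_representative_selection(self):
        rows = [
            {"structure_id": "s1", "rc": "H1_L1", "ec": "E1"},
            {"structure_id": "s2", "rc": "H1_L1", "ec": "E1"},
            {"structure_id": "s3", "rc": "H2_L1", "ec": "E1"},
        ]
        resolution = {"s1": 2.5, "s2": 1.9, "s3": 2.0}
        pair_of, reps, n = distinct_pairs(rows, ("rc", "ec"), resolution)
        assert n == 2
        assert pair_of["s1"] == pair_of["s2"] != pair_of["s3"]
        assert reps[pair_of["s1"]] == "s2"  # best resolution wins

    def test_resolution_tie_breaks_lexicographically(self):
        rows = [{"structure_id": s, "rc": "H1"} for s in ("zz", "aa")]
        _, reps, _ = distinct_pairs(rows, ("rc",), {"zz": 2.0, "aa": 2.0})
        assert reps["H1"] == "aa"

    def test_brute_force_unique_tuple_count(self):
        rng = np.random.default_rng(6)
        rows = [{"structure_id": f"s{i}",
                 "a": str(rng.integers(3)), "b": str(rng.integers(3))}
                for i in range(30)]
        _, _, n = distinct_pairs(rows, ("a", "b"),
                                 {r["structure_id"]: 2.0 for r in rows})
        assert n == len({(r["a"], r["b"]) for r in rows})
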