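"""PMax/PMin site scoring, sorted-list matching, sequence identity and
G-domain mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import linear_sum_assignment

from immunobench import (map_g_domain, match_distances, pairwise_identity,
                         pocketmatch_score, site_distances, sites_similar)
from immunobench.fixtures import make_site_pair
from immunobench.interface import EpitopeSite
from immunobench.similarity import (GDomainRef, SiteScore,
                                    UnscorableSiteError)


def site(coords, ref="s"):
    coords = np.asarray(coords, dtype=float)
    return EpitopeSite(residues=[("G", i) for i in range(len(coords))],
                       coords=coords, complex_ref=ref)


def random_site(rng, n=None):
    n = n or int(rng.integers(4, 25))
    return site(rng.uniform(0, 20, size=(n, 3)))


def max_matching_oracle(list_a, list_b, tol):
    """Exhaustive maximum bipartite matching via assignment."""
    if not len(list_a) or not len(list_b):
        return 0
    weight = (np.abs(np.subtract.outer(np.asarray(list_a),
                                       np.asarray(list_b))) <= tol).astype(int)
    rows, cols = linear_sum_assignment(-weight)
    return int(weight[rows, cols].sum())


class TestSiteDistances:
    def test_collinear_atoms(self):
        d = site_distances(site([(0, 0, 0), (3, 0, 0), (5, 0, 0)]))
        assert d.tolist() == [2.0, 3.0, 5.0]

    def test_two_atoms_single_distance(self):
        assert len(site_distances(site([(0, 0, 0), (1, 1, 1)]))) == 1

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10, size=(10, 3))
        d = site_distances(site(coords))
        oracle = sorted(np.linalg.norm(coords[i] - coords[j])
                        for i in range(10) for j in range(i + 1, 10))
        assert len(d) == 45
        assert np.allclose(d, oracle)

    def test_unscorable_below_two_atoms(self):
        with pytest.raises(UnscorableSiteError):
            site_distances(site([(0, 0, 0)]))


class TestMatchDistances:
    @pytest.mark.parametrize("a,b,tol,expected", [
        ([3.0, 4.0, 5.0], [3.2], 0.5, 1),
        ([1.0], [9.0], 0.5, 0),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0, 3),
        ([], [1.0], 0.5, 0),
    ])
    def test_hand_cases(self, a, b, tol, expected):
        assert match_distances(a, b, tol) == expected
        assert match_distances(b, a, tol) == expected

    def test_identical_lists_fully_match(self):
        rng = np.random.default_rng(1)
        lst = np.sort(rng.uniform(0, 30, 50))
        assert match_distances(lst, lst, 0.0) == 50

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_greedy_equals_exhaustive_maximum_matching(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(0, 9)), int(rng.integers(0, 9))
        a = np.sort(rng.uniform(0, 6, na))
        b = np.sort(rng.uniform(0, 6, nb))
        tol = float(rng.uniform(0, 1.5))
        assert match_distances(a, b, tol) == max_matching_oracle(a, b, tol)


class TestPocketmatchScore:
    def test_self_identity(self):
        s = random_site(np.random.default_rng(2))
        score = pocketmatch_score(s, s)
        assert score.pmax == 1.0 and score.pmin == 1.0

    def test_hand_computed_ratios(self):
        # 3-atom site: pairs {5, 10, 15}; 2-atom site: single pair {5}
        big = site([(0, 0, 0), (5, 0, 0), (15, 0, 0)])
        small = site([(0, 0, 0), (5, 0, 0)])
        score = pocketmatch_score(big, small, tol=0.5)
        assert score.matched == 1
        assert score.pmax == pytest.approx(1 / 3)
        assert score.pmin == pytest.approx(1.0)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = random_site(rng)
        original, moved = make_site_pair(s.coords, jitter=0.0)
        score = pocketmatch_score(site(original), site(moved))
        assert score.pmax == 1.0 and score.pmin == 1.0

    def test_symmetry_and_pmin_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = random_site(rng), random_site(rng)
            s_ab = pocketmatch_score(a, b)
            s_ba = pocketmatch_score(b, a)
            assert (s_ab.pmax, s_ab.pmin) == (s_ba.pmax, s_ba.pmin)
            assert 0.0 <= s_ab.pmax <= s_ab.pmin <= 1.0

    def test_heavy_jitter_destroys_similarity(self):
        rng = np.random.default_rng(5)
        s = random_site(rng, n=12)
        _, noisy = make_site_pair(s.coords, jitter=5.0, rng=rng)
        score = pocketmatch_score(s, site(noisy))
        assert not sites_similar(score)


class TestSitesSimilar:
    @pytest.mark.parametrize("pmax,pmin,expected", [
        (1.0, 1.0, True),
        (0.2, 1.0, True),      # PMin alone at 1.0 suffices
        (0.6, 0.9, True),      # joint-threshold boundary
        (0.59, 0.95, False),
        (0.7, 0.89, False),
    ])
    def test_decision_rule(self, pmax, pmin, expected):
        score = SiteScore(pmax=pmax, pmin=pmin, matched=0, pairs_a=0, pairs_b=0)
        assert sites_similar(score) is expected


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("PEPTIDE", "PEPTIDE") == 100.0

    def test_single_substitution(self):
        assert pairwise_identity("AAAA", "AAAT") == pytest.approx(75.0)

    def test_fragment_scores_full_against_shorter_denominator(self):
        assert pairwise_identity("PEPTIDE", "PEPTI") == pytest.approx(100.0)

    def test_symmetric(self):
        a, b = "ACDEFHIKLMNPQRSTVWY", "ACDEFHIKLMNPQRSTVWA"
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "AAA")


@pytest.fixture(scope="module")
def gdomain_refs():
    rng = np.random.default_rng(10)
    alphabet = list("ACDEFHIKLMNPQRSTVWY")
    def seq(n):
        return "".join(rng.choice(alphabet, n))
    return {
        "refs": [GDomainRef("R1", "I", "a", seq(120)),
                 GDomainRef("R2", "I", "a", seq(120)),
                 GDomainRef("RB", "II", "b", seq(80))],
        "seq": seq,
    }


class TestMapGDomain:
    def test_recovers_planted_reference_and_boundaries(self, gdomain_refs):
        refs = gdomain_refs["refs"]
        query = gdomain_refs["seq"](50) + refs[0].sequence + gdomain_refs["seq"](50)
        hit = map_g_domain(query, refs)
        assert hit is not None
        assert hit.ref_id == "R1"
        assert hit.domain_tag == "a"
        assert hit.mapped_sequence == refs[0].sequence
        assert hit.qcov >= 90 and hit.scov >= 85

    def test_random_query_maps_nowhere(self, gdomain_refs):
        assert map_g_domain(gdomain_refs["seq"](200),
                            gdomain_refs["refs"]) is None

    def test_best_scoring_reference_wins(self, gdomain_refs):
        refs = gdomain_refs["refs"]
        # embed R2 verbatim; R1 can only match by chance
        query = gdomain_refs["seq"](30) + refs[1].sequence
        hit = map_g_domain(query, refs)
        assert hit.ref_id == "R2"

    def test_empty_reference_set_raises(self):
        with pytest.raises(ValueError):
            map_g_domain("ACDEF", [])
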