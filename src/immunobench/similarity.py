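"""Scoring kernels: binding-site conformational similarity, pairwise
sequence identity, and MHC G-domain mapping.

Site comparison follows the sorted-distance-list scheme: all unordered
heavy-atom pair distances within each site are sorted ascending and the
two lists are greedily matched within a tolerance.  PMax divides the
matched count by the pair count of the larger site, PMin by that of the
smaller.  Greedy matching of two sorted lists is optimal for this
interval-overlap matching problem (exchange argument; verified against an
exhaustive maximum-matching oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.spatial.distance import pdist

from .interface import EpitopeSite

__all__ = [
    "SiteScore",
    "GDomainRef",
    "GDomainHit",
    "UnscorableSiteError",
    "PM_TOL",
    "SIMILARITY_RULE",
    "site_distances",
    "match_distances",
    "pocketmatch_score",
    "sites_similar",
    "pairwise_identity",
    "load_gdomain_refs",
    "map_g_domain",
]

PM_TOL = 0.5  # Angstrom; distance-match tolerance (configurable everywhere)
SIMILARITY_RULE = (1.0, 0.9, 0.6)  # exact, pmin floor, pmax floor


class UnscorableSiteError(ValueError):
    """Raised for sites with fewer than two atoms (no distance pairs)."""


@dataclass(frozen=True)
class SiteScore:
    pmax: float
    pmin: float
    matched: int
    pairs_a: int
    pairs_b: int


def site_distances(site: EpitopeSite) -> np.ndarray:
    """Sorted ascending list of all unordered heavy-atom pair distances."""
    if site.n_atoms < 2:
        raise UnscorableSiteError(
            f"site {site.complex_ref}: {site.n_atoms} atom(s), not scorable")
    return np.sort(pdist(site.coords))


def match_distances(list_a: Sequence[float], list_b: Sequence[float],
                    tol: float) -> int:
    """Greedy two-pointer matching of two sorted distance lists.

    Advance both on a match (|da - db| <= tol), otherwise advance the
    smaller; each element is matched at most once.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    i = j = matched = 0
    na, nb = len(list_a), len(list_b)
    while i < na and j < nb:
        da, db = list_a[i], list_b[j]
        if abs(da - db) <= tol:
            matched += 1
            i += 1
            j += 1
        elif da < db:
            i += 1
        else:
            j += 1
    return matched


def pocketmatch_score(site_a: EpitopeSite, site_b: EpitopeSite,
                      tol: float = PM_TOL) -> SiteScore:
    """PMax/PMin conformational similarity of two binding sites.

    Scores depend only on intra-site distances, so they are invariant
    under rigid-body transforms, and symmetric in the two sites.
    """
    da = site_distances(site_a)
    db = site_distances(site_b)
    matched = match_distances(da, db, tol)
    pairs_a, pairs_b = len(da), len(db)
    hi, lo = max(pairs_a, pairs_b), min(pairs_a, pairs_b)
    return SiteScore(
        pmax=matched / hi if hi else 0.0,
        pmin=matched / lo if lo else 0.0,
        matched=matched,
        pairs_a=pairs_a,
        pairs_b=pairs_b,
    )


def sites_similar(score: SiteScore,
                  rule: tuple[float, float, float] = SIMILARITY_RULE) -> bool:
    """Epitope-conformation clustering rule.

    Similar iff PMax or PMin equals 1.0, or PMin >= 0.9 and PMax >= 0.6
    (default thresholds).
    """
    exact, pmin_floor, pmax_floor = rule
    return (score.pmax >= exact or score.pmin >= exact
            or (score.pmin >= pmin_floor and score.pmax >= pmax_floor))


# ---------------------------------------------------------------------------
# Sequence identity

@lru_cache(maxsize=1)
def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@lru_cache(maxsize=1)
def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identical_positions(alignment) -> int:
    count = 0
    qa, qb = alignment.sequences
    for (a1, a2), (b1, b2) in zip(*alignment.aligned):
        seg_a, seg_b = qa[a1:a2], qb[b1:b2]
        count += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    return count


@lru_cache(maxsize=200_000)
def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent sequence identity under global alignment.

    BLOSUM62, gap open 10, gap extend 0.5; identity is the count of
    identical aligned positions over the length of the shorter sequence,
    so a fragment of a protein scores 100% against the full protein.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_a == seq_b:
        return 100.0
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    return 100.0 * _identical_positions(alignment) / min(len(seq_a), len(seq_b))


# ---------------------------------------------------------------------------
# MHC G-domain mapping

@dataclass(frozen=True)
class GDomainRef:
    """One reference groove-domain sequence (class I a1-a2, class II a1 or b1)."""

    ref_id: str
    mhc_class: str  # "I" or "II"
    domain_tag: str  # "a" or "b"
    sequence: str


@dataclass(frozen=True)
class GDomainHit:
    mhc_class: str
    domain_tag: str
    mapped_sequence: str
    ref_id: str
    qcov: float
    scov: float
    score: float
    evalue: float


# Karlin-Altschul parameters for gapped BLOSUM62 with open 10 / extend 0.5
# (standard BLAST values); used to turn raw local-alignment scores into
# e-values so the printed e-value cutoff can be applied.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * np.exp(-_KA_LAMBDA * score)


def load_gdomain_refs(fasta_path) -> list[GDomainRef]:
    """Read a G-domain reference FASTA.

    Headers encode class and domain, e.g. ``>HLA1 class=I domain=a``.
    """
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        fields = dict(part.split("=", 1) for part in rec.description.split()
                      if "=" in part)
        refs.append(GDomainRef(
            ref_id=rec.id,
            mhc_class=fields.get("class", "I"),
            domain_tag=fields.get("domain", "a"),
            sequence=str(rec.seq).upper(),
        ))
    if not refs:
        raise ValueError(f"no G-domain references in {fasta_path}")
    return refs


def map_g_domain(mhc_seq: str, refs: Sequence[GDomainRef],
                 min_qcov: float = 90.0, min_scov: float = 85.0,
                 max_evalue: float = 1e-10) -> Optional[GDomainHit]:
    """Map an MHC chain sequence onto its groove (G-) domain.

    Each reference is locally aligned against the query; a candidate hit
    must have an e-value <= ``max_evalue`` (Karlin-Altschul statistics on
    the raw score, with the reference set as the database), cover
    >= ``min_scov``% of the reference and span a query region of
    >= ``min_qcov``% of the reference length.  The best-scoring hit
    wins; ``None`` means the chain is treated as non-classical and its
    full sequence is used for clustering.
    """
    if not refs:
        raise ValueError("empty G-domain reference set")
    if not mhc_seq:
        raise ValueError("empty MHC sequence")
    mhc_seq = mhc_seq.upper()
    db_size = sum(len(r.sequence) for r in refs)
    aligner = _local_aligner()
    best: Optional[GDomainHit] = None
    for ref in refs:
        alignments = aligner.align(mhc_seq, ref.sequence)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        blocks_q, blocks_r = aln.aligned
        if len(blocks_q) == 0:
            continue
        q_start, q_end = blocks_q[0][0], blocks_q[-1][1]
        r_start, r_end = blocks_r[0][0], blocks_r[-1][1]
        scov = 100.0 * (r_end - r_start) / len(ref.sequence)
        qcov = 100.0 * (q_end - q_start) / len(ref.sequence)
        evalue = _karlin_altschul_evalue(float(aln.score), len(mhc_seq),
                                         db_size)
        if scov < min_scov or qcov < min_qcov or evalue > max_evalue:
            continue
        hit = GDomainHit(
            mhc_class=ref.mhc_class,
            domain_tag=ref.domain_tag,
            mapped_sequence=mhc_seq[q_start:q_end],
            ref_id=ref.ref_id,
            qcov=qcov,
            scov=scov,
            score=float(aln.score),
            evalue=evalue,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best
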