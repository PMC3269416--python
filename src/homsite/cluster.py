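"""Binding-site similarity scoring and clustering.

Two binding sites mapped onto the same query are compared over the union of
their query positions.  Each aligned column contributes the BLOSUM62
substitution value plus a positional bonus; columns where either site is
absent contribute a flat gap penalty.  The raw score becomes a bit score via
the BLOSUM statistical parameters (lambda, K) and is normalized by the
larger of the two self-scores, so similarities from different interface
alignments are comparable and bounded by 1.

Sites are grouped by complete-linkage hierarchical clustering on
d = 1 - S_norm.  The cut through the dendrogram is chosen by a
pseudo-free-energy functional that rewards high mean within-cluster
similarity (energy-like term) and penalizes fragmented descriptions
(entropy-like term, weighted by a temperature T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from homsite.errors import (
    DegenerateSiteError,
    PairingError,
    ValidationError,
)
from homsite.homology import MappedSite

GAP = "-"


def _default_matrix():
    return substitution_matrices.load("BLOSUM62")


def load_matrix(path: str):
    """Read an NCBI-style substitution matrix text file."""
    with open(path) as fh:
        return substitution_matrices.read(fh)


@dataclass
class ScoringParams:
    """Parameters of the bit-score similarity.

    ``lam`` and ``K`` default to the ungapped BLOSUM62 statistical
    parameters (0.3176 nats, 0.134).
    """

    matrix: object = field(default_factory=_default_matrix)
    position_bonus: int = 1     # reward for any aligned (non-gap) column
    gap_penalty: int = -4       # flat per-column penalty when one side is a gap
    lam: float = 0.3176         # nats
    K: float = 0.134

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError("lambda must be positive")
        if not (0 < self.K < 1):
            raise ValidationError("K must be in (0, 1)")

    def sub(self, a: str, b: str) -> int:
        """Substitution value; unknown residues use the wildcard row, else 0."""
        alphabet = str(getattr(self.matrix, "alphabet", ""))
        aa = a if a in alphabet else "X"
        bb = b if b in alphabet else "X"
        try:
            return int(self.matrix[aa, bb])
        except (KeyError, IndexError):
            return 0


@dataclass
class AlignedSitePair:
    """Gapped two-row alignment of a site pair over the union footprint."""

    columns: list[tuple[str, str]]   # (a_i, b_i); GAP for uncovered positions
    delta: list[int]                 # 1 iff neither side is a gap

    def __post_init__(self) -> None:
        for (a, b) in self.columns:
            if a == GAP and b == GAP:
                raise PairingError("column with gaps on both sides")


@dataclass
class SimilarityMatrix:
    site_ids: list[str]
    S: np.ndarray  # N x N, symmetric, unit diagonal

    @property
    def N(self) -> int:
        return len(self.site_ids)


@dataclass
class ClusterPartition:
    clusters: list[list[int]]   # member indices into site_ids
    N: int
    cutoff: float
    T: float
    F: float


def build_site_pair(site_a: MappedSite, site_b: MappedSite) -> AlignedSitePair:
    """Lay two mapped sites over the union of their query positions."""
    if site_a.alignment.query_id != site_b.alignment.query_id:
        raise PairingError(
            f"sites mapped to different queries: {site_a.alignment.query_id} "
            f"vs {site_b.alignment.query_id}")
    union = sorted(set(site_a.query_positions) | set(site_b.query_positions))
    columns = [(site_a.aa_by_pos.get(q, GAP), site_b.aa_by_pos.get(q, GAP))
               for q in union]
    delta = [1 if a != GAP and b != GAP else 0 for a, b in columns]
    return AlignedSitePair(columns=columns, delta=delta)


def raw_similarity(pair: AlignedSitePair, params: ScoringParams) -> int:
    """Sum over columns: aligned -> H(a,b) + bonus; gapped -> gap penalty."""
    total = 0
    for (a, b), d in zip(pair.columns, pair.delta):
        if d:
            total += params.sub(a, b) + params.position_bonus
        else:
            total += params.gap_penalty
    return total


def to_bits(raw: float, params: ScoringParams) -> float:
    """Bit score: (lambda * raw - ln K) / ln 2."""
    return (params.lam * raw - math.log(params.K)) / math.log(2.0)


def _self_pair(site: MappedSite) -> AlignedSitePair:
    cols = [(site.aa_by_pos[q], site.aa_by_pos[q]) for q in site.query_positions]
    return AlignedSitePair(columns=cols, delta=[1] * len(cols))


def self_bits(site: MappedSite, params: ScoringParams) -> float:
    return to_bits(raw_similarity(_self_pair(site), params), params)


def normalized_similarity(site_a: MappedSite, site_b: MappedSite,
                          params: ScoringParams) -> float:
    """Bit score of the pair divided by the larger self bit score."""
    bits_aa = self_bits(site_a, params)
    bits_bb = self_bits(site_b, params)
    denom = max(bits_aa, bits_bb)
    if denom <= 0:
        raise DegenerateSiteError(
            "self bit score non-positive; site cannot be normalized")
    bits_ab = to_bits(raw_similarity(build_site_pair(site_a, site_b), params),
                      params)
    return bits_ab / denom


def similarity_matrix(sites: Sequence[MappedSite],
                      params: ScoringParams | None = None) -> SimilarityMatrix:
    """Pairwise normalized similarities with unit diagonal."""
    if params is None:
        params = ScoringParams()
    n = len(sites)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = normalized_similarity(sites[i], sites[j], params)
    return SimilarityMatrix(site_ids=[s.site_id for s in sites], S=S)


def complete_linkage(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Complete-linkage merge list over a symmetric distance matrix.

    Clusters are numbered 0..N-1 for the leaves, then N, N+1, ... in merge
    order.  Each merge records (cluster_i, cluster_j, height) with i < j;
    ties are broken by the smallest pair of cluster indices.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    n = dist.shape[0]
    # active cluster id -> member leaf indices
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(members) > 1:
        ids = sorted(members)
        best = None
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                ci, cj = ids[x], ids[y]
                h = max(dist[a, b] for a in members[ci] for b in members[cj])
                if best is None or h < best[0]:
                    best = (h, ci, cj)
        h, ci, cj = best
        merges.append((ci, cj, h))
        members[next_id] = members.pop(ci) + members.pop(cj)
        next_id += 1
    return merges


def _partition_after(merges: list[tuple[int, int, float]], n: int,
                     k: int) -> list[list[int]]:
    """Leaf partition after applying the first k merges."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    for ci, cj, _h in merges[:k]:
        members[next_id] = members.pop(ci) + members.pop(cj)
        next_id += 1
    return [sorted(v) for v in sorted(members.values())]


def partition_free_energy(clusters: list[list[int]], S: np.ndarray,
                          T: float) -> float:
    """Mean within-cluster similarity plus T times the partition entropy term.

    F = sum_C (|C|/N) * mean_pairwise_S(C) + T * sum_C (|C|/N) ln(|C|/N);
    singleton clusters take mean similarity 1.
    """
    n = sum(len(c) for c in clusters)
    F = 0.0
    for c in clusters:
        k = len(c)
        p = k / n
        if k == 1:
            s_bar = 1.0
        else:
            vals = [S[a, b] for i, a in enumerate(c) for b in c[i + 1:]]
            s_bar = float(np.mean(vals))
        F += p * s_bar + T * p * math.log(p)
    return F


def select_partition(merges: list[tuple[int, int, float]],
                     sim: SimilarityMatrix, T: float = 0.05) -> ClusterPartition:
    """Choose the dendrogram cut maximizing the pseudo-free-energy functional.

    Every distinct cut (one per merge step, plus the all-singleton state) is
    evaluated; ties prefer the cut with fewer clusters.
    """
    n = sim.N
    best = None
    for k in range(len(merges) + 1):
        clusters = _partition_after(merges, n, k)
        F = partition_free_energy(clusters, sim.S, T)
        cutoff = merges[k - 1][2] if k else 0.0
        # larger k = fewer clusters; >= keeps the later (coarser) cut on ties
        if best is None or F >= best.F - 1e-12:
            if best is None or F > best.F + 1e-12 or len(clusters) < len(best.clusters):
                best = ClusterPartition(clusters=clusters, N=n, cutoff=cutoff,
                                        T=T, F=F)
    return best
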