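"""Cluster classification and ranking.

A cluster of query-mapped binding sites is *conserved* when, after greedy
removal of members that are at least 90% identical in sequence to a retained
representative, more than one representative remains; otherwise it is a
*singleton*.  Conserved clusters are scored on four components — positional
conservation (Henikoff-weighted Shannon negentropy), mean interfacial
contact count, query-versus-PSSM score, and mean full-alignment identity of
the members to the query — each standardized to a Z-score across the
conserved clusters and combined with configurable weights.  Singletons are
unscored and always rank below every conserved cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from homsite.errors import EmptyProfileError, ScoringError
from homsite.homology import AlignmentMap, MappedSite, compose_alignment
from homsite.cluster import GAP, ScoringParams

AA20 = "ARNDCQEGHILKMFPSTWYV"
LOG2_21 = math.log2(21.0)


@dataclass
class ClusterAlignment:
    """Gapped member rows over the union of member query positions."""

    positions: list[int]            # query sequence indices (columns)
    rows: list[str]                 # one gapped string per member site
    query_row: str                  # query residues over the same columns
    member_weights: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.member_weights is None:
            self.member_weights = henikoff_weights(self.rows)


@dataclass
class Pssm:
    """Profile-average position-specific score matrix.

    M[p, b] = sum_a f_w(p, a) * H(a, b) with f_w the weighted residue
    frequencies of column p (gap mass renormalized out).  Columns that are
    entirely gaps carry no information and are dropped.
    """

    scores: np.ndarray              # kept columns x 20
    kept_columns: list[int]         # indices into the alignment's columns


@dataclass
class ScoreComponents:
    conserv: float
    contact: float
    pssm: float
    pcnt: float
    z_conserv: float = 0.0
    z_contact: float = 0.0
    z_pssm: float = 0.0
    z_pcnt: float = 0.0
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    @property
    def combined(self) -> float:
        w = self.weights
        return (w[0] * self.z_conserv + w[1] * self.z_contact
                + w[2] * self.z_pssm + w[3] * self.z_pcnt)


@dataclass
class ClusterRank:
    cluster_id: str
    label: str                       # "conserved" | "singleton"
    size: int
    n_nonredundant: int
    components: ScoreComponents | None
    combined: float | None
    rank: int = 0


def _invert(aln: AlignmentMap) -> AlignmentMap:
    inv = AlignmentMap(neighbor_id=aln.query_id, query_id=aln.neighbor_id,
                       pairs=[(q, n) for n, q in aln.pairs])
    inv.identity_fraction = aln.identity_fraction
    return inv


def _pairwise_identity(a: MappedSite, b: MappedSite) -> float:
    """Sequence identity of two members over columns aligned through the query."""
    composed = compose_alignment(a.alignment, _invert(b.alignment))
    if not composed.pairs:
        return 0.0
    same = sum(1 for i, k in composed.pairs
               if a.member_sequence[i] == b.member_sequence[k])
    return same / len(composed.pairs)


def classify_cluster(members: Sequence[MappedSite],
                     redundancy_identity: float = 0.90
                     ) -> tuple[str, int]:
    """Label a cluster conserved or singleton.

    Greedy reduction: members ordered by descending sequence length then
    site id; a member is redundant when at least ``redundancy_identity``
    identical (over aligned columns) to an already retained representative.
    Returns (label, number of representatives).
    """
    ordered = sorted(members,
                     key=lambda m: (-len(m.member_sequence), m.site_id))
    reps: list[MappedSite] = []
    for m in ordered:
        if not any(_pairwise_identity(m, r) >= redundancy_identity
                   for r in reps):
            reps.append(m)
    label = "conserved" if len(reps) > 1 else "singleton"
    return label, len(reps)


def build_cluster_alignment(members: Sequence[MappedSite],
                            query_seq: str) -> ClusterAlignment:
    """Stack member sites over the union of their query positions."""
    positions = sorted(set().union(*(m.query_positions for m in members)))
    rows = ["".join(m.aa_by_pos.get(q, GAP) for q in positions)
            for m in members]
    query_row = "".join(query_seq[q] for q in positions)
    return ClusterAlignment(positions=positions, rows=rows,
                            query_row=query_row)


def henikoff_weights(rows: Sequence[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to sum 1.

    Per column, a residue type with multiplicity m among k distinct types
    contributes 1/(k*m) to every sequence carrying it; gaps count as a 21st
    type.
    """
    if not rows:
        raise ValueError("need at least one row")
    n = len(rows)
    weights = np.zeros(n)
    ncols = len(rows[0])
    for p in range(ncols):
        column = [row[p] for row in rows]
        counts: dict[str, int] = {}
        for c in column:
            counts[c] = counts.get(c, 0) + 1
        k = len(counts)
        for i, c in enumerate(column):
            weights[i] += 1.0 / (k * counts[c])
    total = weights.sum()
    if total == 0:  # zero columns: fall back to uniform
        return np.full(n, 1.0 / n)
    return weights / total


def conservation_score(aln: ClusterAlignment) -> float:
    """Mean per-column negentropy, log2(21) - h, with weighted frequencies.

    h is the Shannon entropy (base 2) of the weighted residue distribution
    over the 20 amino acids plus gap; identical columns give h = 0, hence
    the maximal score log2(21).
    """
    w = aln.member_weights
    total = 0.0
    ncols = len(aln.positions)
    for p in range(ncols):
        freq: dict[str, float] = {}
        for row, wi in zip(aln.rows, w):
            c = row[p]
            freq[c] = freq.get(c, 0.0) + wi
        h = -sum(f * math.log2(f) for f in freq.values() if f > 0)
        total += LOG2_21 - h
    return total / ncols if ncols else 0.0


def build_pssm(aln: ClusterAlignment, params: ScoringParams | None = None) -> Pssm:
    """Profile-average PSSM from the cluster alignment.

    The weighted frequency mass at gaps is renormalized over the residues
    actually present; all-gap columns are dropped.
    """
    if params is None:
        params = ScoringParams()
    w = aln.member_weights
    kept: list[int] = []
    cols: list[np.ndarray] = []
    for p in range(len(aln.positions)):
        freq: dict[str, float] = {}
        for row, wi in zip(aln.rows, w):
            c = row[p]
            if c != GAP:
                freq[c] = freq.get(c, 0.0) + wi
        mass = sum(freq.values())
        if mass <= 0:
            continue
        kept.append(p)
        scores = np.zeros(len(AA20))
        for a, f in freq.items():
            fa = f / mass
            for jb, b in enumerate(AA20):
                scores[jb] += fa * params.sub(a, b)
        cols.append(scores)
    if not kept:
        raise EmptyProfileError("all alignment columns are gaps")
    return Pssm(scores=np.vstack(cols), kept_columns=kept)


def score_query(pssm: Pssm, query_row: str) -> float:
    """Sum of PSSM scores of the query residues over non-gap query columns."""
    ncols_needed = max(pssm.kept_columns) + 1 if pssm.kept_columns else 0
    if len(query_row) < ncols_needed:
        raise ScoringError(
            f"query row of length {len(query_row)} shorter than profile "
            f"({ncols_needed} columns)")
    total = 0.0
    aa_index = {a: i for i, a in enumerate(AA20)}
    for row_idx, p in enumerate(pssm.kept_columns):
        c = query_row[p]
        if c == GAP:
            continue
        j = aa_index.get(c)
        if j is None:
            continue  # non-standard query residue carries no profile score
        total += pssm.scores[row_idx, j]
    return total


def zscores(values: Sequence[float]) -> list[float]:
    """Standardize across clusters; degenerate spread or n < 2 gives zeros."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        return [0.0] * len(arr)
    sd = arr.std(ddof=0)
    if sd == 0:
        return [0.0] * len(arr)
    mean = arr.mean()
    return [float((x - mean) / sd) for x in arr]


def rank_clusters(clusters: Sequence[ClusterRank],
                  weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
                  ) -> list[ClusterRank]:
    """Z-score the components across conserved clusters and order everything.

    Conserved clusters sort by combined score descending, then size
    descending, then cluster id; singletons follow, by size then id.
    """
    conserved = [c for c in clusters if c.label == "conserved"]
    singletons = [c for c in clusters if c.label != "conserved"]
    if conserved:
        for attr, zattr in (("conserv", "z_conserv"), ("contact", "z_contact"),
                            ("pssm", "z_pssm"), ("pcnt", "z_pcnt")):
            zs = zscores([getattr(c.components, attr) for c in conserved])
            for c, z in zip(conserved, zs):
                setattr(c.components, zattr, z)
        for c in conserved:
            c.components.weights = weights
            c.combined = c.components.combined
    conserved.sort(key=lambda c: (-c.combined, -c.size, c.cluster_id))
    singletons.sort(key=lambda c: (-c.size, c.cluster_id))
    ordered = conserved + singletons
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered
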