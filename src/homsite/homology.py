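"""Homologous-neighbor alignments and projection of binding sites onto a query.

Residue correspondences between each neighbor chain and the query are the
vehicle of inference.  They are normally supplied (the method consumes only
the correspondence and its sequence identity, however it was produced); a
global sequence-alignment fallback is available when no alignment is given.
Neighbors below the identity threshold are discarded, and a neighbor binding
site is projected onto the query only when enough of its residues are
covered by the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from homsite.errors import (
    CompositionError,
    MappingError,
    ParseError,
    ValidationError,
)
from homsite.structure import ResidueKey, StructureModel, chain_sequence_map

ChainRef = tuple[str, str]  # (structure_id, chain_id)


@dataclass
class AlignmentMap:
    """Colinear residue-level correspondence neighbor -> query (0-based)."""

    neighbor_id: ChainRef
    query_id: ChainRef
    pairs: list[tuple[int, int]]
    identity_fraction: float = 0.0

    def __post_init__(self) -> None:
        prev_n, prev_q = -1, -1
        for n, q in self.pairs:
            if n <= prev_n or q <= prev_q:
                raise ValidationError(
                    f"alignment {self.neighbor_id}->{self.query_id}: pairs "
                    "must be strictly increasing on both sides (no crossings)")
            prev_n, prev_q = n, q

    def to_query(self) -> dict[int, int]:
        return dict(self.pairs)

    def compute_identity(self, neighbor_seq: str, query_seq: str) -> None:
        """Identity over aligned columns: identical / aligned."""
        if not self.pairs:
            self.identity_fraction = 0.0
            return
        same = sum(1 for n, q in self.pairs if neighbor_seq[n] == query_seq[q])
        self.identity_fraction = same / len(self.pairs)

    def validate_ranges(self, neighbor_len: int, query_len: int) -> None:
        for n, q in self.pairs:
            if not (0 <= n < neighbor_len):
                raise ValidationError(
                    f"alignment {self.neighbor_id}->{self.query_id}: neighbor "
                    f"index {n} outside chain of length {neighbor_len}")
            if not (0 <= q < query_len):
                raise ValidationError(
                    f"alignment {self.neighbor_id}->{self.query_id}: query "
                    f"index {q} outside chain of length {query_len}")


@dataclass
class MappedSite:
    """A neighbor binding site expressed in query coordinates."""

    site_id: str
    source_site: object  # BindingSite
    neighbor_id: ChainRef
    partner_family: str
    query_positions: list[int]          # 0-based query sequence indices
    aa_by_pos: dict[int, str]           # query position -> neighbor residue
    query_residue_keys: list[ResidueKey]
    aligned_fraction: float
    alignment: AlignmentMap
    member_sequence: str = ""           # full neighbor chain sequence


def _identity_selfmap(query_id: ChainRef, length: int) -> AlignmentMap:
    aln = AlignmentMap(neighbor_id=query_id, query_id=query_id,
                       pairs=[(i, i) for i in range(length)])
    aln.identity_fraction = 1.0
    return aln


def identity_alignment(query_id: ChainRef, length: int) -> AlignmentMap:
    """The query's identity self-map (identity 1.0)."""
    return _identity_selfmap(query_id, length)


def _parse_pairs_field(text: str) -> list[tuple[int, int]]:
    pairs = []
    for tok in text.strip().split(";"):
        tok = tok.strip()
        if not tok:
            continue
        try:
            i, j = tok.split(":")
            pairs.append((int(i), int(j)))
        except ValueError as exc:
            raise ParseError(f"bad pair token {tok!r}") from exc
    return pairs


def _load_tsv(path: Path) -> list[AlignmentMap]:
    import csv

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"neighbor_structure", "neighbor_chain",
                    "query_structure", "query_chain", "pairs"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"alignment TSV needs columns {sorted(required)}")
        for row in reader:
            out.append(AlignmentMap(
                neighbor_id=(row["neighbor_structure"], row["neighbor_chain"]),
                query_id=(row["query_structure"], row["query_chain"]),
                pairs=_parse_pairs_field(row["pairs"])))
    return out


def _load_fasta_pairs(path: Path) -> list[AlignmentMap]:
    """Aligned-FASTA dialect: blocks of two records, neighbor then query.

    Headers are ``>structure_id/chain_id``; gaps are ``-``.
    """
    records: list[tuple[str, str]] = []
    header, seq = None, []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(seq)))
            header, seq = line[1:].strip(), []
        else:
            seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    if len(records) % 2:
        raise ParseError("aligned-FASTA file must hold pairs of records")
    out = []
    for (h_n, s_n), (h_q, s_q) in zip(records[::2], records[1::2]):
        if len(s_n) != len(s_q):
            raise ParseError(f"unequal aligned lengths for {h_n!r}/{h_q!r}")
        try:
            n_sid, n_cid = h_n.split("/")
            q_sid, q_cid = h_q.split("/")
        except ValueError as exc:
            raise ParseError(
                f"FASTA header must be structure_id/chain_id, got {h_n!r}"
            ) from exc
        pairs, i, j = [], 0, 0
        for a, b in zip(s_n, s_q):
            if a != "-" and b != "-":
                pairs.append((i, j))
            if a != "-":
                i += 1
            if b != "-":
                j += 1
        out.append(AlignmentMap(neighbor_id=(n_sid, n_cid),
                                query_id=(q_sid, q_cid), pairs=pairs))
    return out


def load_alignments(path: str | Path,
                    sequences: Mapping[ChainRef, str],
                    fmt: str = "auto",
                    skip_unknown_neighbors: bool = False
                    ) -> list[AlignmentMap]:
    """Load neighbor-to-query alignments from TSV or aligned-FASTA.

    ``sequences`` maps (structure_id, chain_id) to the chain sequence and is
    used to range-check indices and compute identity over aligned columns.
    With ``skip_unknown_neighbors`` records for neighbor chains absent from
    ``sequences`` are dropped instead of raising, so a library-wide
    alignment file can be used with a subset of the library; an unknown
    query chain is always an error.
    """
    path = Path(path)
    if fmt == "auto":
        first = path.read_text().lstrip()[:1]
        fmt = "fasta" if first == ">" else "tsv"
    if fmt == "tsv":
        maps = _load_tsv(path)
    elif fmt == "fasta":
        maps = _load_fasta_pairs(path)
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    kept: list[AlignmentMap] = []
    for aln in maps:
        if aln.query_id not in sequences:
            raise ValidationError(
                f"alignment references unknown query chain {aln.query_id}")
        if aln.neighbor_id not in sequences:
            if skip_unknown_neighbors:
                continue
            raise ValidationError(
                f"alignment references unknown neighbor chain {aln.neighbor_id}")
        nseq = sequences[aln.neighbor_id]
        qseq = sequences[aln.query_id]
        aln.validate_ranges(len(nseq), len(qseq))
        aln.compute_identity(nseq, qseq)
        kept.append(aln)
    return kept


def align_fallback(neighbor_seq: str, query_seq: str,
                   matrix=None, gap_open: float = -11.0,
                   gap_extend: float = -1.0,
                   neighbor_id: ChainRef = ("neighbor", "A"),
                   query_id: ChainRef = ("query", "A")) -> AlignmentMap:
    """Optimal global alignment (affine gaps) as an alignment source.

    The first residue of a gap costs ``gap_open``, each further residue
    ``gap_extend``.  Traceback ties prefer diagonal, then up (gap in query),
    then left, so the result is deterministic.
    """
    if not neighbor_seq or not query_seq:
        raise ValidationError("both sequences must be non-empty")
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")

    def sub(a: str, b: str) -> float:
        try:
            return float(matrix[a, b])
        except (KeyError, IndexError):
            try:
                return float(matrix["X", "X"])
            except (KeyError, IndexError):
                return 0.0

    n, m = len(neighbor_seq), len(query_seq)
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (consume neighbor)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in neighbor (consume query)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(neighbor_seq[i - 1], query_seq[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                           Iy[i - 1, j] + gap_open)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend,
                           Ix[i, j - 1] + gap_open)
    # traceback from the best terminal state; diagonal preferred at every tie
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    mats = {"M": M, "Ix": Ix, "Iy": Iy}
    best = max(mats[s][n, m] for s in mats)
    state = next(s for s in ("M", "Ix", "Iy") if mats[s][n, m] == best)
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            s = sub(neighbor_seq[i - 1], query_seq[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for cand, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if np.isclose(mat[i, j], target):
                    state = cand
                    break
        elif state == "Ix":
            target = Ix[i, j]
            i -= 1
            # predecessor preference: M (open), Ix (extend), Iy (open)
            if np.isclose(M[i, j] + gap_open, target):
                state = "M"
            elif np.isclose(Ix[i, j] + gap_extend, target):
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            target = Iy[i, j]
            j -= 1
            if np.isclose(M[i, j] + gap_open, target):
                state = "M"
            elif np.isclose(Iy[i, j] + gap_extend, target):
                state = "Iy"
            else:
                state = "Ix"
        if i == 0 and j == 0:
            break
    pairs.reverse()
    aln = AlignmentMap(neighbor_id=neighbor_id, query_id=query_id, pairs=pairs)
    aln.compute_identity(neighbor_seq, query_seq)
    return aln


def alignment_score(aln: AlignmentMap, neighbor_seq: str, query_seq: str,
                    matrix=None, gap_open: float = -11.0,
                    gap_extend: float = -1.0) -> float:
    """Affine-gap score of a global alignment (for cross-checks)."""
    if matrix is None:
        matrix = substitution_matrices.load("BLOSUM62")
    score = 0.0
    prev_n, prev_q = -1, -1
    gaps: list[int] = []
    for n, q in aln.pairs:
        score += float(matrix[neighbor_seq[n], query_seq[q]])
        if n - prev_n - 1 > 0:
            gaps.append(n - prev_n - 1)
        if q - prev_q - 1 > 0:
            gaps.append(q - prev_q - 1)
        prev_n, prev_q = n, q
    if len(neighbor_seq) - prev_n - 1 > 0:
        gaps.append(len(neighbor_seq) - prev_n - 1)
    if len(query_seq) - prev_q - 1 > 0:
        gaps.append(len(query_seq) - prev_q - 1)
    for g in gaps:
        score += gap_open + (g - 1) * gap_extend
    return score


def filter_neighbors(alignments: Sequence[AlignmentMap],
                     min_identity: float = 0.30) -> list[AlignmentMap]:
    """Keep neighbors at or above the identity threshold.

    Redundant (even identical) neighbors are deliberately kept: the same
    protein solved with different partners carries distinct evidence.
    """
    return [a for a in alignments if a.identity_fraction >= min_identity]


def compose_alignment(a_to_query: AlignmentMap,
                      query_to_b: AlignmentMap) -> AlignmentMap:
    """Reindex neighbor A through the query onto neighbor B.

    (i, k) appears in the result iff (i, j) is in ``a_to_query`` and (j, k)
    in ``query_to_b`` for some query index j.  Composing through the query
    keeps only the correspondence relevant to the query even when A and B
    are mutually closer than either is to the query.
    """
    if a_to_query.query_id != query_to_b.neighbor_id:
        raise CompositionError(
            f"cannot compose: {a_to_query.query_id} != {query_to_b.neighbor_id}")
    q_to_b = query_to_b.to_query()
    pairs = [(i, q_to_b[j]) for i, j in a_to_query.pairs if j in q_to_b]
    return AlignmentMap(neighbor_id=a_to_query.neighbor_id,
                        query_id=query_to_b.query_id, pairs=pairs)


def map_site_to_query(site, aln: AlignmentMap,
                      neighbor_model: StructureModel,
                      query_model: StructureModel,
                      min_aligned: float = 0.75,
                      site_id: str = "",
                      partner_family: str = "") -> MappedSite | None:
    """Project a neighbor binding site onto the query, or reject it.

    Returns None when fewer than ``min_aligned`` of the site's residues are
    covered by the alignment.  The query's own sites, carried by an identity
    self-map, always pass with fraction 1.0.
    """
    n_sid, n_cid = aln.neighbor_id
    q_sid, q_cid = aln.query_id
    n_seq, n_map = chain_sequence_map(neighbor_model, n_cid)
    q_seq, q_map = chain_sequence_map(query_model, q_cid)
    key_to_index = {k: i for i, k in n_map.items()}
    to_q = aln.to_query()

    positions: list[int] = []
    aa_by_pos: dict[int, str] = {}
    for key in site.residue_keys:
        if key not in key_to_index:
            raise MappingError(
                f"site residue {key} not found in neighbor chain {n_cid!r}")
        ni = key_to_index[key]
        qi = to_q.get(ni)
        if qi is None:
            continue
        positions.append(qi)
        aa_by_pos[qi] = n_seq[ni]
    fraction = len(positions) / len(site.residue_keys)
    if fraction < min_aligned:
        return None
    positions.sort()
    return MappedSite(
        site_id=site_id or f"{n_sid}/{n_cid}:{site.owner_domain}-{site.partner_domain}",
        source_site=site,
        neighbor_id=aln.neighbor_id,
        partner_family=partner_family,
        query_positions=positions,
        aa_by_pos=aa_by_pos,
        query_residue_keys=[q_map[q] for q in positions],
        aligned_fraction=fraction,
        alignment=aln,
        member_sequence=n_seq,
    )
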