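"""Alignment loading, composition, neighbor filtering and site projection."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from homsite.errors import MappingError, ValidationError, CompositionError
from homsite.homology import (
    AlignmentMap,
    align_fallback,
    alignment_score,
    compose_alignment,
    filter_neighbors,
    identity_alignment,
    load_alignments,
    map_site_to_query,
)
from homsite.interface import extract_interaction
from homsite.structure import apply_domains, read_structure
from homsite.synth import FamilySpec, generate_family

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# --- loading ---------------------------------------------------------------

def test_tsv_and_fasta_dialects_agree(tmp_path):
    seqs = {("n1", "A"): "ACDEFG", ("q", "A"): "ACEFG"}
    tsv = tmp_path / "aln.tsv"
    tsv.write_text("neighbor_structure\tneighbor_chain\tquery_structure\t"
                   "query_chain\tpairs\n"
                   "n1\tA\tq\tA\t0:0;1:1;3:2;4:3;5:4\n")
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(">n1/A\nACDEFG\n>q/A\nAC-EFG\n")
    a1 = load_alignments(tsv, seqs)
    a2 = load_alignments(fasta, seqs)
    assert len(a1) == len(a2) == 1
    assert a1[0].pairs == a2[0].pairs
    assert a1[0].identity_fraction == a2[0].identity_fraction == 1.0


def test_identity_alignment_of_chain_to_itself(tmp_path):
    seqs = {("q", "A"): "ACDEF"}
    tsv = tmp_path / "aln.tsv"
    tsv.write_text("neighbor_structure\tneighbor_chain\tquery_structure\t"
                   "query_chain\tpairs\n"
                   "q\tA\tq\tA\t" + ";".join(f"{i}:{i}" for i in range(5)) + "\n")
    aln = load_alignments(tsv, seqs)[0]
    assert aln.pairs == [(i, i) for i in range(5)]
    assert aln.identity_fraction == 1.0


def test_unknown_neighbor_strict_or_skipped(tmp_path):
    seqs = {("n1", "A"): "ACDEF", ("q", "A"): "ACDEF"}
    tsv = tmp_path / "aln.tsv"
    tsv.write_text("neighbor_structure\tneighbor_chain\tquery_structure\t"
                   "query_chain\tpairs\n"
                   "n1\tA\tq\tA\t0:0;1:1\n"
                   "absent\tA\tq\tA\t0:0;1:1\n")
    with pytest.raises(ValidationError):
        load_alignments(tsv, seqs)
    kept = load_alignments(tsv, seqs, skip_unknown_neighbors=True)
    assert [a.neighbor_id for a in kept] == [("n1", "A")]


def test_out_of_range_index_rejected(tmp_path):
    seqs = {("n1", "A"): "ACDEF", ("q", "A"): "ACDEF"}
    tsv = tmp_path / "aln.tsv"
    tsv.write_text("neighbor_structure\tneighbor_chain\tquery_structure\t"
                   "query_chain\tpairs\nn1\tA\tq\tA\t0:0;500:1\n")
    with pytest.raises(ValidationError):
        load_alignments(tsv, seqs)


def test_crossing_pairs_rejected():
    with pytest.raises(ValidationError):
        AlignmentMap(neighbor_id=("n", "A"), query_id=("q", "A"),
                     pairs=[(0, 1), (1, 0)])


# --- fallback aligner ------------------------------------------------------

def _exhaustive_best_score(a, b, gap_open=-11.0, gap_extend=-1.0):
    """Enumerate every global alignment of two short strings."""
    best = [-np.inf]

    def score_column_run(cols):
        total, prev_gap_a, prev_gap_b = 0.0, False, False
        for ca, cb in cols:
            if ca == "-":
                total += gap_extend if prev_gap_a else gap_open
                prev_gap_a, prev_gap_b = True, False
            elif cb == "-":
                total += gap_extend if prev_gap_b else gap_open
                prev_gap_b, prev_gap_a = True, False
            else:
                total += float(BLOSUM62[ca, cb])
                prev_gap_a = prev_gap_b = False
        return total

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_column_run(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def test_fallback_identity_for_identical_sequences():
    aln = align_fallback("ACDEF", "ACDEF")
    assert aln.pairs == [(i, i) for i in range(5)]
    assert aln.identity_fraction == 1.0


def test_fallback_matches_exhaustive_oracle_on_short_strings():
    for a, b in [("ACDE", "ACE"), ("WWWW", "WW"), ("AC", "CA"),
                 ("MKV", "MQV"), ("ACDE", "A")]:
        aln = align_fallback(a, b)
        got = alignment_score(aln, a, b)
        assert got == pytest.approx(_exhaustive_best_score(a, b))


def test_fallback_matches_biopython_optimum_on_random_sequences():
    rng = np.random.default_rng(11)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aas = "ARNDCQEGHILKMFPSTWYV"
    for _ in range(25):
        a = "".join(aas[i] for i in rng.integers(0, 20, rng.integers(4, 15)))
        b = "".join(aas[i] for i in rng.integers(0, 20, rng.integers(4, 15)))
        aln = align_fallback(a, b)
        assert alignment_score(aln, a, b) == pytest.approx(aligner.score(a, b))


def test_fallback_rejects_empty_query():
    with pytest.raises(ValidationError):
        align_fallback("ACD", "")


# --- neighbor filtering ----------------------------------------------------

def _aln_with_identity(fraction, name="n"):
    a = AlignmentMap(neighbor_id=(name, "A"), query_id=("q", "A"),
                     pairs=[(0, 0)])
    a.identity_fraction = fraction
    return a


def test_filter_neighbors_threshold_and_redundancy():
    below = _aln_with_identity(0.299)
    at = _aln_with_identity(0.30)
    dup1 = _aln_with_identity(1.0, "d1")
    dup2 = _aln_with_identity(1.0, "d2")
    kept = filter_neighbors([below, at, dup1, dup2])
    assert below not in kept
    assert at in kept
    assert dup1 in kept and dup2 in kept  # identical neighbors both retained
    assert filter_neighbors([]) == []
    everything = [below, at, dup1]
    assert filter_neighbors(everything, min_identity=0.0) == everything


# --- composition -----------------------------------------------------------

def _random_colinear(rng, n_len, q_len, name=("n", "A"), qname=("q", "A")):
    k = int(rng.integers(1, min(n_len, q_len)))
    left = sorted(rng.choice(n_len, size=k, replace=False).tolist())
    right = sorted(rng.choice(q_len, size=k, replace=False).tolist())
    return AlignmentMap(neighbor_id=name, query_id=qname,
                        pairs=list(zip(left, right)))


def test_compose_with_identity_is_identity_element():
    rng = np.random.default_rng(5)
    a = _random_colinear(rng, 30, 30)
    ident = identity_alignment(("q", "A"), 30)
    assert compose_alignment(a, ident).pairs == a.pairs


def test_compose_matches_join_oracle_and_is_associative():
    rng = np.random.default_rng(17)
    for _ in range(50):
        a = _random_colinear(rng, 25, 20, ("a", "A"), ("q", "A"))
        b = _random_colinear(rng, 20, 25, ("q", "A"), ("b", "A"))
        c = _random_colinear(rng, 25, 30, ("b", "A"), ("c", "A"))
        ab = compose_alignment(a, b)
        # nested-loop relational join oracle
        expected = sorted((i, k) for i, j in a.pairs for j2, k in b.pairs
                          if j == j2)
        assert ab.pairs == expected
        left = compose_alignment(ab, c)
        right = compose_alignment(a, compose_alignment(b, c))
        assert left.pairs == right.pairs


def test_compose_mismatched_query_rejected():
    a = AlignmentMap(neighbor_id=("a", "A"), query_id=("q1", "A"), pairs=[(0, 0)])
    b = AlignmentMap(neighbor_id=("q2", "A"), query_id=("b", "A"), pairs=[(0, 0)])
    with pytest.raises(CompositionError):
        compose_alignment(a, b)


# --- site projection -------------------------------------------------------

@pytest.fixture(scope="module")
def projected(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("proj")
    truth = generate_family(FamilySpec(n_members=1, chain_length=20,
                                       binding_modes=(tuple(range(2, 10)),),
                                       mutation_rate=0.0, seed=9), outdir)
    model = read_structure(truth.members[0].path)
    query = read_structure(truth.query_path)
    da, db = apply_domains(model, None)
    pair = extract_interaction(da, db, model)
    return truth, model, query, pair


def test_site_below_aligned_fraction_rejected(projected):
    truth, model, query, pair = projected
    # 8-residue site; align only 5 of its residues (0.625 < 0.75)
    site_idx = [k.seq_num - 1 for k in pair.site_a.residue_keys]
    kept = site_idx[:5]
    pairs = [(i, i) for i in range(20) if i not in site_idx or i in kept]
    aln = AlignmentMap(neighbor_id=(model.structure_id, "A"),
                       query_id=(query.structure_id, "A"), pairs=pairs)
    assert map_site_to_query(pair.site_a, aln, model, query) is None


def test_identity_projection_full_fraction(projected):
    truth, model, query, pair = projected
    aln = identity_alignment((model.structure_id, "A"), 20)
    aln = AlignmentMap(neighbor_id=(model.structure_id, "A"),
                       query_id=(query.structure_id, "A"), pairs=aln.pairs)
    mapped = map_site_to_query(pair.site_a, aln, model, query)
    assert mapped.aligned_fraction == 1.0
    assert mapped.query_positions == [k.seq_num - 1
                                      for k in pair.site_a.residue_keys]


def test_projection_through_known_gap_pattern(projected):
    truth, model, query, pair = projected
    site_idx = [k.seq_num - 1 for k in pair.site_a.residue_keys]
    dropped = site_idx[0]
    # shift: neighbor i maps to query i-1 for i > dropped, others identity
    pairs = [(i, i) for i in range(dropped)] + \
            [(i, i - 1) for i in range(dropped + 1, 20)]
    aln = AlignmentMap(neighbor_id=(model.structure_id, "A"),
                       query_id=(query.structure_id, "A"), pairs=pairs)
    mapped = map_site_to_query(pair.site_a, aln, model, query)
    assert mapped is not None  # 7/8 = 0.875 >= 0.75
    assert mapped.aligned_fraction == pytest.approx(7 / 8)
    assert mapped.query_positions == [i - 1 for i in site_idx[1:]]


def test_site_residue_missing_from_chain_raises(projected):
    truth, model, query, pair = projected
    aln = AlignmentMap(neighbor_id=(model.structure_id, "B"),
                       query_id=(query.structure_id, "A"),
                       pairs=[(i, i) for i in range(20)])
    # site_a lives on chain A; mapping via chain B's index space must fail
    with pytest.raises(MappingError):
        map_site_to_query(pair.site_a, aln, model, query)
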