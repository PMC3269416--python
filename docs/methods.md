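# Methods

## Model and assumptions

`homsite` infers protein–protein binding sites on a query structure from
interfaces observed in homologous complexes. The underlying assumptions
are: (i) binding-site location and sequence patterns are conserved among
close homologs (≥ 30% identity); (ii) interfaces that recur across
non-redundant homologs are likely biological, while interfaces observed
once are ambiguous (lineage-specific binding or crystal packing); and
(iii) a residue-level alignment between each neighbor chain and the query
is an adequate vehicle for transferring interfaces — the package consumes
only the correspondence and its identity, however it was produced
(structure superposition, sequence alignment, or the built-in global
aligner).

## Geometric interface definition

Contacts are heavy-atom distances: residue *r* of domain *D₁* contacts
domain *D₂* when some heavy atom of *r* is within the contact radius
(default 4.0 Å, boundary inclusive) of some heavy atom of *D₂*. The
inclusive boundary is chosen for determinism. A domain pair is an
interaction when at least one side has ≥ 5 contacting residues. The
per-interface contact count used in ranking is the number of contacting
*residue pairs*; an atom-pair count would differ only by a monotone
rescaling of one ranking component and Z-scoring makes the ranking
invariant to affine rescalings anyway.

Intra-chain domain–domain pairs are tested like inter-chain pairs; no
sequence-separation filter is applied. Hydrogens, waters, and non-protein
residues are removed at parse time; altlocs collapse to the
highest-occupancy conformer (ties: first in file); only the first model of
a multi-model file is used. Non-standard amino acids map to 'X' and score
through the substitution matrix's wildcard row.

## Similarity, normalization, clustering

Raw similarity of two query-mapped sites over the union of their query
positions:

    raw(A,B) = Σ_i [ Δ_i·(H(a_i,b_i) + ω) + (1−Δ_i)·w ]

The position bonus ω (+1) applies only to aligned columns and the gap
penalty w (−4) *replaces* the substitution term at gapped columns (Δ_i
zeroes the substitution contribution there). Bit conversion uses
`(λ·raw − ln K)/ln 2` with λ = 0.3176 nats and K = 0.134, the ungapped
BLOSUM62 statistical parameters; both are configurable, as is the matrix
(NCBI text format accepted). Normalization divides by the larger of the
two self bit scores, which bounds S by 1 because BLOSUM62 rows are
maximized on the diagonal.

Clustering is complete linkage on d = 1 − S (similarity 1 ↔ distance 0),
implemented directly so that merge ties break deterministically on the
smallest pair of cluster indices; scipy's implementation is used as an
independent reference in the tests, not in the pipeline. The cut is chosen
by maximizing

    F(partition) = Σ_C p_C·s̄_C + T·Σ_C p_C·ln p_C,  p_C = |C|/N

over the N dendrogram levels, with T = 0.05, s̄_C the mean pairwise S over
member pairs (singletons: s̄ = 1), and ties resolved toward fewer clusters.
Only dendrogram cuts are scored, not arbitrary partitions. Design choices
left open by the functional's description — self-pairs excluded from s̄,
natural-log entropy term, the singleton convention — are fixed as above
and localized in `partition_free_energy` so variants are a one-line change.

A consequence worth knowing: for small sites (≈ 8 residues) a single
substitution moves S by ≈ 0.1, while at T = 0.05 the entropy term only
absorbs within-cluster spreads of ≈ 0.07 at typical cluster sizes. A
member whose interface drifted by even one residue can therefore split off
its mode's cluster as an extra single-member (hence singleton) cluster.
With realistically sized interfaces (tens of residues) the same functional
is much more tolerant. This is inherent to the energy/entropy balance, not
a tie-break artifact; the exhaustive-cut oracle in the tests confirms the
selected cut is the true optimum of F.

## Classification and ranking

Redundancy reduction is greedy: members ordered by descending sequence
length then id; a member is redundant at ≥ 90% identity (over columns
aligned through the query) to a retained representative. Clusters with
> 1 representative are conserved; the rest are singletons, unscored and
ranked after all conserved clusters (by size, then id — among singletons
of equal size the order carries no meaning).

Conserved clusters are scored on four components:

- **conservation** — mean per-column negentropy `log₂21 − h` of the
  cluster's site alignment, h the Shannon entropy of Henikoff
  position-based weighted frequencies over 20 residues + gap (gap as a
  21st symbol). Negentropy makes larger = more conserved = better.
- **contact** — mean residue-pair contact count over member sites.
- **pssm** — query row summed against a profile-average PSSM
  `M(p,b) = Σ_a f_w(p,a)·H(a,b)`; gap mass is renormalized out per column
  and all-gap columns are dropped. This is the standard implicit
  pseudo-count construction: every column is a convex combination of
  substitution-matrix rows, so unobserved residues inherit scores through
  the matrix.
- **pcnt** — mean identity of members to the query over the *whole*
  neighbor-to-query alignment, not just site columns.

Each component is standardized across conserved clusters
(`z = (x−mean)/sd`, population sd; fewer than two clusters or zero spread
gives z = 0 so the combined score stays finite) and combined with weights
defaulting to (1,1,1,1) — the empirically tuned weights of the original
service are unpublished, so a neutral default is exposed in configuration
rather than guessed.

## Evaluation

A predicted site is a true positive for a reference site when strictly
more than half of the *predicted* residues lie in the reference
(`|P∩R|/|P| > 0.5`); a symmetric Jaccard variant is available behind a
flag. Interaction-level metrics label each reference (biological or not)
as matched/unmatched; residue-level metrics pool predicted vs biological
reference residues, with the candidate universe taken as every residue
named by any cluster or reference. Both are reported for all clusters and
for conserved clusters only, exposing the sensitivity/specificity
trade-off of including singletons.

## Synthetic families

The generator emulates the data regime the method assumes: a family of
homodimers sharing conserved binding modes, sequence divergence from a
common ancestor at an i.i.d. per-site mutation rate (default 0.1), 4-fold
slower at interface columns (configurable ratio), and optionally a decoy
member whose interface recurs nowhere else (a crystal-packing stand-in).
Geometry is two pseudo-atoms (CA, CB) per residue on straight parallel
strands, 5 Å residue spacing; planted interface pairs sit 3.4 Å apart and
every other inter-chain residue pair ≥ 6 Å, so the contact truth table is
exact by construction. Output (PDB files, alignment TSV, truth TSV) is
fully determined by the seed.

What the toy does *not* emulate: realistic stereochemistry and packing,
insertions/deletions between homologs (alignments are 1:1), domain
architecture beyond whole chains, interface sizes beyond ~10 residues, and
non-protein partners. Passing tests therefore demonstrate the correctness
of the geometry, algebra, clustering and ranking machinery under
controlled conditions — not accuracy on real PDB-scale data, which
requires a real homolog library.

Default problem sizes (8 members + decoy → 18 binding sites, chain length
60) keep the full pipeline under a second; similarity and clustering
oracle checks run at N ≤ 10 where exhaustive enumeration is exact.

## Numerical and degenerate-input conventions

- Distances and coordinates are float64; contact comparison uses ≤ with no
  epsilon (fixture geometry keeps planted pairs 0.6 Å inside the radius).
- Sites whose self bit score is non-positive cannot be normalized and
  raise a degenerate-site error (cannot occur with BLOSUM62's positive
  diagonal plus the +1 bonus).
- An empty neighbor set, or one fully removed by the identity filter,
  yields an empty report with status
  `no homologous complexes above threshold`.
- All tie-breaks are deterministic (documented per operation) and reports
  serialize with fixed float formatting, so identical inputs and
  configuration produce byte-identical reports.

## Known limitations

- The free-energy cut fragments small, divergent clusters (see above).
- Global sequence alignment is a weaker neighbor-detection tool than
  structure superposition; supplied alignments are trusted unchecked.
- Whole-chain default domains give each chain its own family id, so the
  homo/hetero flag of an interaction is meaningful only when real family
  annotations are supplied.
- The ranking weights are neutral defaults, not calibrated values.
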