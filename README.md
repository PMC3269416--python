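# homsite

Homology-based annotation of protein–protein binding sites and interaction
partners on a query protein structure.

The reliability of experimentally determined protein–protein interactions is
limited, but the PDB is full of solved complexes of close homologs of almost
any query of interest. `homsite` exploits the observation that the structural
location and sequence patterns of binding sites are conserved between close
homologs: it collects interfaces observed in homologous complexes, projects
them onto the query through residue-level alignments, clusters similar
binding sites, and ranks the clusters by evolutionary conservation and
relevance to the query. Recurrent (conserved) binding modes are strong
evidence of biological interfaces; one-off interfaces (singletons) often
correspond to crystal-packing contacts and are left unscored at the bottom
of the ranking.

It is aimed at structural bioinformaticians who have a query structure plus
a set of homologous complexes (with alignments to the query, or sequences
close enough for the built-in global aligner) and want an auditable,
residue-level annotation of likely binding sites.

## Method

**Observed interfaces.** Domains are the units of interaction (by default,
whole chains; domain boundaries can be supplied as TSV). A residue is in
contact with a partner domain when at least one of its heavy atoms lies
within 4.0 Å (inclusive) of the partner's heavy atoms; the contacting
residues of one domain form its *binding site*, and a domain pair counts as
an interaction when at least one side has ≥ 5 residues in contact.

**Homolog collection.** Structure neighbors aligned to the query with
≥ 30% sequence identity (over aligned columns) are retained — deliberately
*without* removing redundant structures, since the same protein solved with
different partners carries distinct evidence. A neighbor's binding site is
projected onto the query when ≥ 75% of its residues are covered by the
alignment. Alignments between neighbors are composed *through the query*
(A→query ∘ query→B), so only correspondence relevant to the query survives.

**Site similarity.** Two sites mapped onto the query are laid over the
union of their query positions and scored

    raw(A,B) = Σ_i [ Δ_i · (H(a_i, b_i) + ω) + (1 − Δ_i) · w ]

with `H` = BLOSUM62, position bonus ω = +1, gap penalty w = −4, and Δ_i = 0
iff either side is a gap. Raw scores become bit scores,
`bits = (λ·raw − ln K)/ln 2` (λ = 0.3176, K = 0.134, the ungapped BLOSUM62
statistical parameters), and are normalized by the larger self bit score:
`S(A,B) = bits(A,B) / max(bits(A,A), bits(B,B))`, so S(A,A) = 1 and
interface alignments of different sizes are comparable.

**Clustering.** Complete-linkage hierarchical clustering on d = 1 − S; the
dendrogram cut is chosen by a pseudo-free-energy functional

    F = Σ_C (|C|/N)·s̄_C + T · Σ_C (|C|/N)·ln(|C|/N),   T = 0.05

which rewards high mean within-cluster similarity s̄_C and penalizes
fragmented descriptions; the cut maximizing F over all dendrogram levels is
selected.

**Classification and ranking.** A cluster with more than one non-redundant
member (redundancy at 90% sequence identity, greedy reduction) is
*conserved*; otherwise it is a *singleton*, unscored and ranked last.
Conserved clusters are scored on four components — Henikoff-weighted
Shannon negentropy of the site alignment (conservation), mean interfacial
contact count, the query scored against a profile-average PSSM of the
cluster, and mean full-alignment identity of members to the query — each
standardized to a Z-score across conserved clusters and combined with
configurable weights (default 1,1,1,1).

## Worked example

Generate a synthetic family of nine homologous dimers — eight members that
alternate between two planted binding modes, plus one decoy with a one-off
crystal-packing-like interface — and annotate the query from it:

```sh
homsite fixtures demo --seed 7 --decoy
homsite infer demo/fam_query.pdb -n demo/fam_m0.pdb ... -n demo/fam_decoy.pdb \
        -a demo/fam_aln.tsv
```

```
# status: ok
rank  cluster_id  label      n_members  n_nonredundant  ...  combined   query_site_residues          partner_family
1     C2          conserved  8          3               ...   1.000000  31,32,33,34,35,36,37,38,39   A;B
2     C3          conserved  6          3               ...  -1.000000  6,7,8,9,10,11,12,13          A;B
3     C0          singleton  2          1               ...  NA         46,47,48,49,50,51,52,53      A;B
4     C1          singleton  2          1               ...  NA         6,7,8,9,10,11,12,13          A;B
```

The two conserved clusters recover exactly the two planted binding modes
(query residues 31–39 and 6–13, author numbering); their `combined` column
is the weighted sum of the four Z-scores, which with two clusters is ±|Σw·z|
symmetric. The decoy's packing interface (residues 46–53) lands in a
singleton: it recurs in no other member, so the method refuses to score it
and ranks it below every conserved cluster — exactly how crystal-packing
contacts are filtered in practice. (A second singleton here is a family
member whose mutated interface drifted just far enough from its mode's
profile; it is left as unscored evidence rather than forced into the
cluster.)

`homsite extract` reports observed interfaces of a single complex, and
`homsite evaluate` scores a report against labeled reference sites with the
strict more-than-half overlap criterion.

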