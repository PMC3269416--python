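"""End-to-end inference: filter, extract, map, cluster, classify, rank.

``run_inference`` drives the whole annotation of a query structure from a
library of homologous complexes and produces an :class:`AnnotationReport`
whose TSV serialization is byte-stable for fixed inputs and configuration.
``evaluate_run`` scores a report against reference interfaces using the
strict more-than-half residue-overlap criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from homsite.cluster import (
    ScoringParams,
    complete_linkage,
    select_partition,
    similarity_matrix,
)
from homsite.errors import EvaluationError
from homsite.homology import (
    AlignmentMap,
    MappedSite,
    align_fallback,
    filter_neighbors,
    identity_alignment,
    load_alignments,
    map_site_to_query,
)
from homsite.interface import ContactParams, enumerate_interactions
from homsite.ranking import (
    ClusterRank,
    ScoreComponents,
    build_cluster_alignment,
    build_pssm,
    classify_cluster,
    conservation_score,
    rank_clusters,
    score_query,
)
from homsite.structure import (
    ResidueKey,
    StructureModel,
    apply_domains,
    chain_sequence_map,
    read_structure,
)

NO_HOMOLOG_STATUS = "no homologous complexes above threshold"


@dataclass
class RunConfig:
    contact_radius: float = 4.0
    min_contact_residues: int = 5
    min_identity: float = 0.30
    min_aligned: float = 0.75
    temperature: float = 0.05
    redundancy_identity: float = 0.90
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    query_chain: str | None = None       # default: first chain in the file
    include_query_sites: bool = True
    overlap_mode: str = "predicted"      # or "jaccard"
    scoring: ScoringParams = field(default_factory=ScoringParams)

    @property
    def contact(self) -> ContactParams:
        return ContactParams(radius=self.contact_radius,
                             min_residues=self.min_contact_residues)

    def snapshot(self) -> dict:
        return {
            "contact_radius": self.contact_radius,
            "min_contact_residues": self.min_contact_residues,
            "min_identity": self.min_identity,
            "min_aligned": self.min_aligned,
            "temperature": self.temperature,
            "redundancy_identity": self.redundancy_identity,
            "weights": list(self.weights),
            "query_chain": self.query_chain,
            "include_query_sites": self.include_query_sites,
            "overlap_mode": self.overlap_mode,
            "position_bonus": self.scoring.position_bonus,
            "gap_penalty": self.scoring.gap_penalty,
            "lambda": self.scoring.lam,
            "K": self.scoring.K,
        }


@dataclass
class ClusterAnnotation:
    """One ranked cluster with its query-level footprint."""

    rank_entry: ClusterRank
    members: list[MappedSite]
    query_residue_keys: list[ResidueKey]
    partner_families: list[str]


@dataclass
class AnnotationReport:
    query_id: str
    query_chain: str
    status: str
    clusters: list[ClusterAnnotation]
    provenance: list[dict]
    log: list[str]
    config: dict

    def to_tsv(self) -> str:
        header = ("rank\tcluster_id\tlabel\tn_members\tn_nonredundant\t"
                  "z_conserv\tz_contact\tz_pssm\tz_pcnt\tcombined\t"
                  "query_site_residues\tpartner_family")
        lines = [header]
        for ann in self.clusters:
            r = ann.rank_entry
            if r.components is not None:
                zs = (f"{r.components.z_conserv:.6f}\t{r.components.z_contact:.6f}\t"
                      f"{r.components.z_pssm:.6f}\t{r.components.z_pcnt:.6f}\t"
                      f"{r.combined:.6f}")
            else:
                zs = "\t".join(["NA"] * 5)
            residues = ",".join(
                f"{k.seq_num}{k.icode.strip()}" for k in ann.query_residue_keys)
            family = ";".join(sorted(set(ann.partner_families)))
            lines.append(f"{r.rank}\t{r.cluster_id}\t{r.label}\t{r.size}\t"
                         f"{r.n_nonredundant}\t{zs}\t{residues}\t{family}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def _collect_mapped_sites(models: dict[str, StructureModel],
                          alignments: Sequence[AlignmentMap],
                          query_model: StructureModel,
                          config: RunConfig,
                          log: list[str],
                          domains_path: str | Path | None = None
                          ) -> list[MappedSite]:
    by_chain: dict[tuple[str, str], AlignmentMap] = {
        a.neighbor_id: a for a in alignments}
    sites: list[MappedSite] = []
    for sid in sorted(models):
        model = models[sid]
        domains = apply_domains(model, domains_path)
        families = {d.domain_id: d.family_id for d in domains}
        chain_of = {d.domain_id: d.chain_id for d in domains}
        if len(domains) < 2:
            log.append(f"{sid}: single domain, no observed interactions")
            continue
        interactions = enumerate_interactions(model, domains, config.contact)
        for pair in interactions:
            for site in (pair.site_a, pair.site_b):
                owner_chain = chain_of[site.owner_domain]
                aln = by_chain.get((sid, owner_chain))
                if aln is None:
                    log.append(f"{sid}/{owner_chain}: no alignment retained; "
                               f"site {site.owner_domain}-{site.partner_domain} skipped")
                    continue
                mapped = map_site_to_query(
                    site, aln, model, query_model,
                    min_aligned=config.min_aligned,
                    site_id=f"{sid}/{owner_chain}:{site.owner_domain}-{site.partner_domain}",
                    partner_family=families[site.partner_domain])
                if mapped is None:
                    log.append(
                        f"{sid}/{owner_chain}: site {site.owner_domain}-"
                        f"{site.partner_domain} below {config.min_aligned:.0%} "
                        "aligned-residue threshold")
                else:
                    sites.append(mapped)
    return sites


def _majority_footprint(members: Sequence[MappedSite]) -> list[int]:
    """Query positions covered by more than half of the member sites."""
    counts: dict[int, int] = {}
    for m in members:
        for q in m.query_positions:
            counts[q] = counts.get(q, 0) + 1
    half = len(members) / 2
    return sorted(q for q, c in counts.items() if c > half)


def run_inference(query_path: str | Path,
                  neighbor_paths: Iterable[str | Path],
                  alignment_path: str | Path | None,
                  config: RunConfig | None = None,
                  domains_path: str | Path | None = None) -> AnnotationReport:
    """Annotate a query structure from a homologous-complex library.

    Neighbors below the identity threshold and sites below the aligned
    fraction threshold are dropped with a logged reason.  An empty neighbor
    set (or one fully filtered away, with no observed sites on the query)
    yields an empty report with an explicit status.
    """
    if config is None:
        config = RunConfig()
    log: list[str] = []
    query_model = read_structure(query_path)
    query_chain = config.query_chain or query_model.chains[0].chain_id
    query_seq, query_map = chain_sequence_map(query_model, query_chain)
    query_ref = (query_model.structure_id, query_chain)

    models: dict[str, StructureModel] = {}
    for p in neighbor_paths:
        m = read_structure(p)
        models[m.structure_id] = m

    sequences = {(sid, c.chain_id): c.sequence
                 for sid, m in models.items() for c in m.chains}
    sequences[query_ref] = query_seq
    for c in query_model.chains:
        sequences[(query_model.structure_id, c.chain_id)] = c.sequence

    if alignment_path is not None:
        alignments = load_alignments(alignment_path, sequences,
                                     skip_unknown_neighbors=True)
    else:
        alignments = [
            align_fallback(m.chain(c.chain_id).sequence, query_seq,
                           matrix=config.scoring.matrix,
                           neighbor_id=(sid, c.chain_id), query_id=query_ref)
            for sid, m in sorted(models.items()) for c in m.chains
        ]
    kept = filter_neighbors(alignments, config.min_identity)
    for a in alignments:
        if a not in kept:
            log.append(f"{a.neighbor_id[0]}/{a.neighbor_id[1]}: identity "
                       f"{a.identity_fraction:.3f} below "
                       f"{config.min_identity:.0%} threshold")

    sites = _collect_mapped_sites(models, kept, query_model, config, log,
                                  domains_path)

    # the query's own observed interfaces join as neighbors of identity 1.0
    if config.include_query_sites and len(query_model.chains) >= 2:
        self_aln = identity_alignment(query_ref, len(query_seq))
        self_models = {query_model.structure_id: query_model}
        sites.extend(_collect_mapped_sites(
            self_models, [self_aln], query_model, config, log, domains_path))

    provenance = [{"neighbor": f"{a.neighbor_id[0]}/{a.neighbor_id[1]}",
                   "identity": round(a.identity_fraction, 6),
                   "kept": a in kept}
                  for a in alignments]

    if not sites:
        return AnnotationReport(
            query_id=query_model.structure_id, query_chain=query_chain,
            status=NO_HOMOLOG_STATUS, clusters=[], provenance=provenance,
            log=log, config=config.snapshot())

    sim = similarity_matrix(sites, config.scoring)
    merges = complete_linkage(1.0 - sim.S)
    partition = select_partition(merges, sim, T=config.temperature)

    annotations: list[ClusterAnnotation] = []
    entries: list[ClusterRank] = []
    for ci, member_idx in enumerate(partition.clusters):
        members = [sites[i] for i in member_idx]
        label, n_reps = classify_cluster(members, config.redundancy_identity)
        caln = build_cluster_alignment(members, query_seq)
        components = None
        if label == "conserved":
            components = ScoreComponents(
                conserv=conservation_score(caln),
                contact=float(np.mean([m.source_site.total_contacts
                                       for m in members])),
                pssm=score_query(build_pssm(caln, config.scoring),
                                 caln.query_row),
                pcnt=float(np.mean([m.alignment.identity_fraction
                                    for m in members])),
            )
        entry = ClusterRank(cluster_id=f"C{ci}", label=label,
                            size=len(members), n_nonredundant=n_reps,
                            components=components, combined=None)
        entries.append(entry)
        footprint = _majority_footprint(members)
        annotations.append(ClusterAnnotation(
            rank_entry=entry, members=members,
            query_residue_keys=[query_map[q] for q in footprint],
            partner_families=[m.partner_family for m in members]))

    ranked = rank_clusters(entries, config.weights)
    order = {id(e): i for i, e in enumerate(ranked)}
    annotations.sort(key=lambda a: order[id(a.rank_entry)])

    return AnnotationReport(
        query_id=query_model.structure_id, query_chain=query_chain,
        status="ok", clusters=annotations, provenance=provenance, log=log,
        config=config.snapshot())


def overlap_fraction(predicted: set, reference: set,
                     mode: str = "predicted") -> tuple[float, bool]:
    """Overlap of a predicted site with a reference site, plus its TP flag.

    ``predicted`` mode divides the intersection by the predicted set (a
    prediction is correct when more than half of its residues lie in the
    reference, strictly); ``jaccard`` divides by the union.
    """
    if not predicted:
        raise EvaluationError("overlap undefined for an empty predicted set")
    inter = len(set(predicted) & set(reference))
    if mode == "predicted":
        fraction = inter / len(predicted)
    elif mode == "jaccard":
        fraction = inter / len(set(predicted) | set(reference))
    else:
        raise ValueError(f"unknown overlap mode {mode!r}")
    return fraction, fraction > 0.5


@dataclass
class ReferenceSite:
    name: str
    residue_keys: set
    biological: bool | None = None


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    def ratio(a: int, b: int) -> float:
        return a / b if b else 0.0

    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": ratio(tp, tp + fn),
        "recall": ratio(tp, tp + fn),
        "specificity": 1.0 - ratio(fp, fp + tn),
        "precision": ratio(tp, tp + fp),
    }


def evaluate_run(report: AnnotationReport,
                 truth: Sequence[ReferenceSite],
                 overlap_mode: str = "predicted") -> dict:
    """Score a report against labeled reference sites.

    Interaction level: a reference is recovered when some predicted cluster
    overlaps it by more than half; biological references drive TP/FN,
    non-biological ones FP/TN.  Residue level: pooled predicted residues
    against pooled biological reference residues over the query chain.
    Both are reported for all clusters and for conserved clusters only.
    """
    for ref in truth:
        if ref.biological is None:
            raise EvaluationError(f"reference {ref.name!r} is unlabeled")

    def prediction_sets(conserved_only: bool) -> list[set]:
        out = []
        for ann in report.clusters:
            if conserved_only and ann.rank_entry.label != "conserved":
                continue
            if ann.query_residue_keys:
                out.append(set(ann.query_residue_keys))
        return out

    results: dict[str, dict] = {}
    for variant, conserved_only in (("all", False), ("conserved_only", True)):
        preds = prediction_sets(conserved_only)
        tp = fp = tn = fn = 0
        for ref in truth:
            matched = any(
                overlap_fraction(p, ref.residue_keys, overlap_mode)[1]
                for p in preds)
            if ref.biological:
                tp += matched
                fn += not matched
            else:
                fp += matched
                tn += not matched
        interaction = binary_metrics(tp, fp, tn, fn)

        pred_residues = set().union(*preds) if preds else set()
        bio_residues = set().union(
            *(r.residue_keys for r in truth if r.biological), set())
        # candidate universe: every residue named by any cluster or reference
        universe = {k for ann in report.clusters
                    for k in ann.query_residue_keys}
        universe |= set().union(*(r.residue_keys for r in truth), set())
        universe |= pred_residues
        rtp = len(pred_residues & bio_residues)
        rfp = len(pred_residues - bio_residues)
        rfn = len(bio_residues - pred_residues)
        rtn = len(universe - pred_residues - bio_residues)
        residue = binary_metrics(rtp, rfp, rtn, rfn)
        results[variant] = {"interaction": interaction, "residue": residue}
    return results
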