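"""Shared fixtures: synthetic families, random toy structures, random sites."""

from __future__ import annotations

import numpy as np
import pytest

from homsite.homology import AlignmentMap, MappedSite
from homsite.pipeline import RunConfig, run_inference
from homsite.ranking import AA20
from homsite.structure import (
    Atom,
    Chain,
    Residue,
    ResidueKey,
    StructureModel,
)
from homsite.synth import FamilySpec, generate_family

QUERY_REF = ("q", "A")


def make_site(positions, residues, site_id="s", query_len=60,
              identity=1.0, member_sequence=None, neighbor_id=("n", "A")):
    """Build a MappedSite directly from a footprint, bypassing structures."""
    positions = list(positions)
    aa_by_pos = dict(zip(positions, residues))
    aln = AlignmentMap(neighbor_id=neighbor_id, query_id=QUERY_REF,
                       pairs=[(i, i) for i in range(query_len)])
    aln.identity_fraction = identity
    return MappedSite(
        site_id=site_id, source_site=None, neighbor_id=neighbor_id,
        partner_family="F", query_positions=sorted(positions),
        aa_by_pos=aa_by_pos,
        query_residue_keys=[ResidueKey("A", p + 1, " ") for p in sorted(positions)],
        aligned_fraction=1.0, alignment=aln,
        member_sequence=member_sequence or "".join(residues))


def random_site(rng, site_id="s", max_pos=40, min_size=3, max_size=12):
    size = int(rng.integers(min_size, max_size + 1))
    positions = sorted(rng.choice(max_pos, size=size, replace=False).tolist())
    residues = [AA20[int(rng.integers(20))] for _ in positions]
    return make_site(positions, residues, site_id=site_id, query_len=max_pos)


def random_toy_model(rng, n_chains=2, n_residues=8, box=12.0):
    """A random-coordinate structure for contact-oracle comparisons."""
    chains = []
    for ci in range(n_chains):
        cid = chr(ord("A") + ci)
        residues = []
        for i in range(n_residues):
            atoms = [Atom("CA", "C", *rng.uniform(0, box, 3)),
                     Atom("CB", "C", *rng.uniform(0, box, 3))]
            residues.append(Residue(ResidueKey(cid, i + 1, " "),
                                    AA20[int(rng.integers(20))], atoms))
        chains.append(Chain(cid, residues))
    return StructureModel(structure_id="toy", chains=chains)


@pytest.fixture(scope="session")
def family(tmp_path_factory):
    """Default two-mode family with a packing decoy (seed 0)."""
    outdir = tmp_path_factory.mktemp("family")
    return generate_family(FamilySpec(decoy_packing=True, seed=0), outdir)


@pytest.fixture(scope="session")
def family_report(family):
    """End-to-end annotation report for the default family."""
    paths = [m.path for m in family.members]
    return run_inference(family.query_path, paths, family.alignment_path,
                         RunConfig())
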