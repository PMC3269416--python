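"""Synthetic structure families with planted, ground-truth interfaces.

The generator emulates what the inference method consumes in the wild: a
family of homologous dimer complexes that reuse a small number of binding
modes (conserved interfaces), sequence divergence at a controlled mutation
rate with reduced drift at interface columns, and optionally one decoy
member carrying a one-off interface that mimics a crystal-packing contact.

Geometry is deliberately minimal: two pseudo-atoms (CA, CB) per residue on
straight parallel strands, with partner-chain interface residues brought
within 3.5 Å of each other and every other inter-chain residue pair kept at
6 Å or more.  Contact detection needs only distances, so nothing more
realistic is required, and the truth table of every generated complex is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from homsite.errors import GenerationError, ValidationError
from homsite.ranking import AA20
from homsite.structure import (
    Atom,
    Chain,
    Residue,
    ResidueKey,
    StructureModel,
    write_pdb,
)

SPACING = 5.0        # Å between consecutive residues along the strand
CONTACT_Z = 3.4      # Å separation of planted interface residue pairs
FAR_Z = 20.0         # Å separation of all other partner residues


@dataclass
class FamilySpec:
    """Conditions under which a synthetic family is generated."""

    n_members: int = 8
    chain_length: int = 60
    binding_modes: tuple[tuple[int, ...], ...] = (
        tuple(range(5, 13)),    # 8-residue mode
        tuple(range(30, 39)),   # 9-residue mode
    )
    mutation_rate: float = 0.1
    seed: int = 0
    decoy_packing: bool = False
    decoy_interface: tuple[int, ...] = tuple(range(45, 53))
    family_id: str = "fam"

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate < 1):
            raise ValidationError("mutation_rate must be in [0, 1)")
        for mode in self.binding_modes:
            if not mode:
                raise GenerationError("empty binding mode")
            if min(mode) < 0 or max(mode) >= self.chain_length:
                raise GenerationError(
                    f"mode {mode} extends past the chain of length "
                    f"{self.chain_length}")
        if self.decoy_packing:
            planted = set().union(*self.binding_modes)
            if planted & set(self.decoy_interface):
                raise GenerationError(
                    "decoy interface must be disjoint from all binding modes")
            if min(self.decoy_interface) < 0 or \
                    max(self.decoy_interface) >= self.chain_length:
                raise GenerationError("decoy interface outside the chain")


@dataclass
class MemberTruth:
    member_id: str
    path: Path
    sequence: str
    interface: tuple[int, ...]   # 0-based residue indices, both chains
    mode_index: int | None       # None for the decoy
    is_decoy: bool = False


@dataclass
class FixtureTruth:
    spec: FamilySpec
    ancestor: str
    query_id: str
    query_path: Path
    alignment_path: Path
    truth_path: Path
    members: list[MemberTruth] = field(default_factory=list)


def _chain(chain_id: str, sequence: str, z_per_residue) -> Chain:
    residues = []
    for i, aa in enumerate(sequence):
        z = z_per_residue(i)
        x = SPACING * i
        residues.append(Residue(
            key=ResidueKey(chain_id, i + 1, " "),
            aa=aa,
            atoms=[Atom("CA", "C", x, 0.0, z), Atom("CB", "C", x, 1.5, z)],
        ))
    return Chain(chain_id, residues)


def _dimer(structure_id: str, sequence: str,
           interface: set[int]) -> StructureModel:
    chain_a = _chain("A", sequence, lambda i: 0.0)
    chain_b = _chain("B", sequence,
                     lambda i: CONTACT_Z if i in interface else FAR_Z)
    return StructureModel(structure_id=structure_id,
                          chains=[chain_a, chain_b])


def _monomer(structure_id: str, sequence: str) -> StructureModel:
    return StructureModel(structure_id=structure_id,
                          chains=[_chain("A", sequence, lambda i: 0.0)])


def _mutate(seq: str, rate: float, slow_columns: set[int],
            slow_factor: float, rng: np.random.Generator) -> str:
    out = []
    for i, aa in enumerate(seq):
        r = rate * slow_factor if i in slow_columns else rate
        if rng.random() < r:
            choices = [a for a in AA20 if a != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def generate_family(spec: FamilySpec, outdir: str | Path,
                    slow_factor: float = 0.25) -> FixtureTruth:
    """Emit a synthetic family: PDB files, alignment TSV, truth table TSV.

    Members cycle through the planted binding modes; the query is a monomer
    carrying the ancestral sequence.  Interface columns mutate at
    ``slow_factor`` times the family mutation rate, emulating the binding
    site conservation the inference method relies on.  Output is fully
    determined by ``spec.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ancestor = "".join(AA20[rng.integers(20)] for _ in range(spec.chain_length))
    slow = set().union(*spec.binding_modes)

    query_id = f"{spec.family_id}_query"
    query_path = outdir / f"{query_id}.pdb"
    write_pdb(_monomer(query_id, ancestor), query_path)

    truth = FixtureTruth(spec=spec, ancestor=ancestor, query_id=query_id,
                         query_path=query_path,
                         alignment_path=outdir / f"{spec.family_id}_aln.tsv",
                         truth_path=outdir / f"{spec.family_id}_truth.tsv")

    n_modes = len(spec.binding_modes)
    for j in range(spec.n_members):
        member_id = f"{spec.family_id}_m{j}"
        seq = _mutate(ancestor, spec.mutation_rate, slow, slow_factor, rng)
        mode_index = j % n_modes
        interface = tuple(sorted(spec.binding_modes[mode_index]))
        path = outdir / f"{member_id}.pdb"
        write_pdb(_dimer(member_id, seq, set(interface)), path)
        truth.members.append(MemberTruth(
            member_id=member_id, path=path, sequence=seq,
            interface=interface, mode_index=mode_index))
    if spec.decoy_packing:
        truth.members.append(generate_decoy(spec, outdir, rng))

    _write_alignments(truth)
    _write_truth_table(truth)
    return truth


def generate_decoy(spec: FamilySpec, outdir: str | Path,
                   rng: np.random.Generator | None = None) -> MemberTruth:
    """One extra member whose interface recurs in no other member."""
    if not spec.decoy_packing:
        raise GenerationError("decoy requested but decoy_packing is off")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 10_007)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    member_id = f"{spec.family_id}_decoy"
    # the decoy is an unrelated-looking member: full-rate mutation everywhere
    base_rng = np.random.default_rng(spec.seed)
    ancestor = "".join(AA20[base_rng.integers(20)]
                       for _ in range(spec.chain_length))
    seq = _mutate(ancestor, spec.mutation_rate, set(), 1.0, rng)
    interface = tuple(sorted(spec.decoy_interface))
    path = outdir / f"{member_id}.pdb"
    write_pdb(_dimer(member_id, seq, set(interface)), path)
    return MemberTruth(member_id=member_id, path=path, sequence=seq,
                       interface=interface, mode_index=None, is_decoy=True)


def _write_alignments(truth: FixtureTruth) -> None:
    """Known residue correspondences: every member chain aligns 1:1."""
    lines = ["neighbor_structure\tneighbor_chain\tquery_structure\t"
             "query_chain\tpairs"]
    pairs = ";".join(f"{i}:{i}" for i in range(truth.spec.chain_length))
    for m in truth.members:
        for chain_id in ("A", "B"):
            lines.append(f"{m.member_id}\t{chain_id}\t{truth.query_id}\tA\t{pairs}")
    truth.alignment_path.write_text("\n".join(lines) + "\n")


def _write_truth_table(truth: FixtureTruth) -> None:
    lines = ["member_id\tpath\tmode_index\tis_decoy\tinterface\tsequence"]
    for m in truth.members:
        mode = "" if m.mode_index is None else str(m.mode_index)
        iface = ",".join(str(i) for i in m.interface)
        lines.append(f"{m.member_id}\t{m.path.name}\t{mode}\t"
                     f"{int(m.is_decoy)}\t{iface}\t{m.sequence}")
    truth.truth_path.write_text("\n".join(lines) + "\n")
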