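"""Uniform structure model: chains, residues, heavy atoms, domains.

Structures are parsed with :mod:`gemmi` from PDB or mmCIF files into a small
immutable-ish model that downstream stages consume.  Only heavy atoms of
amino-acid residues from the first model are kept; alternate conformations
are collapsed to the highest-occupancy conformer.  Residues are identified
everywhere by author numbering plus insertion code so that every report can
be checked against the deposited file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi

from homsite.errors import (
    EmptyModelError,
    LookupError_,
    ParseError,
    ValidationError,
)

#: one-letter codes for the 20 standard amino acids; everything else is 'X'
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class ResidueKey(NamedTuple):
    """Author-numbering identity of a residue within a structure."""

    chain_id: str
    seq_num: int
    icode: str  # single char, " " when absent


class Atom(NamedTuple):
    name: str
    element: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    key: ResidueKey
    aa: str  # one-letter, 'X' for non-standard
    atoms: list[Atom]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain]
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise LookupError_(
            f"chain {chain_id!r} not found in structure {self.structure_id!r}"
        )

    def residue(self, key: ResidueKey) -> Residue:
        for r in self.chain(key.chain_id).residues:
            if r.key == key:
                return r
        raise LookupError_(f"residue {key} not found in {self.structure_id!r}")


@dataclass
class DomainInstance:
    """A set of residues on one chain acting as a unit of interaction."""

    domain_id: str
    family_id: str
    chain_id: str
    residue_keys: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residue_keys:
            raise ValidationError(f"domain {self.domain_id!r} has no residues")


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def _one_letter(resname: str) -> str:
    return THREE_TO_ONE.get(resname.strip().upper(), "X")


def _collapse_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties first."""
    chosen: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            chosen[atom.name] = atom
    return [chosen[name] for name in order]


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Waters, hydrogens and non-amino-acid residues are dropped; altlocs are
    resolved to the highest-occupancy conformer (ties: first in file); only
    the first model of a multi-model file is read.

    Raises
    ------
    ParseError
        if the file cannot be read under the named standard.
    EmptyModelError
        if no protein chain remains after filtering.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no coordinate model")
    st.setup_entities()

    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    model = st[0]
    chains: list[Chain] = []
    seen_keys: set[ResidueKey] = set()
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            if name == "HOH" or name == "DOD":
                continue
            info = gemmi.find_tabulated_residue(name)
            is_aa = (info is not None and info.is_amino_acid()) or name in THREE_TO_ONE
            if not is_aa:
                continue
            atoms = [
                Atom(a.name, a.element.name, a.pos.x, a.pos.y, a.pos.z)
                for a in _collapse_altlocs(gres)
                if not a.is_hydrogen()
            ]
            if not atoms:
                continue
            icode = gres.seqid.icode if gres.seqid.icode.strip() else " "
            key = ResidueKey(gchain.name, gres.seqid.num, icode)
            if key in seen_keys:  # residue-level altloc: keep first
                continue
            seen_keys.add(key)
            residues.append(Residue(key, _one_letter(name), atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise EmptyModelError(f"{path}: no protein chains after filtering")
    structure_id = st.name.strip() or path.stem
    return StructureModel(structure_id=structure_id, chains=chains,
                          source_format=source_format)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model's heavy atoms back to a minimal fixed-column PDB."""
    lines: list[str] = []
    lines.append(f"HEADER    SYNTHETIC MODEL                         {model.structure_id[:10]:<10}")
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for atom in res.atoms:
                serial += 1
                name = atom.name[:4]
                # pad one-or-two-char names per PDB convention (col 13-16)
                padded = f" {name:<3}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:>5} {padded} {resname:>3} {chain.chain_id[:1]}"
                    f"{res.key.seq_num:>4}{res.key.icode[:1]}   "
                    f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
                )
        lines.append(f"TER   {serial + 1:>5}      {ONE_TO_THREE.get(chain.residues[-1].aa, 'UNK'):>3} "
                     f"{chain.chain_id[:1]}{chain.residues[-1].key.seq_num:>4}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.structure_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.key.seq_num, res.key.icode)
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    """Write the model as mmCIF (via gemmi)."""
    _to_gemmi(model).make_mmcif_document().write_file(str(path))


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        lo, sep, hi = part.partition("-")
        try:
            a = int(lo)
            b = int(hi) if sep else a
        except ValueError as exc:
            raise ValidationError(f"bad range {part!r}") from exc
        if b < a:
            raise ValidationError(f"inverted range {part!r}")
        out.append((a, b))
    if not out:
        raise ValidationError(f"empty range spec {text!r}")
    return out


def apply_domains(model: StructureModel,
                  annotations: str | Path | None = None) -> list[DomainInstance]:
    """Attach domain boundaries, or default to one domain per chain.

    ``annotations`` is a TSV with columns structure_id, chain_id, domain_id,
    family_id, ranges (author numbering, inclusive, e.g. ``5-120,130-200``).
    Rows for other structures are ignored.  Without annotations each whole
    chain becomes one domain whose family is the chain id.
    """
    if annotations is None:
        return [
            DomainInstance(domain_id=c.chain_id, family_id=c.chain_id,
                           chain_id=c.chain_id,
                           residue_keys=[r.key for r in c.residues])
            for c in model.chains
        ]
    domains: list[DomainInstance] = []
    with open(annotations, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"structure_id", "chain_id", "domain_id", "family_id", "ranges"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValidationError(
                f"domain TSV must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            if row["structure_id"] != model.structure_id:
                continue
            chain_ids = {c.chain_id for c in model.chains}
            if row["chain_id"] not in chain_ids:
                raise ValidationError(
                    f"row {i}: chain {row['chain_id']!r} not in structure "
                    f"{model.structure_id!r}")
            chain = model.chain(row["chain_id"])
            ranges = _parse_ranges(row["ranges"])
            keys = [r.key for r in chain.residues
                    if any(a <= r.key.seq_num <= b for a, b in ranges)]
            if not keys:
                raise ValidationError(
                    f"row {i}: ranges {row['ranges']!r} select no residues")
            domains.append(DomainInstance(
                domain_id=row["domain_id"], family_id=row["family_id"],
                chain_id=row["chain_id"], residue_keys=keys))
    if not domains:
        raise ValidationError(
            f"no annotation rows matched structure {model.structure_id!r}")
    return domains


def chain_sequence_map(model: StructureModel,
                       chain_id: str) -> tuple[str, dict[int, ResidueKey]]:
    """Return (sequence, {0-based index -> residue key}) for one chain."""
    chain = model.chain(chain_id)
    index_to_key = {i: r.key for i, r in enumerate(chain.residues)}
    return chain.sequence, index_to_key
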