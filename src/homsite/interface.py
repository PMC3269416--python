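"""Inter-domain contact detection and binding-site definition.

A residue of one domain is in contact with the partner domain when at least
one of its heavy atoms lies within the contact radius (default 4.0 Å,
boundary inclusive) of any heavy atom of the partner.  The contacting
residues of one domain constitute its binding site; a domain pair counts as
an interaction when at least one side has ``min_residues`` (default 5)
residues in contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from homsite.errors import InvalidPairError, ValidationError
from homsite.structure import DomainInstance, ResidueKey, StructureModel


@dataclass(frozen=True)
class ContactParams:
    radius: float = 4.0       # Å, heavy-atom distance, inclusive
    min_residues: int = 5     # residues in contact on at least one side

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("contact radius must be positive")
        if self.min_residues < 1:
            raise ValidationError("min_residues must be >= 1")


@dataclass
class BindingSite:
    """Residues of ``owner_domain`` in contact with ``partner_domain``."""

    owner_domain: str
    partner_domain: str
    residue_keys: list[ResidueKey]
    contacts_per_residue: dict[ResidueKey, int]
    total_contacts: int  # contacting residue pairs across the interface

    def __len__(self) -> int:
        return len(self.residue_keys)


@dataclass
class InteractionPair:
    site_a: BindingSite
    site_b: BindingSite
    homo: bool  # both domains belong to the same family


def _domain_atoms(domain: DomainInstance,
                  model: StructureModel) -> tuple[np.ndarray, list[ResidueKey]]:
    """Stack heavy-atom coordinates; parallel list maps rows to residues."""
    coords: list[tuple[float, float, float]] = []
    owners: list[ResidueKey] = []
    for key in domain.residue_keys:
        res = model.residue(key)
        for atom in res.atoms:
            coords.append((atom.x, atom.y, atom.z))
            owners.append(key)
    return np.asarray(coords, dtype=float), owners


def residue_contacts(domain_a: DomainInstance, domain_b: DomainInstance,
                     model: StructureModel,
                     params: ContactParams = ContactParams()
                     ) -> list[tuple[ResidueKey, ResidueKey]]:
    """All residue pairs (a, b) with heavy atoms within the contact radius.

    The list is deduplicated and sorted by (a-key, b-key).  Domains must be
    disjoint residue sets (they may share a chain).
    """
    if set(domain_a.residue_keys) & set(domain_b.residue_keys):
        raise InvalidPairError(
            f"domains {domain_a.domain_id!r} and {domain_b.domain_id!r} "
            "share residues")
    xyz_a, owners_a = _domain_atoms(domain_a, model)
    xyz_b, owners_b = _domain_atoms(domain_b, model)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return []
    tree = cKDTree(xyz_b)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for ia, neighbors in enumerate(tree.query_ball_point(xyz_a, params.radius)):
        for ib in neighbors:
            pairs.add((owners_a[ia], owners_b[ib]))
    return sorted(pairs)


def _ordered_unique(keys: list[ResidueKey], domain: DomainInstance) -> list[ResidueKey]:
    wanted = set(keys)
    return [k for k in domain.residue_keys if k in wanted]


def extract_interaction(domain_a: DomainInstance, domain_b: DomainInstance,
                        model: StructureModel,
                        params: ContactParams = ContactParams()
                        ) -> InteractionPair | None:
    """Build the interaction for a domain pair, or None below threshold.

    An interaction exists when at least one side has ``min_residues``
    distinct contacting residues; both binding sites are then populated from
    the full contact list.
    """
    contacts = residue_contacts(domain_a, domain_b, model, params)
    if not contacts:
        return None
    res_a = {k for k, _ in contacts}
    res_b = {k for _, k in contacts}
    if max(len(res_a), len(res_b)) < params.min_residues:
        return None
    count_a: dict[ResidueKey, int] = {}
    count_b: dict[ResidueKey, int] = {}
    for ka, kb in contacts:
        count_a[ka] = count_a.get(ka, 0) + 1
        count_b[kb] = count_b.get(kb, 0) + 1
    site_a = BindingSite(
        owner_domain=domain_a.domain_id, partner_domain=domain_b.domain_id,
        residue_keys=_ordered_unique(list(res_a), domain_a),
        contacts_per_residue=count_a, total_contacts=len(contacts))
    site_b = BindingSite(
        owner_domain=domain_b.domain_id, partner_domain=domain_a.domain_id,
        residue_keys=_ordered_unique(list(res_b), domain_b),
        contacts_per_residue=count_b, total_contacts=len(contacts))
    return InteractionPair(site_a=site_a, site_b=site_b, homo=False)


def enumerate_interactions(model: StructureModel,
                           domains: list[DomainInstance],
                           params: ContactParams = ContactParams()
                           ) -> list[InteractionPair]:
    """Test every unordered domain pair (inter- and intra-chain).

    Output is ordered by (domain_id_a, domain_id_b); the ``homo`` flag is set
    when both domains share a family id.
    """
    if len(domains) < 2:
        raise ValidationError("need at least 2 domains to enumerate pairs")
    ordered = sorted(domains, key=lambda d: d.domain_id)
    out: list[InteractionPair] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            pair = extract_interaction(ordered[i], ordered[j], model, params)
            if pair is not None:
                pair.homo = ordered[i].family_id == ordered[j].family_id
                out.append(pair)
    return out
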