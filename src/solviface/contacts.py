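"""Atomic contact detection and interface assembly.

Interactions between two entities are classified purely by heavy-atom
distance and the role flags of the chemistry dictionary:

* hydrogen bond — donor/acceptor atom pair at <= 3.6 A,
* salt bridge   — oppositely charged atom pair at <= 4.0 A,
* van der Waals — any heavy-atom pair at <= 4.5 A.

All criteria are inclusive at the boundary and a pair may carry several
labels (a 3.2 A salt bridge is also a hydrogen bond and a vdW contact).
Water-mediated interactions are residue pairs bridged by a single water
whose oxygen lies within hydrogen-bond distance of a donor/acceptor atom on
each side.  Interfaces are domain-centric: the set of a domain's residues
contacting one ligand entity, annotated per residue with solvation (dry /
wet / dual) and chemistry (hydrophobic / hydrophilic).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .entity_typing import Entity, EntitySet, EntityType
from .structure_io import AtomRecord, ChemistryDictionary, ResidueKey, Structure

logger = logging.getLogger(__name__)

#: numerical slack so that boundary distances written with 3 decimals stay
#: inclusive under floating-point arithmetic
EPS = 1e-9

#: priority used when a residue-level summary reports one label
LABEL_RANK = {"salt_bridge": 2, "hbond": 1, "vdw": 0}


@dataclass(frozen=True)
class Cutoffs:
    """Distance criteria in Angstrom."""

    hbond: float = 3.6
    salt_bridge: float = 4.0
    vdw: float = 4.5
    covalent: float = 1.9

    def __post_init__(self) -> None:
        for name in ("hbond", "salt_bridge", "vdw", "covalent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name} must be positive")


AtomRef = tuple[str, ResidueKey, str]  # (entity_id, residue, atom name)


@dataclass(frozen=True)
class Contact:
    """One classified atomic interaction (or synthesized water bridge)."""

    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    labels: frozenset[str]
    bridging_water: str = ""

    def unordered(self) -> tuple:
        ends = tuple(sorted((self.atom_a, self.atom_b)))
        return (ends, round(self.distance, 6), tuple(sorted(self.labels)), self.bridging_water)


@dataclass
class Interface:
    """A domain's residue set contacting one ligand entity."""

    interface_id: str
    domain_id: str
    family_id: str
    ligand_entity_id: str
    ligand_type: str  # protein | peptide | dna | rna | saccharide
    ligand_family_id: str
    residue_set: list[ResidueKey]
    solvation: dict[ResidueKey, str]  # dry | wet | dual
    chemistry: dict[ResidueKey, str]  # hydrophobic | hydrophilic
    complex_class: str  # homo | hetero
    chain_class: str  # intra | inter
    covalent: bool
    contacts: list[Contact]
    pdb_id: str = ""


# ---------------------------------------------------------------------------
# atom gathering
# ---------------------------------------------------------------------------

def _heavy_atoms(structure: Structure, entity: Entity) -> list[AtomRecord]:
    atoms: list[AtomRecord] = []
    for key in entity.residues:
        if key not in structure._res_atoms:  # entity may reference absent residues
            continue
        for atom in structure.residue_atoms(key):
            if atom.element not in ("H", "D"):
                atoms.append(atom)
    return atoms


def _polar_atoms(
    structure: Structure, entity: Entity, chem: ChemistryDictionary
) -> list[AtomRecord]:
    out = []
    for key in entity.residues:
        if key not in structure._res_atoms:
            continue
        for atom in structure.residue_atoms(key):
            roles = chem.atom_roles(key.res_name, atom.name)
            if "donor" in roles or "acceptor" in roles:
                out.append(atom)
    return out


def _is_covalent(structure: Structure, a: AtomRecord, b: AtomRecord, cutoff: float) -> bool:
    if structure.is_bonded(a.serial, b.serial):
        return True
    return float(np.linalg.norm(a.xyz - b.xyz)) <= cutoff + EPS


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def detect_direct_contacts(
    structure: Structure,
    entity_a: Entity,
    entity_b: Entity,
    chem: ChemistryDictionary,
    cutoffs: Cutoffs = Cutoffs(),
) -> list[Contact]:
    """All classified heavy-atom contacts between two distinct entities.

    Covalently bonded pairs (CONECT or within the covalent fallback
    distance) are excluded from the non-covalent contact list.  The result
    is symmetric: swapping the arguments mirrors each record.
    """
    if entity_a.entity_id == entity_b.entity_id:
        raise ValueError("direct contacts require two distinct entities")
    atoms_a = _heavy_atoms(structure, entity_a)
    atoms_b = _heavy_atoms(structure, entity_b)
    if not atoms_a or not atoms_b:
        return []
    coords_b = np.array([a.coords for a in atoms_b])
    tree = cKDTree(coords_b)
    contacts: list[Contact] = []
    for atom in atoms_a:
        for j in tree.query_ball_point(atom.xyz, r=cutoffs.vdw + EPS):
            other = atoms_b[j]
            dist = float(np.linalg.norm(atom.xyz - other.xyz))
            if dist > cutoffs.vdw + EPS:
                continue
            if _is_covalent(structure, atom, other, cutoffs.covalent):
                continue
            roles_a = chem.atom_roles(atom.residue_key.res_name, atom.name)
            roles_b = chem.atom_roles(other.residue_key.res_name, other.name)
            labels = {"vdw"}
            if dist <= cutoffs.hbond + EPS and (
                ("donor" in roles_a and "acceptor" in roles_b)
                or ("acceptor" in roles_a and "donor" in roles_b)
            ):
                labels.add("hbond")
            if dist <= cutoffs.salt_bridge + EPS and (
                ("positive" in roles_a and "negative" in roles_b)
                or ("negative" in roles_a and "positive" in roles_b)
            ):
                labels.add("salt_bridge")
            contacts.append(
                Contact(
                    atom_a=(entity_a.entity_id, atom.residue_key, atom.name),
                    atom_b=(entity_b.entity_id, other.residue_key, other.name),
                    distance=dist,
                    labels=frozenset(labels),
                )
            )
    contacts.sort(key=lambda c: (c.atom_a[1], c.atom_a[2], c.atom_b[1], c.atom_b[2]))
    return contacts


def detect_water_bridges(
    structure: Structure,
    entity_a: Entity,
    entity_b: Entity,
    waters: Sequence[Entity],
    chem: ChemistryDictionary,
    cutoffs: Cutoffs = Cutoffs(),
) -> list[Contact]:
    """Residue-residue contacts mediated by a single bridging water.

    A residue pair (ra in a, rb in b) is bridged by water W when each
    residue has at least one donor/acceptor atom within hydrogen-bond
    distance of W's oxygen.  One record is synthesized per (ra, rb, W)
    triple; its distance is the longer of the two residue-water legs, and
    the closest polar atom of each residue is reported.
    """
    polar_a = _polar_atoms(structure, entity_a, chem)
    polar_b = _polar_atoms(structure, entity_b, chem)
    if not polar_a or not polar_b:
        return []
    bridges: list[Contact] = []
    for water in waters:
        if water.entity_type is not EntityType.WATER:
            continue
        oxy = structure.find_atom(water.residues[0], "O")
        if oxy is None:
            continue

        def _legs(polar: list[AtomRecord]) -> dict[ResidueKey, tuple[float, str]]:
            legs: dict[ResidueKey, tuple[float, str]] = {}
            for atom in polar:
                dist = float(np.linalg.norm(atom.xyz - oxy.xyz))
                if dist <= cutoffs.hbond + EPS:
                    prev = legs.get(atom.residue_key)
                    if prev is None or dist < prev[0]:
                        legs[atom.residue_key] = (dist, atom.name)
            return legs

        legs_a = _legs(polar_a)
        legs_b = _legs(polar_b)
        for ra in sorted(legs_a):
            for rb in sorted(legs_b):
                da, name_a = legs_a[ra]
                db, name_b = legs_b[rb]
                bridges.append(
                    Contact(
                        atom_a=(entity_a.entity_id, ra, name_a),
                        atom_b=(entity_b.entity_id, rb, name_b),
                        distance=max(da, db),
                        labels=frozenset({"hbond"}),
                        bridging_water=water.entity_id,
                    )
                )
    return bridges


# ---------------------------------------------------------------------------
# interface assembly
# ---------------------------------------------------------------------------

def build_interface(
    structure: Structure,
    domain: Entity,
    ligand: Entity,
    waters: Sequence[Entity],
    chem: ChemistryDictionary,
    cutoffs: Cutoffs = Cutoffs(),
    interface_id: str = "IF_0",
    pdb_id: str = "",
) -> Interface | None:
    """Assemble the domain-centric interface with one ligand entity, or
    ``None`` when there is no direct or water-mediated contact at all."""
    if domain.entity_type is not EntityType.DOMAIN:
        raise ValueError(f"{domain.entity_id}: interface owner must be a domain")
    direct = detect_direct_contacts(structure, domain, ligand, chem, cutoffs)
    bridges = detect_water_bridges(structure, domain, ligand, waters, chem, cutoffs)
    if not direct and not bridges:
        return None

    dry = {c.atom_a[1] for c in direct}
    wet = {c.atom_a[1] for c in bridges}
    residues = sorted(dry | wet)
    solvation = {
        key: "dual" if key in dry and key in wet else ("dry" if key in dry else "wet")
        for key in residues
    }
    # chemistry: hydrophobic only if every contacting atom of the residue is
    # flagged hydrophobic; hydrophilic wins on mixed character
    atoms_by_res: dict[ResidueKey, set[str]] = {}
    for contact in direct + bridges:
        atoms_by_res.setdefault(contact.atom_a[1], set()).add(contact.atom_a[2])
    chemistry = {}
    for key, names in atoms_by_res.items():
        all_phobic = all(
            "hydrophobic" in chem.atom_roles(key.res_name, name) for name in names
        )
        chemistry[key] = "hydrophobic" if all_phobic else "hydrophilic"

    complex_class = (
        "homo"
        if ligand.entity_type is EntityType.DOMAIN
        and ligand.family_id == domain.family_id
        else "hetero"
    )
    covalent = bool(
        ligand.entity_type is EntityType.SACCHARIDE
        and ligand.covalent_to_protein
        and _entities_bonded(structure, domain, ligand, cutoffs)
    )
    chain_class = (
        "intra"
        if covalent or (domain.member_chains & ligand.member_chains)
        else "inter"
    )
    return Interface(
        interface_id=interface_id,
        domain_id=domain.entity_id,
        family_id=domain.family_id,
        ligand_entity_id=ligand.entity_id,
        ligand_type=ligand.ligand_type,
        ligand_family_id=ligand.family_id,
        residue_set=residues,
        solvation=solvation,
        chemistry=chemistry,
        complex_class=complex_class,
        chain_class=chain_class,
        covalent=covalent,
        contacts=direct + bridges,
        pdb_id=pdb_id,
    )


def _entities_bonded(
    structure: Structure, a: Entity, b: Entity, cutoffs: Cutoffs
) -> bool:
    for atom_a in _heavy_atoms(structure, a):
        for atom_b in _heavy_atoms(structure, b):
            if _is_covalent(structure, atom_a, atom_b, cutoffs.covalent):
                return True
    return False


def scan_structure(
    structure: Structure,
    entities: EntitySet,
    chem: ChemistryDictionary,
    cutoffs: Cutoffs = Cutoffs(),
    pdb_id: str = "",
    id_start: int = 1,
) -> list[Interface]:
    """Build every domain-vs-ligand interface of one structure with
    deterministic interface ids."""
    interfaces: list[Interface] = []
    waters = entities.waters
    n = id_start
    for domain in sorted(entities.domains, key=lambda e: e.entity_id):
        for ligand in sorted(entities.ligand_entities, key=lambda e: e.entity_id):
            if ligand.entity_id == domain.entity_id:
                continue
            iface = build_interface(
                structure,
                domain,
                ligand,
                waters,
                chem,
                cutoffs,
                interface_id=f"IF_{n}",
                pdb_id=pdb_id,
            )
            if iface is not None:
                interfaces.append(iface)
                n += 1
    return interfaces


# ---------------------------------------------------------------------------
# crystal-packing filter
# ---------------------------------------------------------------------------

def filter_crystal_packing(
    interfaces: list[Interface],
    classifier_hook: Callable[[Interface], float] | None = None,
    probability_cutoff: float = 0.70,
    naive_heuristic: bool = False,
    min_residues: int = 5,
) -> list[Interface]:
    """Drop probable crystal-packing interfaces.

    With ``classifier_hook`` (an external biological-probability predicate,
    e.g. an SVM-based classifier), interfaces scoring below
    ``probability_cutoff`` are dropped; a raising hook keeps the interface
    and logs the error.  Without a hook no filtering happens unless the
    clearly-labeled naive heuristic is opted in, which drops protein-protein
    interfaces with fewer than ``min_residues`` interface residues.  The
    naive heuristic is a size floor only — not a trained classifier.
    """
    if classifier_hook is None and not naive_heuristic:
        logger.warning("no packing classifier configured; interfaces unfiltered")
        return list(interfaces)
    kept = []
    for iface in interfaces:
        if classifier_hook is not None:
            try:
                prob = classifier_hook(iface)
            except Exception:
                logger.exception(
                    "packing classifier failed on %s; interface kept", iface.interface_id
                )
                kept.append(iface)
                continue
            if prob < probability_cutoff:
                continue
            kept.append(iface)
        else:
            if iface.ligand_type == "protein" and len(iface.residue_set) < min_residues:
                continue
            kept.append(iface)
    return kept


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_contact_table(interfaces: Sequence[Interface]) -> str:
    """TSV contact listing: one row per classified atomic interaction."""
    rows = [
        "interface_id\tentity_a\tchain_a\tresidue_a\tatom_a\t"
        "entity_b\tchain_b\tresidue_b\tatom_b\tdistance\tlabels\tbridging_water"
    ]
    for iface in interfaces:
        for c in iface.contacts:
            ea, ka, na = c.atom_a
            eb, kb, nb = c.atom_b
            rows.append(
                "\t".join(
                    [
                        iface.interface_id,
                        ea,
                        ka.chain_id,
                        f"{ka.res_name}{ka.seq_num}{ka.insertion_code}",
                        na,
                        eb,
                        kb.chain_id,
                        f"{kb.res_name}{kb.seq_num}{kb.insertion_code}",
                        nb,
                        f"{c.distance:.2f}",
                        ",".join(sorted(c.labels, key=lambda l: -LABEL_RANK[l])),
                        c.bridging_water or "-",
                    ]
                )
            )
    return "\n".join(rows) + "\n"


def interface_to_dict(iface: Interface) -> dict:
    """JSON-ready summary mirroring the residue-residue interaction listing
    with physicochemical and water-mediation properties."""
    residue_rows = []
    for key in iface.residue_set:
        partner_rows = []
        for c in iface.contacts:
            if c.atom_a[1] != key:
                continue
            partner = c.atom_b[1]
            partner_rows.append(
                {
                    "partner_residue": partner.label(),
                    "atom": c.atom_a[2],
                    "partner_atom": c.atom_b[2],
                    "distance": round(c.distance, 2),
                    "labels": sorted(c.labels, key=lambda l: -LABEL_RANK[l]),
                    "bridging_water": c.bridging_water,
                }
            )
        residue_rows.append(
            {
                "residue": key.label(),
                "solvation": iface.solvation[key],
                "chemistry": iface.chemistry[key],
                "interactions": partner_rows,
            }
        )
    return {
        "interface_id": iface.interface_id,
        "domain_id": iface.domain_id,
        "family_id": iface.family_id,
        "pdb_id": iface.pdb_id,
        "ligand_entity_id": iface.ligand_entity_id,
        "ligand_type": iface.ligand_type,
        "ligand_family_id": iface.ligand_family_id,
        "complex_class": iface.complex_class,
        "chain_class": iface.chain_class,
        "covalent": iface.covalent,
        "residues": residue_rows,
    }


def write_interface_json(
    interfaces: Sequence[Interface],
    domain_residue_order: dict[str, list[ResidueKey]],
    pdb_id: str = "",
) -> str:
    """Serialize interfaces plus the ordered residue list of each domain
    (needed later to anchor alignment columns)."""
    payload = {
        "pdb_id": pdb_id,
        "domains": {
            domain_id: [list(key) for key in keys]
            for domain_id, keys in sorted(domain_residue_order.items())
        },
        "interfaces": [
            {
                **interface_to_dict(iface),
                "residue_keys": [list(key) for key in iface.residue_set],
            }
            for iface in interfaces
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=False)
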