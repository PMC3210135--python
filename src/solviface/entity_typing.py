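"""Partition a parsed structure into typed molecular entities.

Every residue ends up in exactly one non-water entity: protein domains (from
SCOP-like definitions), peptides (undomained all-ATOM amino-acid chains
shorter than 90 residues), merged nucleic-acid units (duplexes joined by at
least one inter-base atomic interaction), oligosaccharides (sugar units
joined by covalent connectivity), waters, or the report-only categories
``unassigned_protein`` (undomained chains of 90+ residues) and ``other_het``
(unrecognized HETATM residues).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    MODIFIED_AMINO_ACIDS,
    STANDARD_AMINO_ACIDS,
    ChemistryDictionary,
    DomainDefinition,
    ResidueKey,
    SaccharideCodeList,
    Structure,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: inter-base heavy-atom distance that merges two nucleic-acid chains (the
#: van der Waals contact envelope)
BASE_CONTACT_CUTOFF = 4.5
#: heavy-atom distance treated as a covalent bond when CONECT is absent
COVALENT_CUTOFF = 1.9
#: maximum residue count of a peptide chain (chains shorter than 90 residues)
PEPTIDE_MAX_LEN = 89


class EntityType(str, Enum):
    DOMAIN = "domain"
    PEPTIDE = "peptide"
    DNA = "dna"
    RNA = "rna"
    SACCHARIDE = "saccharide"
    WATER = "water"
    UNASSIGNED_PROTEIN = "unassigned_protein"
    OTHER_HET = "other_het"


#: entity types that may act as the ligand side of an interface
LIGAND_TYPES = frozenset(
    {EntityType.DOMAIN, EntityType.PEPTIDE, EntityType.DNA, EntityType.RNA, EntityType.SACCHARIDE}
)


@dataclass
class Entity:
    """A typed molecular unit owning an ordered set of residues."""

    entity_id: str
    entity_type: EntityType
    residues: list[ResidueKey]
    family_id: str = ""
    covalent_to_protein: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"entity {self.entity_id}: empty residue list")
        if self.entity_type is EntityType.DOMAIN and not self.family_id:
            raise ValueError(f"domain entity {self.entity_id}: family_id required")

    @property
    def member_chains(self) -> frozenset[str]:
        return frozenset(key.chain_id for key in self.residues)

    @property
    def ligand_type(self) -> str:
        """Search-facing ligand-type name (domains present as 'protein')."""
        if self.entity_type is EntityType.DOMAIN:
            return "protein"
        return self.entity_type.value


@dataclass
class LigandTypeFilter:
    """Search-option filter: ligand types (conjunctive over a region),
    homo/hetero complex class, intra/inter chain class."""

    allowed: frozenset[str] = frozenset({"protein", "peptide", "dna", "rna", "saccharide"})
    complex_type: str = "any"  # any | homo | hetero
    interaction_type: str = "any"  # any | intra | inter

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("ligand-type filter: allowed set must be non-empty")
        if self.complex_type not in ("any", "homo", "hetero"):
            raise ValueError(f"bad complex_type {self.complex_type!r}")
        if self.interaction_type not in ("any", "intra", "inter"):
            raise ValueError(f"bad interaction_type {self.interaction_type!r}")


@dataclass
class EntitySet:
    """All entities of one structure plus the residue ownership index."""

    entities: list[Entity] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def of_type(self, *types: EntityType) -> list[Entity]:
        return [e for e in self.entities if e.entity_type in types]

    @property
    def waters(self) -> list[Entity]:
        return self.of_type(EntityType.WATER)

    @property
    def domains(self) -> list[Entity]:
        return self.of_type(EntityType.DOMAIN)

    @property
    def ligand_entities(self) -> list[Entity]:
        return [e for e in self.entities if e.entity_type in LIGAND_TYPES]

    def owner_of(self, key: ResidueKey) -> Entity | None:
        for entity in self.entities:
            if entity.entity_type is EntityType.WATER:
                continue
            if key in entity.residues:
                return entity
        return None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _covalently_linked(structure: Structure, atoms_a, atoms_b) -> bool:
    """True if any atom pair across the two groups is CONECT-bonded or lies
    within the covalent fallback distance."""
    for a in atoms_a:
        for b in atoms_b:
            if structure.is_bonded(a.serial, b.serial):
                return True
            if float(np.linalg.norm(a.xyz - b.xyz)) <= COVALENT_CUTOFF:
                return True
    return False


def _is_protein_residue(structure: Structure, key: ResidueKey) -> bool:
    if key.res_name in STANDARD_AMINO_ACIDS and structure.residue_kind(key) == "ATOM":
        return True
    return False


def _backbone_linked_modified(structure: Structure, key: ResidueKey, chain_keys) -> bool:
    """A modified amino acid (HETATM, e.g. MSE) counts as part of the chain
    if it is bonded into a neighboring backbone (CONECT or N-C <= 1.9 A)."""
    if key.res_name not in MODIFIED_AMINO_ACIDS:
        return False
    own = structure.residue_atoms(key)
    idx = chain_keys.index(key)
    for other_idx in (idx - 1, idx + 1):
        if 0 <= other_idx < len(chain_keys):
            other = structure.residue_atoms(chain_keys[other_idx])
            if _covalently_linked(structure, own, other):
                return True
    return False


# ---------------------------------------------------------------------------
# typing operations
# ---------------------------------------------------------------------------

def assign_domains(
    structure: Structure, domain_defs: list[DomainDefinition]
) -> tuple[list[Entity], list[str]]:
    """Build one entity per domain definition from the ATOM-record residues
    inside its segments; overlapping definitions are a hard error."""
    warnings: list[str] = []
    entities: list[Entity] = []
    owner: dict[ResidueKey, str] = {}
    chains = structure.chains
    for definition in domain_defs:
        missing = [c for c, _, _ in definition.segments if c not in chains]
        if missing:
            warnings.append(
                f"domain {definition.domain_id}: chains {sorted(set(missing))} absent, skipped"
            )
            logger.warning(warnings[-1])
            continue
        residues = []
        seen: set[ResidueKey] = set()
        for chain_id, start, end in definition.segments:
            for key in chains[chain_id]:
                if (
                    start <= key.seq_num <= end
                    and structure.residue_kind(key) == "ATOM"
                    and key not in seen
                ):
                    residues.append(key)
                    seen.add(key)
        if not residues:
            warnings.append(f"domain {definition.domain_id}: no residues found, skipped")
            logger.warning(warnings[-1])
            continue
        clashes = [key for key in residues if key in owner]
        if clashes:
            raise ValidationError(
                f"domains {owner[clashes[0]]} and {definition.domain_id} overlap on residues "
                + ", ".join(k.label() for k in clashes[:5])
            )
        for key in residues:
            owner[key] = definition.domain_id
        entities.append(
            Entity(
                entity_id=definition.domain_id,
                entity_type=EntityType.DOMAIN,
                residues=residues,
                family_id=definition.family_id,
            )
        )
    return entities, warnings


def detect_nucleic_acids(
    structure: Structure, chem: ChemistryDictionary
) -> list[Entity]:
    """Group standard-nucleotide chains and merge them into duplex units
    wherever at least one inter-base atomic interaction (base-moiety atoms
    within the vdW envelope) links two chains; type rna iff any member
    nucleotide carries an O2' atom."""
    strands: dict[str, list[ResidueKey]] = {}
    for chain_id, keys in structure.chains.items():
        nts = [k for k in keys if k.res_name in chem.nucleotide_names]
        if nts:
            strands[chain_id] = nts
    if not strands:
        return []

    def base_coords(chain_id: str) -> np.ndarray:
        pts = []
        for key in strands[chain_id]:
            base_set = chem.base_atoms.get(key.res_name, frozenset())
            for atom in structure.residue_atoms(key):
                if atom.name in base_set:
                    pts.append(atom.coords)
        return np.asarray(pts, dtype=float) if pts else np.empty((0, 3))

    graph = nx.Graph()
    graph.add_nodes_from(strands)
    chain_ids = sorted(strands)
    coords = {c: base_coords(c) for c in chain_ids}
    trees = {c: cKDTree(coords[c]) if len(coords[c]) else None for c in chain_ids}
    for i, ca in enumerate(chain_ids):
        for cb in chain_ids[i + 1 :]:
            ta, tb = trees[ca], trees[cb]
            if ta is None or tb is None:
                continue
            if any(ta.query_ball_tree(tb, r=BASE_CONTACT_CUTOFF + 1e-9)):
                graph.add_edge(ca, cb)
    entities = []
    for n, component in enumerate(
        sorted(nx.connected_components(graph), key=lambda comp: sorted(comp)[0]), start=1
    ):
        residues = [key for c in sorted(component) for key in strands[c]]
        is_rna = any(
            structure.find_atom(key, "O2'") is not None for key in residues
        )
        entities.append(
            Entity(
                entity_id=f"NA_{n}",
                entity_type=EntityType.RNA if is_rna else EntityType.DNA,
                residues=residues,
            )
        )
    return entities


def detect_peptides(
    structure: Structure,
    domain_entities: list[Entity],
    na_entities: list[Entity] | None = None,
    max_len: int = PEPTIDE_MAX_LEN,
) -> tuple[list[Entity], list[Entity]]:
    """Classify undomained all-ATOM amino-acid chains: length <= ``max_len``
    residues -> peptide; longer -> unassigned-protein (reported, never a
    ligand).  Returns (peptides, unassigned)."""
    domained: set[ResidueKey] = {k for e in domain_entities for k in e.residues}
    na_chains: set[str] = {
        k.chain_id for e in (na_entities or []) for k in e.residues
    }
    peptides: list[Entity] = []
    unassigned: list[Entity] = []
    n_pep = n_un = 0
    for chain_id in sorted(structure.chains):
        if chain_id in na_chains:
            continue
        keys = structure.chains[chain_id]
        chain_res = [
            k
            for k in keys
            if _is_protein_residue(structure, k)
            or _backbone_linked_modified(structure, k, keys)
        ]
        if not chain_res:
            continue
        if any(k in domained for k in chain_res):
            continue  # chain covered by a domain definition
        if len(chain_res) <= max_len:
            n_pep += 1
            peptides.append(
                Entity(
                    entity_id=f"PEP_{n_pep}",
                    entity_type=EntityType.PEPTIDE,
                    residues=chain_res,
                )
            )
        else:
            n_un += 1
            unassigned.append(
                Entity(
                    entity_id=f"UNP_{n_un}",
                    entity_type=EntityType.UNASSIGNED_PROTEIN,
                    residues=chain_res,
                )
            )
    return peptides, unassigned


def detect_saccharides(
    structure: Structure,
    codes: SaccharideCodeList,
    protein_entities: list[Entity] | None = None,
) -> list[Entity]:
    """Merge recognized HETATM sugar units into oligosaccharide entities via
    covalent connectivity (CONECT pairs, or heavy-atom pairs <= 1.9 A), and
    flag units covalently attached to a protein entity."""
    units = [
        key
        for key in structure.residues
        if key.res_name in codes and structure.residue_kind(key) == "HETATM"
    ]
    if not units:
        return []
    graph = nx.Graph()
    graph.add_nodes_from(units)
    for i, ka in enumerate(units):
        atoms_a = structure.residue_atoms(ka)
        for kb in units[i + 1 :]:
            if _covalently_linked(structure, atoms_a, structure.residue_atoms(kb)):
                graph.add_edge(ka, kb)
    protein_atoms = [
        atom
        for entity in (protein_entities or [])
        for key in entity.residues
        for atom in structure.residue_atoms(key)
    ]
    entities = []
    components = sorted(nx.connected_components(graph), key=lambda comp: sorted(comp)[0])
    for n, component in enumerate(components, start=1):
        residues = sorted(component)
        unit_atoms = [a for key in residues for a in structure.residue_atoms(key)]
        covalent = bool(protein_atoms) and _covalently_linked(
            structure, unit_atoms, protein_atoms
        )
        entities.append(
            Entity(
                entity_id=f"SAC_{n}",
                entity_type=EntityType.SACCHARIDE,
                residues=residues,
                covalent_to_protein=covalent,
            )
        )
    return entities


def detect_waters(
    structure: Structure, chem: ChemistryDictionary
) -> tuple[list[Entity], list[str]]:
    """One single-residue entity per water; only the oxygen atom is used."""
    waters: list[Entity] = []
    warnings: list[str] = []
    n = 0
    for key in structure.residues:
        if key.res_name not in chem.water_names:
            continue
        if structure.find_atom(key, "O") is None:
            warnings.append(f"water {key.label()}: no oxygen atom, skipped")
            logger.warning(warnings[-1])
            continue
        n += 1
        waters.append(
            Entity(entity_id=f"W_{n}", entity_type=EntityType.WATER, residues=[key])
        )
    return waters, warnings


def build_entities(
    structure: Structure,
    domain_defs: list[DomainDefinition],
    chem: ChemistryDictionary,
    sac_codes: SaccharideCodeList,
    peptide_max_len: int = PEPTIDE_MAX_LEN,
) -> EntitySet:
    """Run the full typing pipeline and enforce the partition property:
    every recognized residue lands in exactly one non-water entity, and
    unrecognized HETATM residues are reported as ``other_het``."""
    domains, warnings = assign_domains(structure, domain_defs)
    nas = detect_nucleic_acids(structure, chem)
    peptides, unassigned = detect_peptides(
        structure, domains, nas, max_len=peptide_max_len
    )
    protein_entities = domains + peptides + unassigned
    sacs = detect_saccharides(structure, sac_codes, protein_entities)
    waters, water_warnings = detect_waters(structure, chem)
    warnings.extend(water_warnings)

    assigned: set[ResidueKey] = set()
    for entity in protein_entities + nas + sacs:
        for key in entity.residues:
            if key in assigned:
                raise ValidationError(f"residue {key.label()} assigned to two entities")
            assigned.add(key)
    water_keys = {key for w in waters for key in w.residues}

    leftovers = [
        key
        for key in structure.residues
        if key not in assigned and key not in water_keys
    ]
    others: list[Entity] = []
    for n, key in enumerate(leftovers, start=1):
        others.append(
            Entity(entity_id=f"HET_{n}", entity_type=EntityType.OTHER_HET, residues=[key])
        )
        warnings.append(f"residue {key.label()}: unrecognized, reported as other_het")
    entity_set = EntitySet(
        entities=protein_entities + nas + sacs + waters + others, warnings=warnings
    )
    return entity_set


def write_entity_table(entity_set: EntitySet) -> str:
    """TSV report: one row per entity."""
    rows = ["entity_id\ttype\tfamily_id\tchains\tn_residues\tcovalent_to_protein"]
    for e in entity_set.entities:
        rows.append(
            "\t".join(
                [
                    e.entity_id,
                    e.entity_type.value,
                    e.family_id or "-",
                    ",".join(sorted(e.member_chains)),
                    str(len(e.residues)),
                    str(e.covalent_to_protein).lower(),
                ]
            )
        )
    return "\n".join(rows) + "\n"
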