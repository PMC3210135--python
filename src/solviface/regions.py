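"""Family binding regions: alignment mapping, clustering, hierarchy.

Interfaces of one family are projected onto the family's structure-based
multiple sequence alignment and clustered by interacting-residue overlap.
Similarity between two interfaces is the size of their column intersection
normalized by the smaller set, so a sub-region nested inside a larger one
scores 1.  Clustering is single linkage: interfaces whose similarity
exceeds the cutoff join the same binding region (the default cutoff of zero
merges any two interfaces sharing a single column).

The assembled hierarchy has three levels below the family list: FA (family)
-> BR (binding region) -> IF (interface group, one per distinct ligand
partner).  Alignment columns are 0-based internally and 1-based in every
written report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from io import StringIO

import networkx as nx
from Bio import SeqIO

from .contacts import Interface
from .entity_typing import LigandTypeFilter
from .structure_io import ResidueKey

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")

#: shipped clustering cutoffs selectable in search options
DEFAULT_CLUSTER_CUTOFFS = (0.0, 0.2, 0.4, 0.6)


@dataclass
class FamilyAlignment:
    """Structure-based MSA of one family with residue->column maps."""

    family_id: str
    n_columns: int
    column_map: dict[str, dict[ResidueKey, int]] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return list(self.column_map)

    def columns_of(self, member_id: str) -> dict[ResidueKey, int]:
        return self.column_map[member_id]

    def residue_of_column(self, member_id: str) -> dict[int, ResidueKey]:
        return {col: key for key, col in self.column_map[member_id].items()}


def read_alignment_fasta(fasta_text: str) -> dict[str, str]:
    """Gapped FASTA -> {member_id: gapped sequence}; ids must be domain ids."""
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(StringIO(fasta_text), "fasta")
    }
    if not records:
        raise ValueError("alignment FASTA contains no records")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    return records


def build_family_alignment(
    family_id: str,
    gapped_sequences: dict[str, str],
    residues_by_member: dict[str, list[ResidueKey]],
) -> FamilyAlignment:
    """Anchor each member's gapped row to its ordered structure residues:
    the k-th non-gap position corresponds to the k-th observed residue."""
    n_columns = len(next(iter(gapped_sequences.values())))
    column_map: dict[str, dict[ResidueKey, int]] = {}
    for member_id, row in gapped_sequences.items():
        residues = residues_by_member.get(member_id)
        if residues is None:
            logger.warning(
                "alignment %s: member %s has no structure residues, skipped",
                family_id,
                member_id,
            )
            continue
        ungapped_cols = [i for i, ch in enumerate(row) if ch not in GAP_CHARS]
        if len(ungapped_cols) != len(residues):
            logger.warning(
                "alignment %s member %s: %d alignment positions vs %d residues; "
                "mapping the first %d",
                family_id,
                member_id,
                len(ungapped_cols),
                len(residues),
                min(len(ungapped_cols), len(residues)),
            )
        column_map[member_id] = {
            key: col for key, col in zip(residues, ungapped_cols)
        }
    return FamilyAlignment(family_id=family_id, n_columns=n_columns, column_map=column_map)


# ---------------------------------------------------------------------------
# mapping and similarity
# ---------------------------------------------------------------------------

def map_interface_to_columns(
    interface: Interface, alignment: FamilyAlignment
) -> tuple[frozenset[int], int]:
    """Alignment columns of the interface residues plus the count of
    residues absent from the member's column map."""
    if interface.domain_id not in alignment.column_map:
        raise KeyError(
            f"domain {interface.domain_id} is not a member of alignment "
            f"{alignment.family_id}"
        )
    member_map = alignment.column_map[interface.domain_id]
    columns = set()
    unmapped = 0
    for key in interface.residue_set:
        col = member_map.get(key)
        if col is None:
            unmapped += 1
        else:
            columns.add(col)
    if unmapped:
        logger.info(
            "interface %s: %d residues not in alignment %s",
            interface.interface_id,
            unmapped,
            alignment.family_id,
        )
    return frozenset(columns), unmapped


def region_similarity(cols_a: frozenset[int], cols_b: frozenset[int]) -> float:
    """Interacting-residue overlap normalized by the smaller column set."""
    if not cols_a or not cols_b:
        return 0.0
    return len(cols_a & cols_b) / min(len(cols_a), len(cols_b))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class BindingRegion:
    """A cluster of one family's interfaces as alignment-column sets."""

    region_id: str
    family_id: str
    column_set: frozenset[int]
    interface_ids: list[str]
    origin: str = "observed"  # observed | predicted
    cutoff_used: float = 0.0
    # predicted-region provenance (empty for observed regions)
    source_region_id: str = ""
    source_family_id: str = ""
    coverage: float = 0.0
    predicted_interfaces: list[tuple[str, str]] = field(default_factory=list)


def cluster_regions(
    interfaces: list[Interface],
    alignment: FamilyAlignment,
    cutoff: float = 0.0,
    id_start: int = 1,
) -> tuple[list[BindingRegion], list[str]]:
    """Single-linkage clustering of one family's interfaces.

    Interfaces are nodes; an edge joins two interfaces whose column-set
    similarity is strictly greater than the cutoff; binding regions are the
    connected components.  Interfaces whose domain is missing from the
    alignment are excluded and reported.  Region ids are assigned in order
    of each component's smallest interface id.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"clustering cutoff must be in [0, 1], got {cutoff}")
    usable: list[tuple[Interface, frozenset[int]]] = []
    excluded: list[str] = []
    for iface in sorted(interfaces, key=lambda i: i.interface_id):
        if iface.domain_id not in alignment.column_map:
            excluded.append(iface.interface_id)
            logger.warning(
                "interface %s excluded: domain %s not in alignment %s",
                iface.interface_id,
                iface.domain_id,
                alignment.family_id,
            )
            continue
        cols, _ = map_interface_to_columns(iface, alignment)
        usable.append((iface, cols))
    graph = nx.Graph()
    graph.add_nodes_from(iface.interface_id for iface, _ in usable)
    for i, (iface_a, cols_a) in enumerate(usable):
        for iface_b, cols_b in usable[i + 1 :]:
            if region_similarity(cols_a, cols_b) > cutoff:
                graph.add_edge(iface_a.interface_id, iface_b.interface_id)
    cols_by_id = {iface.interface_id: cols for iface, cols in usable}
    components = sorted(nx.connected_components(graph), key=lambda comp: sorted(comp)[0])
    regions = []
    for n, component in enumerate(components, start=id_start):
        members = sorted(component)
        column_set = frozenset().union(*(cols_by_id[m] for m in members))
        regions.append(
            BindingRegion(
                region_id=f"BR_{n}",
                family_id=alignment.family_id,
                column_set=column_set,
                interface_ids=members,
                origin="observed",
                cutoff_used=cutoff,
            )
        )
    return regions, excluded


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

def _interface_group_key(iface: Interface) -> str:
    """IF-level grouping: partner family for protein ligands, else the
    ligand type."""
    if iface.ligand_type == "protein" and iface.ligand_family_id:
        return iface.ligand_family_id
    return iface.ligand_type


def assemble_hierarchy(
    regions_by_family: dict[str, list[BindingRegion]],
    interfaces: list[Interface],
) -> dict:
    """Nest regions and interfaces into the FA -> BR -> IF hierarchy with a
    stable, deterministic ordering (columns reported 1-based)."""
    by_id = {iface.interface_id: iface for iface in interfaces}
    families = []
    for family_id in sorted(regions_by_family):
        region_records = []
        for region in sorted(regions_by_family[family_id], key=lambda r: r.region_id):
            groups: dict[str, list[dict]] = {}
            for iface_id in region.interface_ids:
                iface = by_id.get(iface_id)
                if iface is None:
                    continue
                member = {
                    "interface_id": iface.interface_id,
                    "domain_id": iface.domain_id,
                    "pdb_id": iface.pdb_id,
                    "ligand_entity_id": iface.ligand_entity_id,
                    "ligand_type": iface.ligand_type,
                    "ligand_family_id": iface.ligand_family_id,
                    "complex_class": iface.complex_class,
                    "chain_class": iface.chain_class,
                    "covalent": iface.covalent,
                    "n_residues": len(iface.residue_set),
                }
                groups.setdefault(_interface_group_key(iface), []).append(member)
            record = {
                "region_id": region.region_id,
                "origin": region.origin,
                "cutoff": region.cutoff_used,
                "columns": sorted(c + 1 for c in region.column_set),
                "ligand_types": sorted(
                    {
                        m["ligand_type"]
                        for members in groups.values()
                        for m in members
                    }
                    | {lt for _, lt in region.predicted_interfaces}
                ),
                "interface_groups": [
                    {"group": key, "members": sorted(groups[key], key=lambda m: m["interface_id"])}
                    for key in sorted(groups)
                ],
            }
            if region.origin == "predicted":
                record["source_region_id"] = region.source_region_id
                record["source_family_id"] = region.source_family_id
                record["coverage"] = round(region.coverage, 4)
                record["predicted_interfaces"] = [
                    {"source_interface_id": sid, "ligand_type": lt}
                    for sid, lt in region.predicted_interfaces
                ]
            region_records.append(record)
        families.append({"family_id": family_id, "regions": region_records})
    return {"families": families}


def apply_search_filters(
    hierarchy: dict,
    search_filter: LigandTypeFilter,
    include_covalent: bool = False,
) -> dict:
    """Apply the search options to a hierarchy.

    When several ligand types are selected the filter is conjunctive: a
    region survives only if its interfaces cover every selected type (the
    same surface region recognizes them all).  Complex-type and
    interaction-type filters drop individual non-matching interfaces, then
    regions and families left empty.  Covalently attached ligands are
    excluded unless opted in.
    """
    all_types = {"protein", "peptide", "dna", "rna", "saccharide"}
    selected = set(search_filter.allowed)
    conjunctive = selected != all_types
    families = []
    for family in hierarchy["families"]:
        regions = []
        for region in family["regions"]:
            new_groups = []
            present_types: set[str] = set()
            for group in region["interface_groups"]:
                members = []
                for m in group["members"]:
                    if m["covalent"] and not include_covalent:
                        continue
                    if m["ligand_type"] not in selected:
                        continue
                    if (
                        search_filter.complex_type != "any"
                        and m["complex_class"] != search_filter.complex_type
                    ):
                        continue
                    if (
                        search_filter.interaction_type != "any"
                        and m["chain_class"] != search_filter.interaction_type
                    ):
                        continue
                    members.append(m)
                    present_types.add(m["ligand_type"])
                if members:
                    new_groups.append({"group": group["group"], "members": members})
            if region["origin"] == "predicted":
                predicted_types = {
                    p["ligand_type"] for p in region.get("predicted_interfaces", [])
                }
                present_types |= predicted_types & selected
            if not new_groups and region["origin"] != "predicted":
                continue
            if conjunctive and not selected <= present_types:
                continue
            new_region = dict(region)
            new_region["interface_groups"] = new_groups
            new_region["ligand_types"] = sorted(present_types)
            regions.append(new_region)
        if regions:
            families.append({"family_id": family["family_id"], "regions": regions})
    return {"families": families}


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_hierarchy_json(hierarchy: dict) -> str:
    return json.dumps(hierarchy, indent=1, sort_keys=False)


def write_hierarchy_tsv(hierarchy: dict) -> str:
    """Flat listing: one row per interface with its region id."""
    rows = [
        "family_id\tregion_id\torigin\tcutoff\tinterface_id\tdomain_id\tpdb_id\t"
        "ligand_type\tligand_family_id\tcomplex_class\tchain_class\tn_residues"
    ]
    for family in hierarchy["families"]:
        for region in family["regions"]:
            for group in region["interface_groups"]:
                for m in group["members"]:
                    rows.append(
                        "\t".join(
                            [
                                family["family_id"],
                                region["region_id"],
                                region["origin"],
                                f"{region['cutoff']:g}",
                                m["interface_id"],
                                m["domain_id"],
                                m["pdb_id"] or "-",
                                m["ligand_type"],
                                m["ligand_family_id"] or "-",
                                m["complex_class"],
                                m["chain_class"],
                                str(m["n_residues"]),
                            ]
                        )
                    )
            if region["origin"] == "predicted" and not region["interface_groups"]:
                rows.append(
                    "\t".join(
                        [
                            family["family_id"],
                            region["region_id"],
                            "predicted",
                            f"{region['cutoff']:g}",
                            "-",
                            "-",
                            "-",
                            ",".join(region["ligand_types"]) or "-",
                            region.get("source_family_id", "-"),
                            "-",
                            "-",
                            str(len(region["columns"])),
                        ]
                    )
                )
    return "\n".join(rows) + "\n"
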