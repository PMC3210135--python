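"""End-to-end orchestration: scan structures, classify regions, infer.

This module owns the file-level plumbing between the analysis stages so the
command-line layer stays thin: reading the configuration tables, running
entity typing and interface detection over a set of PDB files with globally
unique interface ids, rebuilding interfaces from their JSON serialization,
clustering per family at one or more cutoffs, and running the cross-family
transfer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import contacts as _contacts
from . import entity_typing as _entities
from . import inference as _inference
from . import regions as _regions
from .contacts import Cutoffs, Interface
from .entity_typing import EntitySet, LigandTypeFilter
from .regions import DEFAULT_CLUSTER_CUTOFFS, BindingRegion, FamilyAlignment
from .structure_io import (
    ChemistryDictionary,
    ResidueKey,
    SaccharideCodeList,
    load_domain_definitions,
    parse_structure,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every numeric parameter of the pipeline in one place."""

    hbond_cutoff: float = 3.6
    salt_cutoff: float = 4.0
    vdw_cutoff: float = 4.5
    covalent_cutoff: float = 1.9
    peptide_max_len: int = 89
    cluster_cutoffs: tuple[float, ...] = DEFAULT_CLUSTER_CUTOFFS
    inference_threshold: float = 0.5
    dedup_cutoff: float = 0.0
    packing_mode: str = "off"  # off | hook | naive
    packing_probability_cutoff: float = 0.70
    ligand_filter: LigandTypeFilter = field(default_factory=LigandTypeFilter)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hbond_cutoff", "salt_cutoff", "vdw_cutoff", "covalent_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peptide_max_len < 1:
            raise ValueError("peptide_max_len must be >= 1")
        if not 0.0 < self.inference_threshold <= 1.0:
            raise ValueError("inference threshold must be in (0, 1]")
        if self.packing_mode not in ("off", "hook", "naive"):
            raise ValueError(f"bad packing mode {self.packing_mode!r}")

    @property
    def cutoffs(self) -> Cutoffs:
        return Cutoffs(
            hbond=self.hbond_cutoff,
            salt_bridge=self.salt_cutoff,
            vdw=self.vdw_cutoff,
            covalent=self.covalent_cutoff,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key-value text (one ``key = value`` per line) overriding
        defaults."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key == "cluster_cutoffs":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("peptide_max_len", "seed"):
                kwargs[key] = int(value)
            elif key == "packing_mode":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


def load_tables(
    domains_path: str | Path,
    chemistry_path: str | Path | None = None,
    saccharides_path: str | Path | None = None,
):
    """Load domain definitions plus the chemistry dictionary and saccharide
    list (shipped defaults unless overridden); sugar codes are registered
    with the dictionary so their O/N atoms act as donors/acceptors."""
    defs = load_domain_definitions(Path(domains_path).read_text())
    chem = (
        ChemistryDictionary.from_text(Path(chemistry_path).read_text())
        if chemistry_path
        else ChemistryDictionary.default()
    )
    sac = (
        SaccharideCodeList.from_text(Path(saccharides_path).read_text())
        if saccharides_path
        else SaccharideCodeList.default()
    )
    chem.register_generic_polar(sac.codes)
    return defs, chem, sac


@dataclass
class ScanResult:
    pdb_id: str
    entity_set: EntitySet
    interfaces: list[Interface]
    domain_residue_order: dict[str, list[ResidueKey]]


def scan_files(
    pdb_paths: list[str | Path],
    domain_defs,
    chem: ChemistryDictionary,
    sac: SaccharideCodeList,
    config: RunConfig = RunConfig(),
    packing_hook=None,
) -> list[ScanResult]:
    """Scan each structure: entity typing, interface detection, optional
    crystal-packing filtering.  Interface ids are unique across the run;
    unreadable files are reported and skipped."""
    results: list[ScanResult] = []
    next_id = 1
    for path in sorted(Path(p) for p in pdb_paths):
        pdb_id = path.stem
        try:
            structure = parse_structure(path.read_text(), source=str(path))
        except Exception as exc:
            logger.error("%s: %s", path, exc)
            continue
        defs_here = [d for d in domain_defs if d.pdb_id == pdb_id] or domain_defs
        entity_set = _entities.build_entities(
            structure, defs_here, chem, sac, peptide_max_len=config.peptide_max_len
        )
        interfaces = _contacts.scan_structure(
            structure,
            entity_set,
            chem,
            config.cutoffs,
            pdb_id=pdb_id,
            id_start=next_id,
        )
        if config.packing_mode == "hook":
            interfaces = _contacts.filter_crystal_packing(
                interfaces,
                classifier_hook=packing_hook,
                probability_cutoff=config.packing_probability_cutoff,
            )
        elif config.packing_mode == "naive":
            interfaces = _contacts.filter_crystal_packing(
                interfaces, naive_heuristic=True
            )
        next_id += len(interfaces)
        order = {
            e.entity_id: list(e.residues) for e in entity_set.domains
        }
        results.append(
            ScanResult(
                pdb_id=pdb_id,
                entity_set=entity_set,
                interfaces=interfaces,
                domain_residue_order=order,
            )
        )
    return results


# ---------------------------------------------------------------------------
# interface JSON round trip
# ---------------------------------------------------------------------------

def interfaces_from_json(text: str) -> tuple[list[Interface], dict[str, list[ResidueKey]]]:
    """Rebuild interfaces (residue sets and classification; atomic contact
    lists are not round-tripped) plus domain residue orders."""
    payload = json.loads(text)
    orders = {
        domain_id: [ResidueKey(*key) for key in keys]
        for domain_id, keys in payload["domains"].items()
    }
    interfaces = []
    for rec in payload["interfaces"]:
        residue_keys = [ResidueKey(*key) for key in rec["residue_keys"]]
        solvation = {}
        chemistry = {}
        for key, row in zip(residue_keys, rec["residues"]):
            solvation[key] = row["solvation"]
            chemistry[key] = row["chemistry"]
        interfaces.append(
            Interface(
                interface_id=rec["interface_id"],
                domain_id=rec["domain_id"],
                family_id=rec["family_id"],
                ligand_entity_id=rec["ligand_entity_id"],
                ligand_type=rec["ligand_type"],
                ligand_family_id=rec["ligand_family_id"],
                residue_set=residue_keys,
                solvation=solvation,
                chemistry=chemistry,
                complex_class=rec["complex_class"],
                chain_class=rec["chain_class"],
                covalent=rec["covalent"],
                contacts=[],
                pdb_id=rec.get("pdb_id", ""),
            )
        )
    return interfaces, orders


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def load_alignments(
    alignments_dir: str | Path,
    residues_by_member: dict[str, list[ResidueKey]],
    family_of_member: dict[str, str],
) -> dict[str, FamilyAlignment]:
    """Read every ``<family>.fasta`` in the directory and anchor members
    with known structure residues."""
    alignments = {}
    for path in sorted(Path(alignments_dir).glob("*.fasta")):
        family_id = path.stem
        gapped = _regions.read_alignment_fasta(path.read_text())
        alignments[family_id] = _regions.build_family_alignment(
            family_id, gapped, residues_by_member
        )
    return alignments


def classify(
    interfaces: list[Interface],
    alignments: dict[str, FamilyAlignment],
    cutoff: float = 0.0,
    include_covalent: bool = False,
) -> tuple[dict[str, list[BindingRegion]], dict, list[str]]:
    """Cluster observed interfaces per family at one cutoff and assemble
    the hierarchy.  Covalently attached ligands are excluded by default.
    Returns (regions per family, hierarchy, excluded interface ids)."""
    usable = [i for i in interfaces if include_covalent or not i.covalent]
    by_family: dict[str, list[Interface]] = {}
    for iface in usable:
        by_family.setdefault(iface.family_id, []).append(iface)
    missing = sorted(set(by_family) - set(alignments))
    if missing:
        raise ValueError(f"no alignment for families: {missing}")
    regions_by_family: dict[str, list[BindingRegion]] = {}
    excluded_all: list[str] = []
    next_region = 1
    for family_id in sorted(by_family):
        regions, excluded = _regions.cluster_regions(
            by_family[family_id],
            alignments[family_id],
            cutoff=cutoff,
            id_start=next_region,
        )
        next_region += len(regions)
        regions_by_family[family_id] = regions
        excluded_all.extend(excluded)
    hierarchy = _regions.assemble_hierarchy(regions_by_family, usable)
    return regions_by_family, hierarchy, excluded_all


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def regions_from_hierarchy(hierarchy: dict) -> dict[str, list[BindingRegion]]:
    """Reconstruct per-family region objects (columns back to 0-based)."""
    out: dict[str, list[BindingRegion]] = {}
    for family in hierarchy["families"]:
        for rec in family["regions"]:
            interface_ids = [
                m["interface_id"]
                for group in rec["interface_groups"]
                for m in group["members"]
            ]
            out.setdefault(family["family_id"], []).append(
                BindingRegion(
                    region_id=rec["region_id"],
                    family_id=family["family_id"],
                    column_set=frozenset(c - 1 for c in rec["columns"]),
                    interface_ids=interface_ids,
                    origin=rec["origin"],
                    cutoff_used=rec["cutoff"],
                    source_region_id=rec.get("source_region_id", ""),
                    source_family_id=rec.get("source_family_id", ""),
                    coverage=rec.get("coverage", 0.0),
                    predicted_interfaces=[
                        (p["source_interface_id"], p["ligand_type"])
                        for p in rec.get("predicted_interfaces", [])
                    ],
                )
            )
    return out


def ligands_by_region(hierarchy: dict) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    for family in hierarchy["families"]:
        for rec in family["regions"]:
            pairs = [
                (m["interface_id"], m["ligand_type"])
                for group in rec["interface_groups"]
                for m in group["members"]
            ]
            out[rec["region_id"]] = pairs
    return out


def infer(
    hierarchy: dict,
    correspondences,
    alignments: dict[str, FamilyAlignment],
    threshold: float = 0.5,
    dedup_cutoff: float = 0.0,
) -> dict:
    """Append predicted regions to a hierarchy of observed regions."""
    observed = {
        fam: [r for r in regs if r.origin == "observed"]
        for fam, regs in regions_from_hierarchy(hierarchy).items()
    }
    predicted = _inference.infer_predicted_regions(
        observed,
        ligands_by_region(hierarchy),
        correspondences,
        alignments,
        threshold=threshold,
        dedup_cutoff=dedup_cutoff,
    )
    merged: dict[str, list[BindingRegion]] = {
        fam: list(regs) for fam, regs in observed.items()
    }
    for fam, preds in predicted.items():
        merged.setdefault(fam, []).extend(preds)
    all_ifaces_stub: list[Interface] = []
    hierarchy_out = _regions.assemble_hierarchy(merged, all_ifaces_stub)
    # re-attach the observed interface members from the input hierarchy
    members_by_region = {
        rec["region_id"]: rec["interface_groups"]
        for family in hierarchy["families"]
        for rec in family["regions"]
    }
    for family in hierarchy_out["families"]:
        for rec in family["regions"]:
            if rec["region_id"] in members_by_region:
                rec["interface_groups"] = members_by_region[rec["region_id"]]
                rec["ligand_types"] = sorted(
                    {
                        m["ligand_type"]
                        for group in rec["interface_groups"]
                        for m in group["members"]
                    }
                )
    return hierarchy_out
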