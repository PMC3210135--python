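"""Cross-family transfer of binding regions.

A non-sequential structural alignment between a member of a source family
and a member of a target family gives a one-to-one residue correspondence.
When an observed binding region of the source family is sufficiently
conserved in that correspondence (coverage, the fraction of the region's
residues with a counterpart, reaches the threshold), the region is
transferred: its residues are mapped through the correspondence, projected
onto the target family's alignment, and emitted as a predicted binding
region that inherits the source ligands as predicted interfaces.  No
coordinates are modeled for the inferred complex — predictions carry
ligand identity and binding-mode provenance only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import networkx as nx
import pandas as pd

from .regions import BindingRegion, FamilyAlignment, region_similarity
from .structure_io import ResidueKey, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class CorrespondenceMap:
    """One-to-one residue pairing between members of two families."""

    family_a: str
    family_b: str
    member_a: str
    member_b: str
    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValidationError(
                f"correspondence {self.member_a}~{self.member_b}: pairs are not one-to-one"
            )

    def forward(self) -> dict[ResidueKey, ResidueKey]:
        return dict(self.pairs)


_CORR_COLUMNS = [
    "family_a",
    "member_a",
    "chain_a",
    "seq_a",
    "icode_a",
    "resname_a",
    "family_b",
    "member_b",
    "chain_b",
    "seq_b",
    "icode_b",
    "resname_b",
]


def read_correspondences(table_text: str) -> list[CorrespondenceMap]:
    """Parse the tab-separated correspondence table into maps grouped by
    (family_a, member_a, family_b, member_b)."""
    df = pd.read_csv(StringIO(table_text), sep="\t", dtype=str, comment="#").fillna("")
    missing = [c for c in _CORR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"correspondence table missing columns: {missing}")
    maps = []
    group_cols = ["family_a", "member_a", "family_b", "member_b"]
    for (fam_a, mem_a, fam_b, mem_b), grp in df.groupby(group_cols, sort=True):
        pairs = tuple(
            (
                ResidueKey(r["chain_a"], int(r["seq_a"]), r["icode_a"], r["resname_a"]),
                ResidueKey(r["chain_b"], int(r["seq_b"]), r["icode_b"], r["resname_b"]),
            )
            for _, r in grp.iterrows()
        )
        maps.append(
            CorrespondenceMap(
                family_a=fam_a,
                family_b=fam_b,
                member_a=mem_a,
                member_b=mem_b,
                pairs=pairs,
                source_tag=str(grp.iloc[0].get("source_tag", "")),
            )
        )
    return maps


def write_correspondences(maps: list[CorrespondenceMap]) -> str:
    rows = ["\t".join(_CORR_COLUMNS)]
    for corr in maps:
        for a, b in corr.pairs:
            rows.append(
                "\t".join(
                    [
                        corr.family_a,
                        corr.member_a,
                        a.chain_id,
                        str(a.seq_num),
                        a.insertion_code,
                        a.res_name,
                        corr.family_b,
                        corr.member_b,
                        b.chain_id,
                        str(b.seq_num),
                        b.insertion_code,
                        b.res_name,
                    ]
                )
            )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------

def transfer_region(
    source_region: BindingRegion,
    corr: CorrespondenceMap,
    source_alignment: FamilyAlignment,
    target_alignment: FamilyAlignment,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    region_id: str = "BR_P1",
    predicted_interfaces: list[tuple[str, str]] | None = None,
) -> BindingRegion | None:
    """Transfer one observed region through a correspondence map.

    The region's columns are realized as residues of the correspondence's
    source member, mapped through the residue pairs, and projected onto the
    target alignment.  Coverage is the mapped fraction; the prediction is
    emitted only when coverage reaches the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"coverage threshold must be in (0, 1], got {threshold}")
    if source_region.family_id != corr.family_a:
        raise ValidationError(
            f"region {source_region.region_id} belongs to {source_region.family_id}, "
            f"correspondence maps {corr.family_a}"
        )
    if corr.member_b not in target_alignment.column_map:
        raise ValidationError(
            f"correspondence member {corr.member_b} is not in alignment "
            f"{target_alignment.family_id}"
        )
    if not source_region.column_set:
        raise ValidationError(f"region {source_region.region_id} is empty")
    if corr.member_a not in source_alignment.column_map:
        raise ValidationError(
            f"correspondence member {corr.member_a} is not in alignment "
            f"{source_alignment.family_id}"
        )
    col_to_res = source_alignment.residue_of_column(corr.member_a)
    source_residues = [
        col_to_res[col] for col in sorted(source_region.column_set) if col in col_to_res
    ]
    if not source_residues:
        return None
    forward = corr.forward()
    target_map = target_alignment.column_map[corr.member_b]
    target_columns = set()
    mapped = 0
    for res in source_residues:
        counterpart = forward.get(res)
        if counterpart is None:
            continue
        col = target_map.get(counterpart)
        if col is None:
            continue
        mapped += 1
        target_columns.add(col)
    coverage = mapped / len(source_residues)
    if coverage < threshold:
        return None
    return BindingRegion(
        region_id=region_id,
        family_id=corr.family_b,
        column_set=frozenset(target_columns),
        interface_ids=[],
        origin="predicted",
        cutoff_used=source_region.cutoff_used,
        source_region_id=source_region.region_id,
        source_family_id=source_region.family_id,
        coverage=coverage,
        predicted_interfaces=list(predicted_interfaces or []),
    )


def deduplicate_predictions(
    predictions: list[BindingRegion], cutoff: float = 0.0
) -> list[BindingRegion]:
    """Merge predictions on one target family whose column sets overlap
    (similarity strictly greater than the cutoff), retaining all source
    provenance records."""
    families = {p.family_id for p in predictions}
    if len(families) > 1:
        raise ValidationError(f"predictions span several families: {sorted(families)}")
    preds = sorted(predictions, key=lambda p: p.region_id)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(preds)))
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            if region_similarity(preds[i].column_set, preds[j].column_set) > cutoff:
                graph.add_edge(i, j)
    merged = []
    for component in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        members = [preds[i] for i in sorted(component)]
        head = members[0]
        if len(members) == 1:
            merged.append(head)
            continue
        merged.append(
            BindingRegion(
                region_id=head.region_id,
                family_id=head.family_id,
                column_set=frozenset().union(*(m.column_set for m in members)),
                interface_ids=[],
                origin="predicted",
                cutoff_used=head.cutoff_used,
                source_region_id=";".join(m.source_region_id for m in members),
                source_family_id=";".join(
                    dict.fromkeys(m.source_family_id for m in members)
                ),
                coverage=max(m.coverage for m in members),
                predicted_interfaces=[
                    p for m in members for p in m.predicted_interfaces
                ],
            )
        )
    return merged


def split_corroborating(
    predictions: list[BindingRegion],
    observed_regions: list[BindingRegion],
    cutoff: float = 0.0,
) -> tuple[list[BindingRegion], list[BindingRegion]]:
    """Partition predictions into (novel, corroborating): a prediction that
    overlaps an observed region of the target family corroborates it rather
    than introducing a new region."""
    novel, corroborating = [], []
    for pred in predictions:
        overlapping = [
            obs
            for obs in observed_regions
            if obs.family_id == pred.family_id
            and region_similarity(pred.column_set, obs.column_set) > cutoff
        ]
        (corroborating if overlapping else novel).append(pred)
    return novel, corroborating


def infer_predicted_regions(
    observed_by_family: dict[str, list[BindingRegion]],
    interfaces_by_region: dict[str, list[tuple[str, str]]],
    correspondences: list[CorrespondenceMap],
    alignments: dict[str, FamilyAlignment],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    dedup_cutoff: float = 0.0,
) -> dict[str, list[BindingRegion]]:
    """Run every observed region through every applicable correspondence
    map and collect deduplicated, novel predictions per target family.

    ``interfaces_by_region`` supplies the (interface id, ligand type) pairs
    each observed region recognizes; predictions inherit them.
    """
    raw_by_target: dict[str, list[BindingRegion]] = {}
    counter = 0
    for corr in sorted(
        correspondences, key=lambda c: (c.family_a, c.member_a, c.family_b, c.member_b)
    ):
        src_aln = alignments.get(corr.family_a)
        tgt_aln = alignments.get(corr.family_b)
        if src_aln is None or tgt_aln is None:
            logger.warning(
                "correspondence %s~%s references unknown family, skipped",
                corr.family_a,
                corr.family_b,
            )
            continue
        for region in observed_by_family.get(corr.family_a, []):
            counter += 1
            pred = transfer_region(
                region,
                corr,
                src_aln,
                tgt_aln,
                threshold=threshold,
                region_id=f"BR_P{counter}",
                predicted_interfaces=interfaces_by_region.get(region.region_id, []),
            )
            if pred is not None:
                raw_by_target.setdefault(corr.family_b, []).append(pred)
    result: dict[str, list[BindingRegion]] = {}
    for family_id in sorted(raw_by_target):
        deduped = deduplicate_predictions(raw_by_target[family_id], cutoff=dedup_cutoff)
        novel, corroborating = split_corroborating(
            deduped, observed_by_family.get(family_id, []), cutoff=dedup_cutoff
        )
        if corroborating:
            logger.info(
                "family %s: %d predictions corroborate observed regions",
                family_id,
                len(corroborating),
            )
        if novel:
            result[family_id] = novel
    return result


def families_with_only_predictions(hierarchy: dict) -> list[str]:
    """Families that present predicted binding regions but no observed ones
    (no binding information available in any structure)."""
    out = []
    for family in hierarchy["families"]:
        origins = {region["origin"] for region in family["regions"]}
        if origins and origins == {"predicted"}:
            out.append(family["family_id"])
    return sorted(out)
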