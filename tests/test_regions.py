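"""Alignment mapping, region similarity, clustering, hierarchy, filters."""

import json
import random

import pytest

from solviface.contacts import Interface
from solviface.entity_typing import LigandTypeFilter
from solviface.regions import (
    FamilyAlignment,
    apply_search_filters,
    assemble_hierarchy,
    build_family_alignment,
    cluster_regions,
    map_interface_to_columns,
    read_alignment_fasta,
    region_similarity,
    write_hierarchy_json,
)
from solviface.structure_io import ResidueKey


def _iface(iface_id, domain_id, residues, ligand_type="protein", family="famX",
           ligand_family="famY", complex_class="hetero", chain_class="inter",
           covalent=False):
    keys = [ResidueKey("A", i, "", "ALA") for i in residues]
    return Interface(
        interface_id=iface_id,
        domain_id=domain_id,
        family_id=family,
        ligand_entity_id=f"L_{iface_id}",
        ligand_type=ligand_type,
        ligand_family_id=ligand_family,
        residue_set=keys,
        solvation={k: "dry" for k in keys},
        chemistry={k: "hydrophilic" for k in keys},
        complex_class=complex_class,
        chain_class=chain_class,
        covalent=covalent,
        contacts=[],
    )


def _alignment(members_cols, family="famX", n_columns=40):
    """members_cols: {domain_id: {seq_num: column}}"""
    column_map = {
        member: {ResidueKey("A", seq, "", "ALA"): col for seq, col in mapping.items()}
        for member, mapping in members_cols.items()
    }
    return FamilyAlignment(family_id=family, n_columns=n_columns, column_map=column_map)


class TestRegionSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3}, {2, 3, 4}, 2 / 3),
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            (set(), {1}, 0.0),
            (set(), set(), 0.0),
            ({1, 2, 3, 4, 5}, {4, 5}, 1.0),  # nested sub-region scores 1
        ],
    )
    def test_overlap_over_smaller_set(self, a, b, expected):
        assert region_similarity(frozenset(a), frozenset(b)) == pytest.approx(expected)
        assert region_similarity(frozenset(b), frozenset(a)) == pytest.approx(expected)


class TestColumnMapping:
    def test_direct_lookup(self):
        aln = _alignment({"d1": {10: 4, 12: 7}})
        cols, unmapped = map_interface_to_columns(_iface("IF_1", "d1", [10, 12]), aln)
        assert cols == frozenset({4, 7})
        assert unmapped == 0

    def test_unmapped_residue_counted(self):
        aln = _alignment({"d1": {10: 4}})
        cols, unmapped = map_interface_to_columns(_iface("IF_1", "d1", [10, 12]), aln)
        assert cols == frozenset({4})
        assert unmapped == 1

    def test_empty_residue_set(self):
        aln = _alignment({"d1": {10: 4}})
        cols, unmapped = map_interface_to_columns(_iface("IF_1", "d1", []), aln)
        assert cols == frozenset()

    def test_unknown_member_raises(self):
        aln = _alignment({"d1": {10: 4}})
        with pytest.raises(KeyError, match="d2.*famX"):
            map_interface_to_columns(_iface("IF_1", "d2", [10]), aln)


class TestAlignmentReader:
    def test_gapped_fasta_column_anchoring(self):
        gapped = read_alignment_fasta(">d1\nGAK-D\n>d2\n-AKSD\n")
        residues = {
            "d1": [ResidueKey("A", i, "", "ALA") for i in (1, 2, 3, 4)],
            "d2": [ResidueKey("A", i, "", "ALA") for i in (1, 2, 3, 4)],
        }
        aln = build_family_alignment("famX", gapped, residues)
        assert aln.n_columns == 5
        assert [aln.column_map["d1"][k] for k in residues["d1"]] == [0, 1, 2, 4]
        assert [aln.column_map["d2"][k] for k in residues["d2"]] == [1, 2, 3, 4]

    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            read_alignment_fasta(">d1\nGAKD\n>d2\nGA\n")


class TestClusterRegions:
    def test_similarity_graph_components(self):
        # sims: (i1,i2)=0.5, (i1,i3)=0, (i2,i3)=0
        aln = _alignment({"d1": {i: i for i in range(1, 30)}})
        ifaces = [
            _iface("IF_1", "d1", [1, 2]),
            _iface("IF_2", "d1", [2, 3]),
            _iface("IF_3", "d1", [9]),
        ]
        regions, excluded = cluster_regions(ifaces, aln, cutoff=0.0)
        assert len(regions) == 2 and not excluded
        regions, _ = cluster_regions(ifaces, aln, cutoff=0.6)
        assert len(regions) == 3

    def test_identical_interfaces_always_merge_below_one(self):
        aln = _alignment({"d1": {i: i for i in range(1, 10)}})
        ifaces = [_iface("IF_1", "d1", [1, 2, 3]), _iface("IF_2", "d1", [1, 2, 3])]
        for cutoff in (0.0, 0.5, 0.99):
            regions, _ = cluster_regions(ifaces, aln, cutoff=cutoff)
            assert len(regions) == 1
        regions, _ = cluster_regions(ifaces, aln, cutoff=1.0)
        assert len(regions) == 2  # similarity can never exceed 1

    def test_missing_member_excluded_and_reported(self):
        aln = _alignment({"d1": {1: 1}})
        ifaces = [_iface("IF_1", "d1", [1]), _iface("IF_2", "d_missing", [1])]
        regions, excluded = cluster_regions(ifaces, aln, cutoff=0.0)
        assert excluded == ["IF_2"]
        in_regions = [i for r in regions for i in r.interface_ids]
        assert sorted(in_regions + excluded) == ["IF_1", "IF_2"]

    def test_matches_transitive_closure_oracle(self):
        rng = random.Random(5)
        aln = _alignment({"d1": {i: i for i in range(1, 26)}})
        for _ in range(20):
            n = rng.randint(2, 12)
            ifaces = [
                _iface(f"IF_{i:02d}", "d1", sorted(rng.sample(range(1, 26), rng.randint(1, 6))))
                for i in range(n)
            ]
            cutoff = rng.choice([0.0, 0.2, 0.5, 0.8])
            regions, _ = cluster_regions(ifaces, aln, cutoff=cutoff)
            got = sorted(frozenset(r.interface_ids) for r in regions)

            # oracle: boolean similarity matrix + explicit transitive closure
            cols = [frozenset(k.seq_num for k in i.residue_set) for i in ifaces]
            adj = [
                [region_similarity(cols[i], cols[j]) > cutoff for j in range(n)]
                for i in range(n)
            ]
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        adj[i][j] = adj[i][j] or (adj[i][k] and adj[k][j])
            seen, oracle = set(), []
            for i in range(n):
                if i in seen:
                    continue
                comp = {j for j in range(n) if adj[i][j]} | {i}
                seen |= comp
                oracle.append(frozenset(ifaces[j].interface_id for j in comp))
            assert got == sorted(oracle)

    def test_region_count_monotone_in_cutoff(self):
        rng = random.Random(9)
        aln = _alignment({"d1": {i: i for i in range(1, 26)}})
        ifaces = [
            _iface(f"IF_{i:02d}", "d1", sorted(rng.sample(range(1, 26), 5)))
            for i in range(8)
        ]
        counts = [
            len(cluster_regions(ifaces, aln, cutoff=c)[0]) for c in (0, 0.2, 0.4, 0.6, 1.0)
        ]
        assert counts == sorted(counts)
        assert counts[-1] == len(ifaces)

    def test_region_columns_are_union_of_members(self):
        aln = _alignment({"d1": {i: i + 10 for i in range(1, 10)}})
        ifaces = [_iface("IF_1", "d1", [1, 2]), _iface("IF_2", "d1", [2, 5])]
        regions, _ = cluster_regions(ifaces, aln, cutoff=0.0)
        assert regions[0].column_set == frozenset({11, 12, 15})


class TestHierarchy:
    def _small_hierarchy(self):
        aln = _alignment({"d1": {i: i for i in range(1, 20)}})
        ifaces = [
            _iface("IF_1", "d1", [1, 2, 3], ligand_type="dna", ligand_family=""),
            _iface("IF_2", "d1", [2, 3, 4], ligand_type="protein", ligand_family="famZ"),
        ]
        regions, _ = cluster_regions(ifaces, aln, cutoff=0.0)
        return assemble_hierarchy({"famX": regions}, ifaces), ifaces

    def test_region_with_two_ligand_types_has_two_if_groups(self):
        hierarchy, _ = self._small_hierarchy()
        assert len(hierarchy["families"]) == 1
        regions = hierarchy["families"][0]["regions"]
        assert len(regions) == 1
        assert len(regions[0]["interface_groups"]) == 2
        assert regions[0]["ligand_types"] == ["dna", "protein"]

    def test_columns_reported_one_based(self):
        hierarchy, _ = self._small_hierarchy()
        assert hierarchy["families"][0]["regions"][0]["columns"] == [2, 3, 4, 5]

    def test_empty_hierarchy(self):
        assert assemble_hierarchy({}, []) == {"families": []}

    def test_two_families_no_cross_links(self):
        aln_x = _alignment({"d1": {i: i for i in range(1, 10)}})
        aln_y = _alignment({"d9": {i: i for i in range(1, 10)}}, family="famY")
        ix = _iface("IF_1", "d1", [1, 2])
        iy = _iface("IF_2", "d9", [3, 4], family="famY")
        rx, _ = cluster_regions([ix], aln_x, cutoff=0.0)
        ry, _ = cluster_regions([iy], aln_y, cutoff=0.0, id_start=2)
        hierarchy = assemble_hierarchy({"famX": rx, "famY": ry}, [ix, iy])
        fams = {f["family_id"]: f for f in hierarchy["families"]}
        assert set(fams) == {"famX", "famY"}
        assert all(len(f["regions"]) == 1 for f in fams.values())

    def test_deterministic_under_input_permutation(self):
        aln = _alignment({"d1": {i: i for i in range(1, 20)}})
        ifaces = [
            _iface("IF_1", "d1", [1, 2, 3], ligand_type="dna", ligand_family=""),
            _iface("IF_2", "d1", [2, 3, 4]),
            _iface("IF_3", "d1", [10, 11]),
        ]
        outs = []
        for order in (ifaces, ifaces[::-1], [ifaces[1], ifaces[2], ifaces[0]]):
            regions, _ = cluster_regions(list(order), aln, cutoff=0.0)
            outs.append(write_hierarchy_json(assemble_hierarchy({"famX": regions}, list(order))))
        assert outs[0] == outs[1] == outs[2]


class TestSearchFilters:
    def _hier(self):
        aln = _alignment({"d1": {i: i for i in range(1, 20)}})
        dual = [
            _iface("IF_1", "d1", [1, 2, 3], ligand_type="dna", ligand_family=""),
            _iface("IF_2", "d1", [2, 3, 4], ligand_type="protein", ligand_family="famZ"),
        ]
        solo = [_iface("IF_3", "d1", [10, 11], ligand_type="protein", ligand_family="famZ")]
        regions, _ = cluster_regions(dual + solo, aln, cutoff=0.0)
        return assemble_hierarchy({"famX": regions}, dual + solo)

    def test_conjunctive_ligand_filter(self):
        hierarchy = self._hier()
        filt = LigandTypeFilter(allowed=frozenset({"protein", "dna"}))
        out = apply_search_filters(hierarchy, filt)
        regions = out["families"][0]["regions"]
        # only the region recognizing both protein and DNA survives
        assert len(regions) == 1
        assert regions[0]["ligand_types"] == ["dna", "protein"]

    def test_single_type_filter_drops_nonmatching(self):
        out = apply_search_filters(self._hier(), LigandTypeFilter(allowed=frozenset({"dna"})))
        members = [
            m
            for f in out["families"]
            for r in f["regions"]
            for g in r["interface_groups"]
            for m in g["members"]
        ]
        assert all(m["ligand_type"] == "dna" for m in members)

    def test_hetero_filter_drops_homo_only_region(self):
        aln = _alignment({"d1": {i: i for i in range(1, 10)}})
        homo = _iface("IF_1", "d1", [1, 2], complex_class="homo", ligand_family="famX")
        regions, _ = cluster_regions([homo], aln, cutoff=0.0)
        hierarchy = assemble_hierarchy({"famX": regions}, [homo])
        out = apply_search_filters(hierarchy, LigandTypeFilter(complex_type="hetero"))
        assert out == {"families": []}

    def test_identity_filter_keeps_everything(self):
        hierarchy = self._hier()
        out = apply_search_filters(hierarchy, LigandTypeFilter())
        assert json.dumps(out) == json.dumps(hierarchy)

    def test_covalent_members_excluded_by_default(self):
        aln = _alignment({"d1": {i: i for i in range(1, 10)}})
        cov = _iface("IF_1", "d1", [1, 2], ligand_type="saccharide",
                     ligand_family="", chain_class="intra", covalent=True)
        regions, _ = cluster_regions([cov], aln, cutoff=0.0)
        hierarchy = assemble_hierarchy({"famX": regions}, [cov])
        assert apply_search_filters(hierarchy, LigandTypeFilter()) == {"families": []}
        kept = apply_search_filters(hierarchy, LigandTypeFilter(), include_covalent=True)
        assert kept["families"]
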