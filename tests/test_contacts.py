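"""Contact classification, water bridges, interface assembly, packing filter."""

import numpy as np
import pytest

from solviface.contacts import (
    Contact,
    Cutoffs,
    Interface,
    build_interface,
    detect_direct_contacts,
    detect_water_bridges,
    filter_crystal_packing,
    scan_structure,
)
from solviface.entity_typing import Entity, EntityType, build_entities
from solviface.fixtures import (
    StructureBuilder,
    make_atom_pair,
    make_peptide_chain,
    make_water_bridge,
)
from solviface.structure_io import DomainDefinition, ResidueKey, parse_structure


def _chain_entities(st, entity_type=EntityType.PEPTIDE):
    return {
        chain: Entity(entity_id=f"E_{chain}", entity_type=entity_type, residues=keys)
        for chain, keys in st.chains.items()
    }


def _named_labels(contacts, name_a, name_b):
    for c in contacts:
        if c.atom_a[2] == name_a and c.atom_b[2] == name_b:
            return set(c.labels)
    return None


class TestDirectContacts:
    @pytest.mark.parametrize(
        "res_a,atom_a,res_b,atom_b,distance,expected",
        [
            # hydrogen-bond boundary: donor/acceptor <= 3.6
            ("GLY", "N", "GLY", "O", 3.50, {"hbond", "vdw"}),
            ("GLY", "N", "GLY", "O", 3.60, {"hbond", "vdw"}),
            ("GLY", "N", "GLY", "O", 3.70, {"vdw"}),
            # salt-bridge boundary: opposite charges <= 4.0 (also donor/acceptor)
            ("LYS", "NZ", "ASP", "OD1", 3.20, {"salt_bridge", "hbond", "vdw"}),
            ("LYS", "NZ", "ASP", "OD1", 3.90, {"salt_bridge", "vdw"}),
            ("LYS", "NZ", "ASP", "OD1", 4.00, {"salt_bridge", "vdw"}),
            ("LYS", "NZ", "ASP", "OD1", 4.05, {"vdw"}),
            # vdW envelope: any heavy atoms <= 4.5
            ("ALA", "CB", "ALA", "CB", 4.50, {"vdw"}),
            ("ALA", "CB", "ALA", "CB", 4.60, None),
        ],
    )
    def test_label_boundaries(self, chem, res_a, atom_a, res_b, atom_b, distance, expected):
        st = parse_structure(make_atom_pair(res_a, atom_a, res_b, atom_b, distance))
        ents = _chain_entities(st)
        contacts = detect_direct_contacts(st, ents["A"], ents["B"], chem)
        assert _named_labels(contacts, atom_a, atom_b) == expected

    def test_symmetry(self, chem):
        st = parse_structure(make_atom_pair("LYS", "NZ", "ASP", "OD1", 3.2))
        ents = _chain_entities(st)
        ab = detect_direct_contacts(st, ents["A"], ents["B"], chem)
        ba = detect_direct_contacts(st, ents["B"], ents["A"], chem)
        assert sorted(c.unordered() for c in ab) == sorted(c.unordered() for c in ba)

    def test_empty_entity_gives_empty_list(self, chem):
        st = parse_structure(make_peptide_chain(2).to_pdb())
        a = Entity("E_A", EntityType.PEPTIDE, st.chains["A"])
        ghost = Entity(
            "E_G", EntityType.PEPTIDE, [ResidueKey("Z", 1, "", "GLY")]
        )
        assert detect_direct_contacts(st, a, ghost, chem) == []

    def test_covalent_pairs_excluded(self, chem):
        # 1.45 A apart: a glycosidic-bond distance, not a vdW contact
        st = parse_structure(make_atom_pair("GLY", "N", "GLY", "O", 1.45))
        ents = _chain_entities(st)
        contacts = detect_direct_contacts(st, ents["A"], ents["B"], chem)
        assert _named_labels(contacts, "N", "O") is None

    def test_enlarging_cutoffs_never_removes_contacts(self, chem):
        rng = np.random.default_rng(3)
        st = _random_two_chain_structure(rng, n_per_chain=30)
        ents = _chain_entities(st)
        base = detect_direct_contacts(st, ents["A"], ents["B"], chem, Cutoffs())
        wide = detect_direct_contacts(
            st, ents["A"], ents["B"], chem, Cutoffs(hbond=4.0, salt_bridge=4.4, vdw=5.5)
        )
        base_pairs = {(c.atom_a, c.atom_b) for c in base}
        wide_pairs = {(c.atom_a, c.atom_b) for c in wide}
        assert base_pairs <= wide_pairs

    def test_matches_all_pairs_brute_force(self, chem):
        """KD-tree contact detection equals an O(n^2) scan with the rule
        table re-stated independently."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            st = _random_two_chain_structure(rng, n_per_chain=40)
            ents = _chain_entities(st)
            got = sorted(
                (c.atom_a[1], c.atom_a[2], c.atom_b[1], c.atom_b[2],
                 round(c.distance, 6), tuple(sorted(c.labels)))
                for c in detect_direct_contacts(st, ents["A"], ents["B"], chem)
            )
            expected = sorted(_brute_force_contacts(st, chem))
            assert got == expected


def _random_two_chain_structure(rng, n_per_chain=40):
    """Single-atom GLY residues (N donor / O acceptor / CA apolar) scattered
    in a box; LYS NZ / ASP OD1 sprinkled in for charges."""
    builder = StructureBuilder()
    choices = [("GLY", "N", "N"), ("GLY", "O", "O"), ("GLY", "CA", "C"),
               ("LYS", "NZ", "N"), ("ASP", "OD1", "O")]
    for chain in "AB":
        for i in range(n_per_chain):
            res, atom, elem = choices[rng.integers(len(choices))]
            pos = rng.uniform(0, 14, size=3)
            builder.add_atom("ATOM", atom, elem, res, chain, i + 1, pos)
    return parse_structure(builder.to_pdb())


def _brute_force_contacts(st, chem):
    """Independent all-pairs oracle for the three distance criteria."""
    rows = []
    chains = st.chains
    atoms_a = [a for k in chains["A"] for a in st.residue_atoms(k)]
    atoms_b = [a for k in chains["B"] for a in st.residue_atoms(k)]
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d > 4.5 + 1e-9 or d <= 1.9 + 1e-9:
                continue
            ra = chem.atom_roles(a.residue_key.res_name, a.name)
            rb = chem.atom_roles(b.residue_key.res_name, b.name)
            labels = {"vdw"}
            if d <= 3.6 + 1e-9 and (
                ("donor" in ra and "acceptor" in rb) or ("acceptor" in ra and "donor" in rb)
            ):
                labels.add("hbond")
            if d <= 4.0 + 1e-9 and (
                ("positive" in ra and "negative" in rb)
                or ("negative" in ra and "positive" in rb)
            ):
                labels.add("salt_bridge")
            rows.append(
                (a.residue_key, a.name, b.residue_key, b.name, round(d, 6), tuple(sorted(labels)))
            )
    return rows


class TestWaterBridges:
    def _bridge(self, chem, d_a, d_b, n_waters=1):
        st = parse_structure(
            make_water_bridge("SER", "OG", "ASN", "OD1", d_a, d_b, n_waters=n_waters)
        )
        ents = _chain_entities(st)
        waters = [
            Entity(f"W_{i}", EntityType.WATER, [k])
            for i, k in enumerate(st.chains.get("W", []), start=1)
        ]
        return detect_water_bridges(st, ents["A"], ents["B"], waters, chem)

    def test_single_bridge(self, chem):
        bridges = self._bridge(chem, 2.8, 3.0)
        assert len(bridges) == 1
        assert bridges[0].bridging_water == "W_1"
        assert bridges[0].distance == pytest.approx(3.0, abs=1e-3)

    def test_long_leg_breaks_bridge(self, chem):
        assert self._bridge(chem, 2.8, 3.8) == []

    def test_two_waters_give_two_records(self, chem):
        bridges = self._bridge(chem, 2.8, 3.0, n_waters=2)
        # brute-force enumeration of (residue_a, residue_b, water) triples
        assert len(bridges) == 2
        assert {b.bridging_water for b in bridges} == {"W_1", "W_2"}


class TestBuildInterface:
    def _domain_and_ligand(self, chem, with_water=False):
        builder = make_peptide_chain(4)
        # ligand ASP OD1 placed 3.0 A above residue 2's backbone O
        o_atom = next(a for a in builder.atoms if a["seq"] == 2 and a["name"] == "O")
        ox, oy, oz = o_atom["xyz"]
        for name, element, xyz in [("OD1", "O", (0, 3.0, 0)), ("CG", "C", (0, 4.4, 0))]:
            builder.add_atom("ATOM", name, element, "ASP", "B", 1,
                             (ox + xyz[0], oy + xyz[1], oz + xyz[2]))
        if with_water:
            # water hydrogen-bonded to residue 2's O and the ligand OD1
            builder.add_atom("HETATM", "O", "O", "HOH", "W", 1, (ox + 2.6, oy + 1.5, oz))
        st = parse_structure(builder.to_pdb())
        domain = Entity("d_t", EntityType.DOMAIN, st.chains["A"], family_id="famT")
        ligand = Entity("L1", EntityType.PEPTIDE, st.chains["B"])
        waters = [
            Entity("W_1", EntityType.WATER, [k]) for k in st.chains.get("W", [])
        ]
        return st, domain, ligand, waters

    def test_no_contacts_returns_none(self, chem):
        builder = make_peptide_chain(2)
        make_peptide_chain(2, chain_id="B", offset=(0, 50, 0), builder=builder)
        st = parse_structure(builder.to_pdb())
        domain = Entity("d_t", EntityType.DOMAIN, st.chains["A"], family_id="famT")
        ligand = Entity("L1", EntityType.PEPTIDE, st.chains["B"])
        assert build_interface(st, domain, ligand, [], chem) is None

    def test_dry_and_dual_solvation(self, chem):
        st, domain, ligand, waters = self._domain_and_ligand(chem, with_water=True)
        iface = build_interface(st, domain, ligand, waters, chem)
        res2 = next(k for k in iface.residue_set if k.seq_num == 2)
        assert iface.solvation[res2] == "dual"
        for key, solv in iface.solvation.items():
            has_direct = any(not c.bridging_water and c.atom_a[1] == key for c in iface.contacts)
            has_bridge = any(c.bridging_water and c.atom_a[1] == key for c in iface.contacts)
            expected = "dual" if has_direct and has_bridge else ("dry" if has_direct else "wet")
            assert solv == expected

    def test_chemistry_hydrophilic_wins_on_mixed_atoms(self, chem):
        st, domain, ligand, waters = self._domain_and_ligand(chem)
        iface = build_interface(st, domain, ligand, waters, chem)
        res2 = next(k for k in iface.residue_set if k.seq_num == 2)
        assert iface.chemistry[res2] == "hydrophilic"

    def test_homo_vs_hetero_and_intra(self, chem, sac_codes):
        # one chain, two domain segments close in space: intra interaction;
        # same family -> homo, different family -> hetero
        for fam_b, expected_class in [("famX", "homo"), ("famY", "hetero")]:
            builder = make_peptide_chain(8, chain_id="A")
            make_peptide_chain(
                8, chain_id="A", start_seq=40, offset=(0, 6.3, 0), builder=builder
            )
            st = parse_structure(builder.to_pdb())
            defs = [
                DomainDefinition("d_a", "famX", "t", (("A", 1, 8),)),
                DomainDefinition("d_b", fam_b, "t", (("A", 40, 47),)),
            ]
            entity_set = build_entities(st, defs, chem, sac_codes)
            ifaces = scan_structure(st, entity_set, chem)
            assert ifaces, "segments should be in contact"
            assert ifaces[0].complex_class == expected_class
            assert ifaces[0].chain_class == "intra"

    def test_separate_chains_are_inter(self, chem, sac_codes):
        builder = make_peptide_chain(8, chain_id="A")
        make_peptide_chain(8, chain_id="B", offset=(0, 6.3, 0), builder=builder)
        st = parse_structure(builder.to_pdb())
        defs = [DomainDefinition("d_a", "famX", "t", (("A", 1, 8),))]
        entity_set = build_entities(st, defs, chem, sac_codes)
        ifaces = scan_structure(st, entity_set, chem)
        assert ifaces[0].chain_class == "inter"


class TestCrystalPackingFilter:
    def _iface(self, n_residues=6, ligand_type="protein"):
        keys = [ResidueKey("A", i, "", "ALA") for i in range(1, n_residues + 1)]
        return Interface(
            interface_id="IF_1",
            domain_id="d_a",
            family_id="famX",
            ligand_entity_id="d_b",
            ligand_type=ligand_type,
            ligand_family_id="famY",
            residue_set=keys,
            solvation={k: "dry" for k in keys},
            chemistry={k: "hydrophilic" for k in keys},
            complex_class="hetero",
            chain_class="inter",
            covalent=False,
            contacts=[],
        )

    def test_hook_probability_cutoff(self):
        kept = filter_crystal_packing([self._iface()], classifier_hook=lambda i: 0.65)
        assert kept == []
        kept = filter_crystal_packing([self._iface()], classifier_hook=lambda i: 0.90)
        assert len(kept) == 1

    def test_raising_hook_keeps_interface(self):
        def boom(_):
            raise RuntimeError("classifier offline")

        kept = filter_crystal_packing([self._iface()], classifier_hook=boom)
        assert len(kept) == 1

    def test_naive_heuristic_drops_tiny_protein_interfaces(self):
        small, large = self._iface(3), self._iface(8)
        sugar = self._iface(3, ligand_type="saccharide")
        kept = filter_crystal_packing([small, large, sugar], naive_heuristic=True)
        assert [i.interface_id for i in kept] == ["IF_1", "IF_1"]
        assert small not in kept and large in kept and sugar in kept

    def test_no_hook_no_heuristic_passes_through(self, caplog):
        ifaces = [self._iface()]
        with caplog.at_level("WARNING"):
            assert filter_crystal_packing(ifaces) == ifaces
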