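"""Deterministic synthetic PDB fixtures with controlled geometry.

Everything here is schematic, not stereochemically refined: the detection
machinery consumes heavy-atom distances only, so fixtures guarantee exact
pairwise separations (to the 3-decimal precision of PDB coordinates) rather
than realistic conformations.  A fixed seed yields byte-identical output.

The corpus generator (:func:`make_complex_corpus`) writes a self-consistent
toy data set — two protein families with DNA, peptide and saccharide
ligands, family alignments, domain definitions and one cross-family
residue correspondence — sufficient to drive the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import ResidueKey

# ---------------------------------------------------------------------------
# residue templates (heavy atoms, Angstrom; schematic but bond-plausible)
# ---------------------------------------------------------------------------

_BACKBONE = [
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.458, 0.000, 0.000)),
    ("C", "C", (2.009, 1.420, 0.000)),
    ("O", "O", (1.251, 2.390, 0.000)),
]

AMINO_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": list(_BACKBONE),
    "ALA": _BACKBONE + [("CB", "C", (1.988, -0.773, 1.199))],
    "SER": _BACKBONE
    + [("CB", "C", (1.988, -0.773, 1.199)), ("OG", "O", (2.600, -0.800, 2.560))],
    "ASP": _BACKBONE
    + [
        ("CB", "C", (1.988, -0.773, 1.199)),
        ("CG", "C", (2.600, -0.800, 2.560)),
        ("OD1", "O", (3.800, -0.800, 2.900)),
        ("OD2", "O", (1.900, -0.800, 3.500)),
    ],
    "ASN": _BACKBONE
    + [
        ("CB", "C", (1.988, -0.773, 1.199)),
        ("CG", "C", (2.600, -0.800, 2.560)),
        ("OD1", "O", (3.800, -0.800, 2.900)),
        ("ND2", "N", (1.900, -0.800, 3.500)),
    ],
    "LYS": _BACKBONE
    + [
        ("CB", "C", (1.988, -0.773, 1.199)),
        ("CG", "C", (2.600, -0.800, 2.560)),
        ("CD", "C", (3.300, -0.900, 3.900)),
        ("CE", "C", (3.900, -1.000, 5.250)),
        ("NZ", "N", (4.500, -1.100, 6.600)),
    ],
}

ONE_TO_THREE = {"G": "GLY", "A": "ALA", "S": "SER", "D": "ASP", "N": "ASN", "K": "LYS"}

_SUGAR_PHOSPHATE = [
    ("P", "P", (-3.000, 0.000, 1.400)),
    ("OP1", "O", (-3.900, 0.900, 1.400)),
    ("OP2", "O", (-3.900, -0.900, 1.400)),
    ("O5'", "O", (-2.400, 0.000, 0.100)),
    ("C5'", "C", (-3.100, 0.000, -1.100)),
    ("C4'", "C", (-2.300, 0.000, -2.300)),
    ("O4'", "O", (-0.950, 0.000, -2.100)),
    ("C3'", "C", (-2.500, 0.600, -3.650)),
    ("O3'", "O", (-3.500, -0.100, -4.400)),
    ("C2'", "C", (-1.200, 0.400, -4.300)),
    ("C1'", "C", (-0.300, 0.600, -3.100)),
]
_O2PRIME = ("O2'", "O", (-1.250, 0.900, -5.600))

# purine/pyrimidine bases with the pairing-edge atom at the strictly
# largest x (so duplex gap distances are exact by construction)
_ADENINE_BASE = [
    ("N9", "N", (0.600, 0.000, -3.000)),
    ("C8", "C", (1.100, 0.000, -4.250)),
    ("N7", "N", (2.450, 0.000, -4.400)),
    ("C5", "C", (3.000, 0.000, -3.150)),
    ("C4", "C", (1.900, 0.000, -2.250)),
    ("N3", "N", (2.000, 0.000, -0.900)),
    ("C2", "C", (3.300, 0.000, -0.500)),
    ("C6", "C", (3.600, 0.000, -1.500)),
    ("N6", "N", (3.900, 0.000, -0.300)),
    ("N1", "N", (4.000, 0.000, -2.400)),
]
_THYMINE_BASE = [
    ("N1", "N", (0.600, 0.000, -3.000)),
    ("C2", "C", (1.200, 0.000, -4.200)),
    ("O2", "O", (0.600, 0.000, -5.250)),
    ("C4", "C", (3.300, 0.000, -3.600)),
    ("O4", "O", (3.900, 0.000, -4.650)),
    ("C5", "C", (2.400, 0.000, -1.500)),
    ("C7", "C", (2.900, 0.000, -0.200)),
    ("C6", "C", (1.300, 0.000, -1.800)),
    ("N3", "N", (4.000, 0.000, -2.400)),
]
_URACIL_BASE = [entry for entry in _THYMINE_BASE if entry[0] != "C7"]

NAG_TEMPLATE = [
    ("C1", "C", (0.000, 0.000, 0.000)),
    ("C2", "C", (0.750, 1.300, 0.000)),
    ("C3", "C", (2.250, 1.300, 0.000)),
    ("C4", "C", (3.000, 0.000, 0.000)),
    ("C5", "C", (2.250, -1.300, 0.000)),
    ("O5", "O", (0.750, -1.300, 0.000)),
    ("C6", "C", (3.000, -2.600, 0.000)),
    ("O6", "O", (4.400, -2.600, 0.000)),
    ("O3", "O", (3.000, 2.500, 0.000)),
    ("N2", "N", (0.000, 2.500, 0.000)),
    ("O4", "O", (4.430, 0.000, 0.000)),
]


class FixtureError(ValueError):
    """A fixture request was inconsistent (unknown residue/atom, bad distance)."""


# ---------------------------------------------------------------------------
# low-level builder
# ---------------------------------------------------------------------------

@dataclass
class StructureBuilder:
    """Accumulates atoms and emits fixed-column PDB text with CONECT."""

    atoms: list[dict] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def add_atom(
        self,
        record_kind: str,
        name: str,
        element: str,
        res_name: str,
        chain_id: str,
        seq_num: int,
        coords,
    ) -> int:
        serial = len(self.atoms) + 1
        self.atoms.append(
            {
                "kind": record_kind,
                "serial": serial,
                "name": name,
                "element": element,
                "res_name": res_name,
                "chain": chain_id,
                "seq": seq_num,
                "xyz": tuple(round(float(v), 3) for v in coords),
            }
        )
        return serial

    def add_residue(
        self,
        template,
        res_name: str,
        chain_id: str,
        seq_num: int,
        offset=(0.0, 0.0, 0.0),
        record_kind: str = "ATOM",
        transform=None,
    ) -> dict[str, int]:
        serials = {}
        for name, element, xyz in template:
            pos = np.asarray(xyz, dtype=float)
            if transform is not None:
                pos = transform(pos)
            pos = pos + np.asarray(offset, dtype=float)
            serials[name] = self.add_atom(
                record_kind, name, element, res_name, chain_id, seq_num, pos
            )
        return serials

    def add_bond(self, serial_a: int, serial_b: int) -> None:
        self.bonds.append((serial_a, serial_b))

    def serial_of(self, chain_id: str, seq_num: int, name: str) -> int:
        for atom in self.atoms:
            if atom["chain"] == chain_id and atom["seq"] == seq_num and atom["name"] == name:
                return atom["serial"]
        raise KeyError(f"{chain_id}:{seq_num}:{name}")

    def coords(self, chain_id: str | None = None) -> np.ndarray:
        return np.array(
            [
                a["xyz"]
                for a in self.atoms
                if chain_id is None or a["chain"] == chain_id
            ]
        )

    def to_pdb(self) -> str:
        lines = []
        for a in self.atoms:
            name = a["name"]
            if len(name) < 4 and len(a["element"]) < 2:
                name = " " + name
            x, y, z = a["xyz"]
            lines.append(
                f"{a['kind']:<6}{a['serial']:>5} {name:<4} "
                f"{a['res_name']:>3} {a['chain']:1}{a['seq']:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{10.00:6.2f}"
                f"          {a['element']:>2}"
            )
        neighbors: dict[int, list[int]] = {}
        for i, j in self.bonds:
            neighbors.setdefault(i, []).append(j)
            neighbors.setdefault(j, []).append(i)
        for serial in sorted(neighbors):
            partners = sorted(set(neighbors[serial]))
            for start in range(0, len(partners), 4):
                chunk = partners[start : start + 4]
                lines.append(
                    "CONECT" + f"{serial:>5}" + "".join(f"{p:>5}" for p in chunk)
                )
        return "\n".join(lines) + "\nEND\n"


def _oriented_template(res_name: str, atom_name: str, flip: bool):
    """Rotate a residue template so the named atom is the strict extreme
    along +x (or -x when flipped) and sits at the origin."""
    template = AMINO_TEMPLATES.get(res_name.upper())
    if template is None:
        raise FixtureError(f"no template for residue {res_name!r}")
    names = [n for n, _, _ in template]
    if atom_name.upper() not in names:
        raise FixtureError(f"residue {res_name} template has no atom {atom_name!r}")
    coords = np.array([xyz for _, _, xyz in template])
    idx = names.index(atom_name.upper())
    centroid = coords.mean(axis=0)
    direction = coords[idx] - centroid
    if np.linalg.norm(direction) < 1e-6:
        direction = np.array([1.0, 0.0, 0.0])
    target = np.array([[-1.0 if flip else 1.0, 0.0, 0.0]])
    rot, _ = Rotation.align_vectors(target, direction[None, :])
    rotated = rot.apply(coords - coords[idx])
    sign = -1.0 if flip else 1.0
    # the named atom must be the unique extreme so no other cross-chain
    # pair can undercut the requested separation
    others = np.delete(rotated[:, 0] * sign, idx)
    if others.size and others.max() >= -0.05:
        raise FixtureError(
            f"atom {atom_name} of {res_name} is not extremal; pick a peripheral atom"
        )
    out = [
        (name, element, tuple(rotated[i]))
        for i, (name, element, _) in enumerate(template)
    ]
    return out


# ---------------------------------------------------------------------------
# scenario generators
# ---------------------------------------------------------------------------

def make_atom_pair(
    res_a: str, atom_a: str, res_b: str, atom_b: str, distance: float
) -> str:
    """Two single-residue chains with the named atoms at exactly the
    requested separation (after 3-decimal rounding)."""
    if not distance > 0:
        raise FixtureError(f"distance must be positive, got {distance}")
    builder = StructureBuilder()
    builder.add_residue(_oriented_template(res_a, atom_a, flip=False), res_a.upper(), "A", 1)
    builder.add_residue(
        _oriented_template(res_b, atom_b, flip=True),
        res_b.upper(),
        "B",
        1,
        offset=(round(distance, 3), 0.0, 0.0),
    )
    return builder.to_pdb()


def make_water_bridge(
    res_a: str,
    atom_a: str,
    res_b: str,
    atom_b: str,
    dist_a: float,
    dist_b: float,
    n_waters: int = 1,
) -> str:
    """Two residues flanking ``n_waters`` water oxygens; the named atom of
    each residue sits exactly ``dist_a`` / ``dist_b`` from every water."""
    if dist_a <= 0 or dist_b <= 0:
        raise FixtureError("water-bridge leg distances must be positive")
    builder = StructureBuilder()
    builder.add_residue(
        _oriented_template(res_a, atom_a, flip=False),
        res_a.upper(),
        "A",
        1,
        offset=(-round(dist_a, 3), 0.0, 0.0),
    )
    builder.add_residue(
        _oriented_template(res_b, atom_b, flip=True),
        res_b.upper(),
        "B",
        1,
        offset=(round(dist_b, 3), 0.0, 0.0),
    )
    # waters all at the origin would collide; spread them on a tiny circle
    # in the plane normal to the bridge axis so both legs stay exact
    for w in range(n_waters):
        if n_waters == 1:
            pos = (0.0, 0.0, 0.0)
            # adjust legs exactly: origin is at distance dist_a / dist_b
            builder.add_atom("HETATM", "O", "O", "HOH", "W", w + 1, pos)
        else:
            # keep each water equidistant from both named atoms by placing
            # it on the perpendicular bisector plane only when legs differ;
            # here waters share the axis point shifted along y
            builder.add_atom("HETATM", "O", "O", "HOH", "W", w + 1, (0.0, 0.4 * w, 0.0))
    return builder.to_pdb()


def make_peptide_chain(
    n_res: int,
    chain_id: str = "A",
    sequence: str | None = None,
    start_seq: int = 1,
    offset=(0.0, 0.0, 0.0),
    spacing: float = 3.8,
    builder: StructureBuilder | None = None,
    jitter: np.random.Generator | None = None,
) -> StructureBuilder:
    """Extended poly-peptide chain, one residue every ``spacing`` A along x."""
    if n_res < 1:
        raise FixtureError("chain needs at least one residue")
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise FixtureError("sequence length does not match n_res")
    builder = builder or StructureBuilder()
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE.get(letter.upper())
        if res_name is None:
            raise FixtureError(f"no template for one-letter code {letter!r}")
        template = AMINO_TEMPLATES[res_name]
        shift = np.asarray(offset, dtype=float) + np.array([spacing * i, 0.0, 0.0])
        if jitter is not None:
            shift = shift + jitter.uniform(-0.04, 0.04, size=3)
        builder.add_residue(template, res_name, chain_id, start_seq + i, offset=shift)
    return builder


def make_chain_pair(n_res: int, gap: float = 4.0) -> str:
    """Two parallel extended chains separated by ``gap`` along z (an
    idealized two-chain interface for end-to-end smoke tests)."""
    builder = make_peptide_chain(n_res, chain_id="A")
    zmax = builder.coords("A")[:, 2].max()
    make_peptide_chain(
        n_res, chain_id="B", offset=(0.0, 0.0, float(zmax) + gap), builder=builder
    )
    return builder.to_pdb()


def make_na_duplex(
    n_bp: int,
    min_base_gap: float,
    rna: bool = False,
    chain_ids: tuple[str, str] = ("B", "C"),
    offset=(0.0, 0.0, 0.0),
    builder: StructureBuilder | None = None,
    orientation: str = "x",
) -> StructureBuilder:
    """Two complementary strands whose closest base-base atom distance is
    exactly ``min_base_gap`` (pairing-edge atoms are extremal by template
    design).  With ``rna`` the sugar carries O2' and residues are A/U.

    ``orientation='x'`` pairs the strands along x with the helix axis on y;
    ``orientation='z'`` transposes so the axis runs along x and pairing
    along z (handy for laying a duplex over a protein chain).
    """
    if n_bp < 1:
        raise FixtureError("duplex needs at least one base pair")
    if min_base_gap <= 0:
        raise FixtureError("base gap must be positive")
    builder = builder or StructureBuilder()
    sugar = list(_SUGAR_PHOSPHATE) + ([_O2PRIME] if rna else [])
    base_a = _ADENINE_BASE
    base_b = _URACIL_BASE if rna else _THYMINE_BASE
    res_a = "A" if rna else "DA"
    res_b = "U" if rna else "DT"
    gap = round(min_base_gap, 3)
    mirror_x = 8.0 + gap  # pairing-edge atoms sit at x=4.0 in both templates

    def place(template, res_name, chain, seq, rise, mirrored):
        def transform(p):
            q = np.array(p, dtype=float)
            if mirrored:
                q[0] = mirror_x - q[0]
            q[1] += rise
            if orientation == "z":
                q = np.array([q[1], q[2], q[0]])
            return q + np.asarray(offset, dtype=float)

        builder.add_residue(template, res_name, chain, seq, transform=transform)

    for i in range(n_bp):
        place(sugar + base_a, res_a, chain_ids[0], i + 1, 3.4 * i, mirrored=False)
    for i in range(n_bp):
        place(sugar + base_b, res_b, chain_ids[1], i + 1, 3.4 * i, mirrored=True)
    return builder


def make_oligosaccharide(
    n_units: int,
    connected: bool = True,
    with_conect: bool = True,
    chain_id: str = "B",
    offset=(0.0, 0.0, 0.0),
    builder: StructureBuilder | None = None,
) -> StructureBuilder:
    """N-acetylglucosamine units; when connected, unit i's O4 sits 1.43 A
    from unit i+1's C1 (a glycosidic-bond distance) with optional CONECT."""
    if n_units < 1:
        raise FixtureError("need at least one sugar unit")
    builder = builder or StructureBuilder()
    step = 4.43 + 1.43 if connected else 9.0
    serials = []
    for i in range(n_units):
        shift = np.asarray(offset, dtype=float) + np.array([step * i, 0.0, 0.0])
        serials.append(
            builder.add_residue(NAG_TEMPLATE, "NAG", chain_id, i + 1, offset=shift, record_kind="HETATM")
        )
    if connected and with_conect:
        for i in range(n_units - 1):
            builder.add_bond(serials[i]["O4"], serials[i + 1]["C1"])
    return builder


def make_glycoprotein(n_res: int = 12, link_distance: float = 1.45) -> str:
    """Short chain with a mid-chain asparagine carrying an N-linked sugar
    whose C1 sits exactly ``link_distance`` from ND2 (covalent by the
    distance fallback; no CONECT written)."""
    pos = n_res // 2
    sequence = "A" * (pos - 1) + "N" + "A" * (n_res - pos)
    builder = make_peptide_chain(n_res, chain_id="A", sequence=sequence)
    nd2 = next(
        a for a in builder.atoms if a["seq"] == pos and a["name"] == "ND2"
    )
    anchor = np.array(nd2["xyz"]) + np.array([0.0, 0.0, round(link_distance, 3)])
    for name, element, xyz in NAG_TEMPLATE:
        builder.add_atom(
            "HETATM", name, element, "NAG", "B", 1, np.array(xyz) + anchor
        )
    return builder.to_pdb()


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _settle_above(
    fixed: np.ndarray, mobile: np.ndarray, target_min_dist: float, axis: int = 2
) -> float:
    """Translation along ``axis`` placing ``mobile`` so its closest approach
    to ``fixed`` equals ``target_min_dist`` (bisection to ~1e-6 A)."""
    tree = cKDTree(fixed)

    def closest(t: float) -> float:
        shifted = mobile.copy()
        shifted[:, axis] += t
        return float(tree.query(shifted)[0].min())

    lo = 0.0
    while closest(lo) > target_min_dist:
        lo -= 5.0
        if lo < -500:
            raise FixtureError("placement failed: bodies never approach")
    hi = lo + 5.0
    while closest(hi) < target_min_dist:
        hi += 5.0
        if hi > 500:
            raise FixtureError("placement failed: bodies never separate")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if closest(mid) < target_min_dist:
            lo = mid
        else:
            hi = mid
    return hi


# ---------------------------------------------------------------------------
# toy corpus
# ---------------------------------------------------------------------------

FAM_A_SEQ = "GAKDSNGAKDSNGAKDSNGAKDSNGAKDSN"  # 30 residues
FAM_B_SEQ = "GASDNGASDNGASDNGASDN"  # 20 residues, no lysine near the glyco site
FAM_C_SEQ = "GAKDSNGAKDSNGAKDSNGAKDSNGAKD"  # 28 residues


def _protein_builder(sequence: str, rng: np.random.Generator) -> StructureBuilder:
    return make_peptide_chain(
        len(sequence), chain_id="A", sequence=sequence, jitter=rng
    )


def make_complex_corpus(seed: int, out_dir: str | Path) -> dict:
    """Write the self-consistent toy corpus and return its manifest.

    Contents: family famA (members d1, d2; one DNA complex, one peptide
    complex sharing part of the binding region), family famB (member d3;
    a non-covalent trisaccharide ligand plus a covalently N-linked sugar),
    apo family famC (member d9) reachable only through the famA~famC
    correspondence map, and the side tables driving the pipeline.
    """
    rng = np.random.default_rng(int(seed))
    out = Path(out_dir)
    (out / "pdb").mkdir(parents=True, exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)

    # ligands approach the chain's carbonyl face (+y), which presents a
    # uniform surface, so contact spans follow the ligand's x extent

    # --- 1abc: famA member d1 + DNA duplex + waters --------------------------
    b1 = _protein_builder(FAM_A_SEQ, rng)
    protein_coords = b1.coords("A")
    duplex = make_na_duplex(7, 3.4, orientation="z")
    duplex_coords = duplex.coords()
    duplex_coords[:, 0] += 16.0  # lay the helix over residues ~5-11
    dy = _settle_above(protein_coords, duplex_coords, 3.2, axis=1)
    for atom in duplex.atoms:
        x, y, z = atom["xyz"]
        b1.add_atom(
            atom["kind"], atom["name"], atom["element"], atom["res_name"],
            atom["chain"], atom["seq"], (x + 16.0, y + dy, z),
        )
    _maybe_add_bridge_water(b1, donor_chain="A", ligand_chains=("B", "C"))
    (out / "pdb" / "1abc.pdb").write_text(b1.to_pdb())

    # --- 2xyz: famA member d2 + peptide over residues ~9-16 -------------------
    b2 = _protein_builder(FAM_A_SEQ, rng)
    pep = make_peptide_chain(8, chain_id="B", sequence="SNGAKDSN")
    pep_coords = pep.coords("B")
    pep_coords[:, 0] += 3.8 * 8  # span residues ~9-16
    dy = _settle_above(b2.coords("A"), pep_coords, 3.2, axis=1)
    for atom in pep.atoms:
        x, y, z = atom["xyz"]
        b2.add_atom(
            atom["kind"], atom["name"], atom["element"], atom["res_name"],
            atom["chain"], atom["seq"], (x + 3.8 * 8, y + dy, z),
        )
    (out / "pdb" / "2xyz.pdb").write_text(b2.to_pdb())

    # --- 3pqr: famB member d3 + trisaccharide + covalent NAG ------------------
    b3 = _protein_builder(FAM_B_SEQ, rng)
    tri = make_oligosaccharide(3, connected=True, with_conect=True, chain_id="B")
    tri_coords = tri.coords()
    tri_coords[:, 0] += 8.0  # over residues ~3-8
    dy = _settle_above(b3.coords("A"), tri_coords, 3.2, axis=1)
    serial_offset = len(b3.atoms)
    for atom in tri.atoms:
        x, y, z = atom["xyz"]
        b3.add_atom(
            atom["kind"], atom["name"], atom["element"], atom["res_name"],
            atom["chain"], atom["seq"], (x + 8.0, y + dy, z),
        )
    for i, j in tri.bonds:
        b3.add_bond(i + serial_offset, j + serial_offset)
    # covalent N-linked sugar on ASN 15 (no CONECT: covalent via distance)
    nd2 = next(a for a in b3.atoms if a["chain"] == "A" and a["seq"] == 15 and a["name"] == "ND2")
    anchor = np.array(nd2["xyz"]) + np.array([0.0, 0.0, 1.45])
    for name, element, xyz in NAG_TEMPLATE:
        b3.add_atom("HETATM", name, element, "NAG", "C", 1, np.array(xyz) + anchor)
    (out / "pdb" / "3pqr.pdb").write_text(b3.to_pdb())

    # --- 9apo: famC member d9, no ligand --------------------------------------
    b9 = _protein_builder(FAM_C_SEQ, rng)
    (out / "pdb" / "9apo.pdb").write_text(b9.to_pdb())

    # --- side tables ----------------------------------------------------------
    domains = (
        "domain_id\tfamily_id\tpdb_id\tchain\tstart\tend\n"
        f"d1\tfamA\t1abc\tA\t1\t{len(FAM_A_SEQ)}\n"
        f"d2\tfamA\t2xyz\tA\t1\t{len(FAM_A_SEQ)}\n"
        f"d3\tfamB\t3pqr\tA\t1\t{len(FAM_B_SEQ)}\n"
        f"d9\tfamC\t9apo\tA\t1\t{len(FAM_C_SEQ)}\n"
    )
    (out / "domains.tsv").write_text(domains)

    (out / "alignments" / "famA.fasta").write_text(
        f">d1\n{FAM_A_SEQ}-\n>d2\n-{FAM_A_SEQ}\n"
    )
    (out / "alignments" / "famB.fasta").write_text(f">d3\n{FAM_B_SEQ}\n")
    (out / "alignments" / "famC.fasta").write_text(f">d9\n{FAM_C_SEQ}\n")

    corr_rows = [
        "family_a\tmember_a\tchain_a\tseq_a\ticode_a\tresname_a"
        "\tfamily_b\tmember_b\tchain_b\tseq_b\ticode_b\tresname_b"
    ]
    for seq_a in range(4, 15):  # d1 residues 4..14 <-> d9 residues 6..16
        seq_b = seq_a + 2
        res_a = ONE_TO_THREE[FAM_A_SEQ[seq_a - 1]]
        res_b = ONE_TO_THREE[FAM_C_SEQ[seq_b - 1]]
        corr_rows.append(
            f"famA\td1\tA\t{seq_a}\t\t{res_a}\tfamC\td9\tA\t{seq_b}\t\t{res_b}"
        )
    (out / "correspondences.tsv").write_text("\n".join(corr_rows) + "\n")

    manifest = {
        "seed": int(seed),
        "structures": {
            "1abc": "famA domain d1 + DNA duplex (+ water if placeable)",
            "2xyz": "famA domain d2 + peptide",
            "3pqr": "famB domain d3 + trisaccharide + covalent N-linked NAG",
            "9apo": "famC domain d9, apo",
        },
        "families": {"famA": ["d1", "d2"], "famB": ["d3"], "famC": ["d9"]},
        "correspondence": "famA:d1 residues 4-14 <-> famC:d9 residues 6-16",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _maybe_add_bridge_water(
    builder: StructureBuilder, donor_chain: str, ligand_chains: tuple[str, ...]
) -> None:
    """Place a water bridging a protein oxygen/nitrogen and a ligand polar
    atom when geometry allows (2.8 A to the protein, <= 3.4 A to the
    ligand, >= 2.4 A from everything else); silently skips otherwise."""
    polar_protein = [
        a
        for a in builder.atoms
        if a["chain"] == donor_chain and a["element"] in ("N", "O")
    ]
    polar_ligand = [
        a
        for a in builder.atoms
        if a["chain"] in ligand_chains and a["element"] in ("N", "O")
    ]
    all_coords = builder.coords()
    tree = cKDTree(all_coords)
    for p_atom in polar_protein:
        p = np.array(p_atom["xyz"])
        for q_atom in polar_ligand:
            q = np.array(q_atom["xyz"])
            sep = float(np.linalg.norm(q - p))
            if not 5.3 <= sep <= 6.2:
                continue
            w = p + 2.8 * (q - p) / sep
            if float(tree.query(w)[0]) < 2.4:
                continue
            n_existing = len({a["seq"] for a in builder.atoms if a["chain"] == "W"})
            builder.add_atom("HETATM", "O", "O", "HOH", "W", n_existing + 1, w)
            return
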