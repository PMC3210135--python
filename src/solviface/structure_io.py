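"""Structure parsing and configuration tables.

Reads fixed-column PDB coordinate files (ATOM/HETATM/CONECT, first model
only, heavy-atom oriented), tab-separated domain-definition tables, and the
editable chemistry dictionary / saccharide code list that drive all
downstream physicochemical typing.

Alternate locations are resolved to a single conformer per atom (highest
occupancy, ties broken by the lexicographically smallest alt-loc id), so a
parsed :class:`Structure` always holds one coordinate per (residue, atom
name).  Hydrogens and deuteriums, if present, are dropped: every distance
criterion in this package is defined between heavy atoms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: role flags an atom may carry in the chemistry dictionary
ROLE_FLAGS = frozenset({"donor", "acceptor", "positive", "negative", "hydrophobic"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
#: modified amino acids that may appear as HETATM within a polypeptide chain
MODIFIED_AMINO_ACIDS = frozenset({"MSE"})


class PDBParseError(ValueError):
    """A coordinate line could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """The input contained no ATOM or HETATM record."""


class ValidationError(ValueError):
    """A configuration table violated its contract."""


class ResidueKey(NamedTuple):
    """Identity of one residue: the full 4-tuple including insertion code."""

    chain_id: str
    seq_num: int
    insertion_code: str
    res_name: str

    def label(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.seq_num}{self.insertion_code}"


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record after alt-loc resolution."""

    serial: int
    name: str
    element: str
    alt_loc: str
    record_kind: str  # "ATOM" | "HETATM"
    coords: tuple[float, float, float]
    occupancy: float
    residue_key: ResidueKey

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Structure:
    """Atoms grouped by residue and chain, plus the covalent-bond list."""

    atoms: list[AtomRecord]
    bonds: frozenset[tuple[int, int]] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        self._res_atoms: dict[ResidueKey, list[AtomRecord]] = {}
        self._chains: dict[str, list[ResidueKey]] = {}
        self._serial: dict[int, AtomRecord] = {}
        for atom in self.atoms:
            key = atom.residue_key
            if key not in self._res_atoms:
                self._res_atoms[key] = []
                self._chains.setdefault(key.chain_id, []).append(key)
            self._res_atoms[key].append(atom)
            self._serial[atom.serial] = atom
        self._bondset = frozenset(
            (min(i, j), max(i, j)) for i, j in self.bonds if i != j
        )

    # -- residue / chain access -------------------------------------------------
    @property
    def residues(self) -> list[ResidueKey]:
        return list(self._res_atoms)

    @property
    def chains(self) -> dict[str, list[ResidueKey]]:
        return {c: list(keys) for c, keys in self._chains.items()}

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return list(self._res_atoms[key])

    def find_atom(self, key: ResidueKey, name: str) -> AtomRecord | None:
        for atom in self._res_atoms.get(key, ()):
            if atom.name == name:
                return atom
        return None

    def atom_by_serial(self, serial: int) -> AtomRecord | None:
        return self._serial.get(serial)

    def residue_kind(self, key: ResidueKey) -> str:
        kinds = {a.record_kind for a in self._res_atoms[key]}
        return "ATOM" if "ATOM" in kinds else "HETATM"

    def is_bonded(self, serial_a: int, serial_b: int) -> bool:
        pair = (min(serial_a, serial_b), max(serial_a, serial_b))
        return pair in self._bondset

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _parse_coordinate_line(line: str, lineno: int) -> AtomRecord:
    try:
        record_kind = line[:6].strip()
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        seq_num = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed {line[:6].strip()!r} record: {exc}") from exc
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper()
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    return AtomRecord(
        serial=serial,
        name=name,
        element=element.upper(),
        alt_loc=alt_loc,
        record_kind=record_kind,
        coords=(x, y, z),
        occupancy=occupancy,
        residue_key=ResidueKey(chain_id, seq_num, icode, res_name),
    )


def _resolve_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per (residue, atom name): highest occupancy, then
    lexicographically smallest alt-loc id."""
    best: dict[tuple[ResidueKey, str], AtomRecord] = {}
    order: list[tuple[ResidueKey, str]] = []
    for atom in atoms:
        slot = (atom.residue_key, atom.name)
        if slot not in best:
            best[slot] = atom
            order.append(slot)
        else:
            kept = best[slot]
            if (atom.occupancy, _altloc_rank(atom.alt_loc)) > (
                kept.occupancy,
                _altloc_rank(kept.alt_loc),
            ):
                best[slot] = atom
    return [best[slot] for slot in order]


def _altloc_rank(alt_loc: str) -> float:
    # higher rank wins ties; smaller alt-loc id ranks higher
    return -ord(alt_loc) if alt_loc else 1.0


def parse_structure(pdb_text: str | Iterable[str], source: str = "") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL of a multi-model file is kept.  Hydrogens are
    dropped.  CONECT records become a symmetric, deduplicated bond list.
    """
    if isinstance(pdb_text, str):
        lines = pdb_text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in pdb_text]

    atoms: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()
    model_index = 0
    for lineno, line in enumerate(lines, start=1):
        tag = line[:6].strip()
        if tag == "MODEL":
            model_index += 1
            continue
        if tag == "ENDMDL":
            continue
        if model_index > 1:
            continue
        if tag in ("ATOM", "HETATM"):
            atom = _parse_coordinate_line(line, lineno)
            if atom.element in ("H", "D"):
                continue
            atoms.append(atom)
        elif tag == "CONECT":
            try:
                serials = [
                    int(line[start : start + 5])
                    for start in range(6, min(len(line), 31), 5)
                    if line[start : start + 5].strip()
                ]
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed CONECT record: {exc}") from exc
            if serials:
                center = serials[0]
                for other in serials[1:]:
                    if other != center:
                        bonds.add((min(center, other), max(center, other)))
    if not atoms:
        raise EmptyStructureError("no ATOM or HETATM records found")
    atoms = _resolve_alt_locs(atoms)
    return Structure(atoms=atoms, bonds=frozenset(bonds), source=source)


def write_pdb(structure: Structure) -> str:
    """Serialize a structure back to fixed-column PDB text (with CONECT)."""
    out = StringIO()
    for atom in structure.atoms:
        name = atom.name
        # standard alignment: 1-char element symbols start in column 14
        if len(name) < 4 and len(atom.element) < 2:
            name = " " + name
        key = atom.residue_key
        out.write(
            f"{atom.record_kind:<6}{atom.serial:>5} {name:<4}{atom.alt_loc or ' ':1}"
            f"{key.res_name:>3} {key.chain_id or ' ':1}{key.seq_num:>4}{key.insertion_code or ' ':1}"
            f"   {atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{atom.occupancy:6.2f}{10.00:6.2f}          {atom.element:>2}\n"
        )
    neighbors: dict[int, list[int]] = {}
    for i, j in sorted(structure.bonds):
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for serial in sorted(neighbors):
        partners = sorted(neighbors[serial])
        for start in range(0, len(partners), 4):
            chunk = partners[start : start + 4]
            out.write("CONECT" + f"{serial:>5}" + "".join(f"{p:>5}" for p in chunk) + "\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Domain definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainDefinition:
    """SCOP-like definition of one domain: family + chain/residue segments."""

    domain_id: str
    family_id: str
    pdb_id: str
    segments: tuple[tuple[str, int, int], ...]

    def covers(self, key: ResidueKey) -> bool:
        return any(
            key.chain_id == chain and start <= key.seq_num <= end
            for chain, start, end in self.segments
        )


_DOMAIN_COLUMNS = ["domain_id", "family_id", "pdb_id", "chain", "start", "end"]


def load_domain_definitions(table_text: str) -> list[DomainDefinition]:
    """Load a tab-separated domain table; rows sharing domain_id merge into
    one multi-segment definition."""
    df = pd.read_csv(StringIO(table_text), sep="\t", dtype=str, comment="#")
    unknown = [c for c in df.columns if c not in _DOMAIN_COLUMNS]
    if unknown:
        logger.warning("domain table: ignoring unknown columns %s", unknown)
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"domain table missing columns: {missing}")
    merged: dict[str, dict] = {}
    for _, row in df.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if start > end:
            raise ValidationError(
                f"domain {row['domain_id']}: segment start {start} > end {end}"
            )
        entry = merged.setdefault(
            row["domain_id"],
            {"family_id": row["family_id"], "pdb_id": row["pdb_id"], "segments": []},
        )
        if entry["family_id"] != row["family_id"]:
            raise ValidationError(
                f"domain {row['domain_id']}: conflicting family ids "
                f"{entry['family_id']!r} vs {row['family_id']!r}"
            )
        entry["segments"].append((str(row["chain"]), start, end))
    return [
        DomainDefinition(
            domain_id=did,
            family_id=entry["family_id"],
            pdb_id=entry["pdb_id"],
            segments=tuple(entry["segments"]),
        )
        for did, entry in merged.items()
    ]


# ---------------------------------------------------------------------------
# Chemistry dictionary and saccharide codes
# ---------------------------------------------------------------------------

@dataclass
class ChemistryDictionary:
    """Editable per-(residue, atom) role flags plus residue-class tables.

    ``roles`` maps (res_name, atom_name) to a frozenset of flags drawn from
    :data:`ROLE_FLAGS`.  Carbon atoms of residues the dictionary knows about
    default to {hydrophobic} when they carry no explicit entry; completely
    unknown (residue, atom) pairs yield the empty set.
    """

    roles: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    water_names: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})
    base_atoms: dict[str, frozenset[str]] = field(default_factory=dict)
    generic_polar_residues: set[str] = field(default_factory=set)

    @property
    def nucleotide_names(self) -> frozenset[str]:
        return frozenset(self.base_atoms)

    def __post_init__(self) -> None:
        self._listed_residues = {res for res, _ in self.roles}

    def known_residue(self, res_name: str) -> bool:
        return (
            res_name in STANDARD_AMINO_ACIDS
            or res_name in MODIFIED_AMINO_ACIDS
            or res_name in self.water_names
            or res_name in self.base_atoms
            or res_name in self.generic_polar_residues
            or res_name in self._listed_residues
        )

    def atom_roles(self, res_name: str, atom_name: str) -> frozenset[str]:
        entry = self.roles.get((res_name, atom_name))
        if entry is not None:
            return entry
        if res_name in self.generic_polar_residues:
            # generic sugar-like chemistry: hydroxyl oxygens donate and
            # accept, ring/amide nitrogens donate
            if atom_name.startswith("O"):
                return frozenset({"donor", "acceptor"})
            if atom_name.startswith("N"):
                return frozenset({"donor"})
        if self.known_residue(res_name) and atom_name.startswith("C"):
            return frozenset({"hydrophobic"})
        return frozenset()

    def register_generic_polar(self, res_names: Iterable[str]) -> None:
        self.generic_polar_residues.update(res_names)

    @classmethod
    def from_text(cls, text: str) -> "ChemistryDictionary":
        roles: dict[tuple[str, str], frozenset[str]] = {}
        water: set[str] = set()
        base_atoms: dict[str, frozenset[str]] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "@water":
                water.update(p.upper() for p in parts[1:])
                continue
            if parts[0] == "@base":
                if len(parts) != 3:
                    raise ValidationError(f"chemistry line {lineno}: bad @base directive")
                base_atoms[parts[1].upper()] = frozenset(parts[2].split(","))
                continue
            if len(parts) != 3:
                raise ValidationError(f"chemistry line {lineno}: expected 'RES ATOM flags'")
            res, atom, flag_field = parts
            flags = frozenset(flag_field.split(","))
            bad = flags - ROLE_FLAGS
            if bad:
                raise ValidationError(f"chemistry line {lineno}: unknown flags {sorted(bad)}")
            if {"positive", "negative"} <= flags:
                raise ValidationError(
                    f"chemistry line {lineno}: atom cannot be both positive and negative"
                )
            roles[(res.upper(), atom.upper())] = flags
        return cls(
            roles=roles,
            water_names=frozenset(water) or frozenset({"HOH", "WAT", "DOD"}),
            base_atoms=base_atoms,
        )

    @classmethod
    def default(cls) -> "ChemistryDictionary":
        text = resources.files("solviface.data").joinpath("chemistry.txt").read_text()
        return cls.from_text(text)


def atom_roles(res_name: str, atom_name: str, dictionary: ChemistryDictionary) -> frozenset[str]:
    """Role flags for one atom; unknown pairs give the empty set."""
    return dictionary.atom_roles(res_name.upper(), atom_name.upper())


@dataclass(frozen=True)
class SaccharideCodeList:
    """Residue codes treated as monosaccharide units."""

    codes: frozenset[str]

    def __contains__(self, code: str) -> bool:
        return code.upper() in self.codes

    @classmethod
    def from_text(cls, text: str) -> "SaccharideCodeList":
        codes = {
            line.strip().upper()
            for line in text.splitlines()
            if line.strip() and not line.strip().startswith("#")
        }
        return cls(codes=frozenset(codes))

    @classmethod
    def default(cls) -> "SaccharideCodeList":
        text = resources.files("solviface.data").joinpath("saccharides.txt").read_text()
        return cls.from_text(text)
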