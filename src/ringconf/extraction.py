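"""Ligand parsing, component bond dictionaries, and carbon-ring detection.

Coordinates come from mmCIF or legacy PDB files; connectivity is taken
from a CCD-style component dictionary rather than perceived from
distances, mirroring how ligand chemistry is defined in the PDB.  Rings
are the chordless 5- and 6-cycles of the component bond graph whose
members are all carbon; classification into cyclohexane / cyclopentane /
benzene then looks only at the ring-internal bond orders and aromatic
flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np

from .errors import FormatError, MissingComponentError, ParseError

__all__ = [
    "AtomRecord", "ComponentBondTable", "RingInstance",
    "parse_structure", "load_component_bonds", "find_carbon_rings",
    "classify_ring_type", "write_ring_pdb", "WATER_NAMES",
]

logger = logging.getLogger(__name__)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_ORDER_MAP = {"SING": "single", "DOUB": "double", "TRIP": "triple",
              "AROM": "aromatic", "SINGLE": "single", "DOUBLE": "double",
              "TRIPLE": "triple", "AROMATIC": "aromatic"}


@dataclass
class AtomRecord:
    """One ligand atom with its provenance."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    chain: str = ""
    residue_number: int = 0
    component_id: str = ""
    entry_id: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] "
                             f"for atom {self.name}")


@dataclass
class ComponentBondTable:
    """Bond list of one chemical component (CCD-style)."""

    component_id: str
    # keyed by frozenset({name1, name2}) -> (order, aromatic_flag)
    bonds: dict = field(default_factory=dict)

    def add_bond(self, a1: str, a2: str, order: str, aromatic: bool) -> None:
        if a1 == a2:
            raise ValueError(f"bond with identical endpoints {a1!r} in "
                             f"{self.component_id}")
        key = frozenset((a1, a2))
        if key in self.bonds:
            raise ValueError(f"duplicate bond {a1}-{a2} in {self.component_id}")
        self.bonds[key] = (order, aromatic)

    def bond(self, a1: str, a2: str):
        """(order, aromatic) for the bond a1-a2, or None if absent."""
        return self.bonds.get(frozenset((a1, a2)))

    @property
    def atom_names(self) -> set:
        names = set()
        for key in self.bonds:
            names |= key
        return names

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for key, (order, aromatic) in self.bonds.items():
            a1, a2 = sorted(key)
            g.add_edge(a1, a2, order=order, aromatic=aromatic)
        return g


@dataclass
class RingInstance:
    """A cyclically ordered 5- or 6-membered all-carbon ring in one ligand."""

    atoms: list            # of AtomRecord, cyclic order
    ring_type: str = "other"

    def __len__(self):
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def serials(self) -> np.ndarray:
        return np.array([a.serial for a in self.atoms])

    @property
    def atom_names(self) -> list:
        return [a.name for a in self.atoms]

    @property
    def provenance(self) -> tuple:
        a = self.atoms[0]
        return (a.entry_id, a.component_id, a.chain, a.residue_number, a.altloc)


def _coor_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    if fmt == "auto":
        return gemmi.CoorFormat.Detect
    if fmt.lower() in ("mmcif", "cif"):
        return gemmi.CoorFormat.Mmcif
    if fmt.lower() == "pdb":
        return gemmi.CoorFormat.Pdb
    raise FormatError(f"unknown coordinate format {fmt!r}")


def parse_structure(path, fmt: str = "auto") -> list:
    """Read a structure file and return its ligand atoms grouped by residue.

    Parameters
    ----------
    path : str or Path to an mmCIF or legacy PDB file.
    fmt : "mmCIF", "PDB" or "auto" (detect from contents/extension).

    Returns
    -------
    list of lists of AtomRecord, one inner list per ligand (HETATM,
    non-water) residue, in file order.  Polymer and water atoms are
    skipped.  Hydrogens are kept in the records but play no role in ring
    detection.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(path, fmt))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    entry_id = (st.name or path.stem).lower()
    groups = []
    if len(st) == 0:
        return groups
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag != "H" or residue.name in WATER_NAMES:
                continue
            records = []
            for atom in residue:
                records.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    altloc=atom.altloc if atom.altloc != "\0" else "",
                    occupancy=atom.occ,
                    chain=chain.name,
                    residue_number=residue.seqid.num,
                    component_id=residue.name,
                    entry_id=entry_id,
                ))
            if records:
                groups.append(records)
    return groups


def load_component_bonds(path) -> dict:
    """Read a CCD-style mmCIF dictionary into per-component bond tables.

    Every row of the _chem_comp_bond category becomes one bond with its
    order (single/double/triple/aromatic) and aromatic flag preserved.

    Returns
    -------
    dict mapping component_id -> ComponentBondTable.
    """
    path = Path(path)
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse dictionary {path}: {exc}") from exc

    tables: dict[str, ComponentBondTable] = {}
    for block in doc:
        rows = block.find("_chem_comp_bond.",
                          ["comp_id", "atom_id_1", "atom_id_2",
                           "value_order", "pdbx_aromatic_flag"])
        for row in rows:
            comp = gemmi.cif.as_string(row[0])
            a1 = gemmi.cif.as_string(row[1])
            a2 = gemmi.cif.as_string(row[2])
            order_raw = gemmi.cif.as_string(row[3]).upper()
            order = _ORDER_MAP.get(order_raw)
            if order is None:
                raise ParseError(
                    f"unknown bond order {order_raw!r} for {comp} in {path}")
            aromatic = gemmi.cif.as_string(row[4]).upper() == "Y"
            table = tables.setdefault(comp, ComponentBondTable(comp))
            try:
                table.add_bond(a1, a2, order, aromatic)
            except ValueError as exc:
                raise ParseError(str(exc)) from exc
    return tables


def require_components(tables: dict, component_ids) -> None:
    """Raise MissingComponentError if any referenced component is absent."""
    missing = [c for c in component_ids if c not in tables]
    if missing:
        raise MissingComponentError(missing)


def _chordless_cycles_5_6(g: nx.Graph) -> list:
    """All chordless cycles of length 5 or 6, each once, in cyclic order."""
    seen = set()
    out = []
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) not in (5, 6):
            continue
        nodes = frozenset(cycle)
        if nodes in seen:
            continue
        # chordless: the induced subgraph has exactly as many edges as atoms
        if g.subgraph(nodes).number_of_edges() != len(cycle):
            continue
        seen.add(nodes)
        out.append(list(cycle))
    return out


def select_altloc(atoms: list, altloc: str = "A") -> list:
    """Keep atoms with blank altloc or the requested alternate location."""
    return [a for a in atoms if a.altloc in ("", altloc)]


def find_carbon_rings(atoms: list, table: ComponentBondTable,
                      altloc: str | None = "A") -> list:
    """Find all-carbon chordless 5/6-rings of one ligand residue.

    The cycle search runs on the dictionary bond graph (authoritative for
    connectivity); the structure supplies elements and coordinates.  Rings
    whose atoms are missing from the structure, or that contain a
    non-carbon, are skipped (with a log message for the former, since that
    indicates a structure/dictionary naming mismatch).

    Parameters
    ----------
    atoms : AtomRecords of a single ligand residue.
    table : the residue's component bond table.
    altloc : alternate-location id to analyse (with blank-altloc atoms);
        None keeps all atoms as given.
    """
    if altloc is not None:
        atoms = select_altloc(atoms, altloc)
    by_name = {a.name: a for a in atoms}
    g = table.graph()
    rings = []
    for cycle in _chordless_cycles_5_6(g):
        missing = [n for n in cycle if n not in by_name]
        if missing:
            logger.warning("ring %s in %s skipped: atoms %s absent from "
                           "structure", cycle, table.component_id, missing)
            continue
        members = [by_name[n] for n in cycle]
        if any(m.element != "C" for m in members):
            continue
        rings.append(RingInstance(atoms=members))
    return rings


def classify_ring_type(ring: RingInstance, table: ComponentBondTable,
                       mode: str = "aromatic_flag") -> str:
    """Classify a ring as cyclohexane, cyclopentane, benzene, or other.

    Only ring-internal bonds are inspected (an exocyclic double bond, as
    in cyclohexanone, does not disqualify a cyclohexane).  In
    "aromatic_flag" mode a six-ring whose bonds all carry the dictionary's
    aromatic flag is benzene.  "paper_replication" mode additionally
    rejects fused aromatics: if any ring atom has an aromatic bond leaving
    the ring (as at the fusion carbons of naphthalene or anthracene), the
    ring is classified "other" — reproducing a workflow that reads the
    Kekulé single/double orders and mistakes fused benzenes for
    cyclohexadienes.
    """
    if mode not in ("aromatic_flag", "paper_replication"):
        raise ValueError(f"unknown classification mode {mode!r}")
    names = ring.atom_names
    n = len(names)
    ring_bonds = []
    for i in range(n):
        b = table.bond(names[i], names[(i + 1) % n])
        if b is None:
            return "other"
        ring_bonds.append(b)

    all_single = all(order == "single" and not aromatic
                     for order, aromatic in ring_bonds)
    all_aromatic = all(aromatic or order == "aromatic"
                       for order, aromatic in ring_bonds)

    if n == 6 and all_single:
        return "cyclohexane"
    if n == 5 and all_single:
        return "cyclopentane"
    if n == 6 and all_aromatic:
        if mode == "paper_replication" and _has_external_aromatic(ring, table):
            return "other"
        return "benzene"
    return "other"


def _has_external_aromatic(ring: RingInstance, table: ComponentBondTable) -> bool:
    members = set(ring.atom_names)
    for key, (order, aromatic) in table.bonds.items():
        if not (aromatic or order == "aromatic"):
            continue
        inside = key & members
        if len(inside) == 1:
            return True
        if len(inside) == 2 and frozenset(inside) != key:
            return True
    return False


def write_ring_pdb(ring: RingInstance, path) -> None:
    """Write one extracted ring as a minimal standalone PDB file."""
    st = gemmi.Structure()
    st.name = ring.atoms[0].entry_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(ring.atoms[0].chain or "A")
    residue = gemmi.Residue()
    residue.name = ring.atoms[0].component_id or "LIG"
    residue.seqid = gemmi.SeqId(ring.atoms[0].residue_number or 1, " ")
    residue.het_flag = "H"
    for rec in ring.atoms:
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.coords)
        atom.occ = rec.occupancy
        atom.serial = int(rec.serial)
        if rec.altloc:
            atom.altloc = rec.altloc
        residue.add_atom(atom)
    chain.add_residue(residue)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
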