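"""Synthetic test data: parametric ring conformers, component
dictionaries, structure files, and density maps with known ground truth.

The conformer generator places ring carbons on a regular N-gon and adds
out-of-plane z displacements.  For each named conformation the
displacement vector was calibrated once (by least squares over the
pipeline: plane fit, C1/C2 ordering, flap angles) so that the computed,
sign-normalized flap angles reproduce the packaged reference table to
well under 0.01 degrees; the calibrated vectors are frozen below.  The
shapes are geometric stand-ins for quantum-chemically optimised rings:
they match the reference conformers in flap-angle space, not bond-angle
by bond-angle.

Density maps are sums of isotropic atom-centred Gaussians plus a low
level of seeded background noise (needed for a stable sigma scale), and
the generator reports the interpolated sigma value at each atom centre
so coverage expectations are directly checkable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .density import DensityMap, interpolate_sigma, write_map
from .extraction import ComponentBondTable

__all__ = [
    "ConformerSpec", "make_conformer", "regular_polygon", "ideal_z",
    "component_table", "naphthalene_like_table", "make_density_map",
    "write_component_dictionary", "write_structure_files",
    "write_fixture_bundle", "CONFORMATIONS", "FIXTURE_Z",
    "COMPONENT_IDS", "DEFAULT_BOND_LENGTH",
]

DEFAULT_BOND_LENGTH = {"cyclohexane": 1.54, "cyclopentane": 1.54,
                       "benzene": 1.39}

COMPONENT_IDS = {"cyclohexane": "CHX", "cyclopentane": "CPN",
                 "benzene": "BNZ"}

CONFORMATIONS = {
    "cyclohexane": ("chair", "half-chair", "boat", "twist-boat", "flat"),
    "cyclopentane": ("half-chair", "envelope", "flat"),
    "benzene": ("flat",),
}

# z displacements (Å) on the regular polygon, calibrated against the
# packaged reference flap-angle table (residuals < 1e-3 degrees).
FIXTURE_Z = {
    ("cyclohexane", "chair"):
        (0.242704, -0.242145, 0.242785, -0.242131, 0.242721, -0.242199),
    ("cyclohexane", "half-chair"):
        (0.418489, -0.378821, 0.169583, 0.128253, -0.198034, -0.139470),
    ("cyclohexane", "boat"):
        (0.529860, -0.204984, -0.292715, 0.466181, -0.299951, -0.198390),
    ("cyclohexane", "twist-boat"):
        (-0.004018, 0.500363, -0.409077, -0.007791, 0.415746, -0.495224),
    ("cyclohexane", "flat"):
        (0.002240, -0.000672, -0.000448, 0.0, 0.001568, -0.002688),
    ("cyclopentane", "half-chair"):
        (0.171878, -0.266466, 0.237876, -0.149497, -0.015393),
    ("cyclopentane", "envelope"):
        (0.386706, -0.131555, 0.192682, 0.227374, -0.065210),
    ("cyclopentane", "flat"):
        (0.001413, -0.000873, 0.0, 0.000873, -0.001413),
    ("benzene", "flat"): (0.0,) * 6,
}

# Textbook displacement patterns (unit scale) for symmetry-based tests:
# alternating chair, same-side prow atoms for the boat, single lifted atom
# for the envelope, and so on.  Not calibrated to the reference table.
IDEAL_Z_PATTERN = {
    ("cyclohexane", "chair"): (1, -1, 1, -1, 1, -1),
    ("cyclohexane", "boat"): (1, -0.5, -0.5, 1, -0.5, -0.5),
    ("cyclohexane", "twist-boat"): (0, 1, -1, 0, 1, -1),
    ("cyclohexane", "half-chair"): (1, -1, 0, 0, 0, 0),
    ("cyclopentane", "envelope"): (1, 0, 0, 0, 0),
    ("cyclopentane", "half-chair"): (0, 0, 1, 0, -1),
}


def regular_polygon(n: int, bond_length: float) -> np.ndarray:
    """Vertices of a planar regular N-gon with the given edge length."""
    radius = bond_length / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)])


def ideal_z(ring_type: str, conformation: str, amplitude: float) -> np.ndarray:
    """Textbook displacement pattern scaled to a given amplitude (Å)."""
    return amplitude * np.asarray(IDEAL_Z_PATTERN[(ring_type, conformation)],
                                  dtype=float)


@dataclass
class ConformerSpec:
    """Recipe for one synthetic ring conformer.

    ``amplitude`` scales the calibrated displacement vector (1.0 keeps
    the calibration; 0.0 makes the ring exactly planar).  ``pose``
    applies a rigid-body transform: None for identity, "random" for a
    seeded uniform rotation plus translation, or an explicit
    ``(rotation_matrix, translation)`` pair.  ``noise_sd`` adds seeded
    isotropic Gaussian coordinate noise in Å.
    """

    ring_type: str
    conformation: str
    bond_length: float | None = None
    amplitude: float = 1.0
    pose: object = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.ring_type not in CONFORMATIONS:
            raise ValueError(f"unknown ring type {self.ring_type!r}")
        if self.conformation not in CONFORMATIONS[self.ring_type]:
            raise ValueError(f"unknown conformation {self.conformation!r} "
                             f"for {self.ring_type}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if self.bond_length is None:
            self.bond_length = DEFAULT_BOND_LENGTH[self.ring_type]

    @property
    def n_atoms(self) -> int:
        return 5 if self.ring_type == "cyclopentane" else 6


def make_conformer(spec: ConformerSpec) -> np.ndarray:
    """Generate (N, 3) ring coordinates in Å for a conformer spec."""
    z = np.asarray(FIXTURE_Z[(spec.ring_type, spec.conformation)])
    coords = regular_polygon(spec.n_atoms, spec.bond_length)
    coords[:, 2] = spec.amplitude * z

    rng = np.random.default_rng(spec.seed)
    if spec.pose == "random":
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-10.0, 10.0, 3)
        coords = coords @ rot.T + shift
    elif spec.pose is not None:
        rot, shift = spec.pose
        coords = coords @ np.asarray(rot).T + np.asarray(shift)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)
    return coords


def atom_names(n: int) -> list:
    return [f"C{i + 1}" for i in range(n)]


def component_table(ring_type: str) -> ComponentBondTable:
    """CCD-style bond table for a plain ring component.

    Cyclohexane/cyclopentane get all-single non-aromatic ring bonds;
    benzene gets the usual Kekulé alternation of single/double orders
    with the aromatic flag set on every bond.
    """
    n = 5 if ring_type == "cyclopentane" else 6
    names = atom_names(n)
    table = ComponentBondTable(COMPONENT_IDS[ring_type])
    for i in range(n):
        a1, a2 = names[i], names[(i + 1) % n]
        if ring_type == "benzene":
            table.add_bond(a1, a2, "double" if i % 2 == 0 else "single", True)
        else:
            table.add_bond(a1, a2, "single", False)
    return table


def naphthalene_like_table(component_id: str = "NPH") -> ComponentBondTable:
    """Fused bicyclic aromatic: 10 carbons, 11 bonds, Kekulé orders.

    Two six-rings (C1..C6 and C1,C6,C7,C8,C9,C10) share the C1-C6 edge.
    All bonds carry the aromatic flag; orders follow one Kekulé structure,
    so one ring shows perfect single/double alternation and the other
    does not — the situation that makes fused benzenes look like
    cyclohexadienes to an order-based filter.
    """
    table = ComponentBondTable(component_id)
    kekule = [("C1", "C2", "double"), ("C2", "C3", "single"),
              ("C3", "C4", "double"), ("C4", "C5", "single"),
              ("C5", "C6", "double"), ("C6", "C1", "single"),
              ("C6", "C7", "single"), ("C7", "C8", "double"),
              ("C8", "C9", "single"), ("C9", "C10", "double"),
              ("C10", "C1", "single")]
    for a1, a2, order in kekule:
        table.add_bond(a1, a2, order, True)
    return table


def naphthalene_like_coords(bond_length: float = 1.39) -> tuple:
    """Planar coordinates and names for the fused 10-carbon fixture."""
    h = bond_length * np.sqrt(3) / 2.0
    half = bond_length / 2.0
    pts = {
        "C1": (0.0, half), "C6": (0.0, -half),
        "C2": (h, bond_length), "C3": (2 * h, half),
        "C4": (2 * h, -half), "C5": (h, -bond_length),
        "C7": (-h, -bond_length), "C8": (-2 * h, -half),
        "C9": (-2 * h, half), "C10": (-h, bond_length),
    }
    names = [f"C{i + 1}" for i in range(10)]
    coords = np.array([[pts[n][0], pts[n][1], 0.0] for n in names])
    return coords, names


def make_density_map(atom_coords: np.ndarray,
                     grid_spacing: float = 0.5,
                     peak_sigma_width: float = 0.9,
                     peak_amplitude: float = 3.0,
                     drop_atoms=(),
                     seed: int = 0,
                     margin: float = 5.0,
                     box=None,
                     noise_level: float = 0.1) -> tuple:
    """Build a Gaussian-atom density map with known sigma statistics.

    A Gaussian of width ``peak_sigma_width`` (Å) is placed at every atom
    centre not listed in ``drop_atoms``; seeded background noise at
    ``noise_level`` times the peak height scale keeps the grid RMS
    nonzero.  The common peak height is iterated so that the smallest
    interpolated sigma value over the kept atoms reaches approximately
    ``peak_amplitude`` (in sigma units).

    Parameters
    ----------
    box : optional explicit orthorhombic cell lengths (3 floats, Å).  All
        atoms must then lie inside [0, box); otherwise the cell is sized
        from the atom bounding box plus ``margin`` on each side.

    Returns
    -------
    (DensityMap, expected_sigma) where ``expected_sigma[i]`` is the
    map's own interpolated sigma value at atom ``i``.
    """
    coords = np.asarray(atom_coords, dtype=float)
    if grid_spacing <= 0 or peak_sigma_width <= 0:
        raise ValueError("grid_spacing and peak_sigma_width must be positive")
    if box is not None:
        lengths = np.asarray(box, dtype=float)
        if np.any(coords < 0) or np.any(coords >= lengths):
            raise ValueError("atoms outside the declared box")
    else:
        extent = coords.max(axis=0) - coords.min(axis=0)
        lengths = extent + 2.0 * margin

    shape = np.maximum(np.ceil(lengths / grid_spacing).astype(int), 2)
    axes = [np.arange(n) * (length / n)
            for n, length in zip(shape, lengths)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid_pts = np.stack([gx, gy, gz], axis=-1)

    kept = [i for i in range(len(coords)) if i not in set(drop_atoms)]
    peaks = np.zeros(tuple(shape))
    for i in kept:
        # minimum-image displacement keeps peaks consistent with wrapping
        d = grid_pts - coords[i]
        d -= np.round(d / lengths) * lengths
        r2 = np.sum(d * d, axis=-1)
        peaks += np.exp(-r2 / (2.0 * peak_sigma_width ** 2))

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, tuple(shape))
    cell = (float(lengths[0]), float(lengths[1]), float(lengths[2]),
            90.0, 90.0, 90.0)

    def build(height):
        return DensityMap(grid=height * peaks + noise_level * noise,
                          cell=cell, periodic=True)

    height = 1.0
    dmap = build(height)
    if kept:
        for _ in range(40):
            vals = [interpolate_sigma(dmap, coords[i]) for i in kept]
            lowest = min(vals)
            if lowest > 0 and abs(lowest - peak_amplitude) < 1e-9:
                break
            if lowest <= 0:
                height *= 2.0
            else:
                height *= peak_amplitude / lowest
            dmap = build(height)
    expected = np.array([interpolate_sigma(dmap, c) for c in coords])
    return dmap, expected


def write_component_dictionary(tables, path) -> None:
    """Write bond tables as a CCD-style mmCIF dictionary file."""
    doc = gemmi.cif.Document()
    for table in tables:
        block = doc.add_new_block(f"comp_{table.component_id}")
        loop = block.init_loop("_chem_comp_bond.",
                               ["comp_id", "atom_id_1", "atom_id_2",
                                "value_order", "pdbx_aromatic_flag"])
        rev = {"single": "SING", "double": "DOUB", "triple": "TRIP",
               "aromatic": "AROM"}
        for key in sorted(table.bonds, key=sorted):
            a1, a2 = sorted(key)
            order, aromatic = table.bonds[key]
            loop.add_row([table.component_id, a1, a2, rev[order],
                          "Y" if aromatic else "N"])
    doc.write_file(str(path))


def _build_structure(entry_id, component_id, coords, names,
                     chain="A", residue_number=1) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = entry_id
    st.cell = gemmi.UnitCell(50, 50, 50, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    res = gemmi.Residue()
    res.name = component_id
    res.seqid = gemmi.SeqId(residue_number, " ")
    res.het_flag = "H"
    for i, (name, pos) in enumerate(zip(names, coords)):
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        atom.occ = 1.0
        atom.serial = i + 1
        res.add_atom(atom)
    ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure_files(entry_id, component_id, coords, names, out_dir,
                          chain="A", residue_number=1) -> tuple:
    """Write one synthetic ligand as both PDB and mmCIF; return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = _build_structure(entry_id, component_id, coords, names,
                          chain, residue_number)
    pdb_path = out_dir / f"{entry_id}.pdb"
    cif_path = out_dir / f"{entry_id}.cif"
    st.write_pdb(str(pdb_path))
    st.make_mmcif_document().write_file(str(cif_path))
    return pdb_path, cif_path


def default_bundle_specs(seed: int = 0) -> list:
    """One randomly posed spec per (ring type, conformation)."""
    specs = []
    i = 0
    for ring_type, confs in CONFORMATIONS.items():
        for conf in confs:
            specs.append(ConformerSpec(ring_type, conf, pose="random",
                                       seed=seed * 1000 + i))
            i += 1
    return specs


def write_fixture_bundle(out_dir, specs=None, resolutions=None,
                         seed: int = 0, with_maps: bool = True) -> dict:
    """Write a self-contained analysis input directory.

    Produces one structure per spec (PDB and mmCIF, entry ids fx01,
    fx02, ...), a shared component dictionary, a resolution table, and —
    optionally — one Gaussian-atom CCP4 map per entry with all ring
    atoms covered.  Deterministic for fixed seeds.

    Returns a manifest dict: entry id -> {spec, expected conformation,
    resolution, paths}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = default_bundle_specs(seed)
    if resolutions is None:
        resolutions = [1.5] * len(specs)
    if len(resolutions) != len(specs):
        raise ValueError("need one resolution per spec")

    dict_path = out_dir / "components.cif"
    tables = [component_table(rt) for rt in CONFORMATIONS]
    write_component_dictionary(tables, dict_path)

    manifest = {}
    rows = [("entry_id", "resolution")]
    for i, (spec, resolution) in enumerate(zip(specs, resolutions)):
        entry_id = f"fx{i + 1:02d}"
        coords = make_conformer(spec)
        names = atom_names(spec.n_atoms)
        pdb_path, cif_path = write_structure_files(
            entry_id, COMPONENT_IDS[spec.ring_type], coords, names,
            out_dir / "structures")
        entry = {"spec": spec, "conformation": spec.conformation,
                 "ring_type": spec.ring_type, "resolution": resolution,
                 "pdb": pdb_path, "cif": cif_path, "dictionary": dict_path}
        if with_maps:
            dmap, expected = make_density_map(coords, seed=seed * 997 + i)
            map_dir = out_dir / "maps"
            map_dir.mkdir(exist_ok=True)
            map_path = map_dir / f"{entry_id}.ccp4"
            write_map(dmap, map_path)
            entry["map"] = map_path
            entry["expected_sigma"] = expected
        manifest[entry_id] = entry
        rows.append((entry_id, str(float(resolution))))

    with open(out_dir / "resolutions.csv", "w", newline="") as fh:
        csv.writer(fh).writerows(rows)
    return manifest
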