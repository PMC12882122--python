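"""Structure parsing, bond dictionaries, ring finding and typing."""

import itertools

import numpy as np
import pytest

from ringconf import fixtures
from ringconf.errors import MissingComponentError, ParseError
from ringconf.extraction import (ComponentBondTable, RingInstance,
                                 classify_ring_type, find_carbon_rings,
                                 load_component_bonds, parse_structure,
                                 require_components, write_ring_pdb)

ALTLOC_PDB = """\
HETATM    1  C1 ALIG A   1       0.000   0.000   0.000  0.60          C
HETATM    2  C1 BLIG A   1       0.300   0.000   0.000  0.40          C
HETATM    3  C2  LIG A   1       1.540   0.000   0.000  1.00          C
END
"""


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("struct")
    spec = fixtures.ConformerSpec("cyclohexane", "chair")
    coords = fixtures.make_conformer(spec)
    names = fixtures.atom_names(6)
    pdb, cif = fixtures.write_structure_files("tst1", "CHX", coords, names,
                                              tmp, chain="B",
                                              residue_number=42)
    return coords, names, pdb, cif


class TestParseStructure:
    def test_pdb_read_back(self, written):
        coords, names, pdb, _ = written
        groups = parse_structure(pdb, fmt="PDB")
        assert len(groups) == 1
        atoms = groups[0]
        assert [a.name for a in atoms] == names
        assert np.allclose([a.coords for a in atoms], coords, atol=1e-3)
        a = atoms[0]
        assert (a.element, a.chain, a.residue_number, a.component_id) == \
            ("C", "B", 42, "CHX")
        assert a.entry_id == "tst1"

    def test_mmcif_matches_pdb_field_for_field(self, written):
        _, _, pdb, cif = written
        from_pdb = parse_structure(pdb, fmt="PDB")[0]
        from_cif = parse_structure(cif, fmt="mmCIF")[0]
        assert len(from_pdb) == len(from_cif)
        for a, b in zip(from_pdb, from_cif):
            assert (a.name, a.element, a.altloc, a.chain,
                    a.residue_number, a.component_id) == \
                (b.name, b.element, b.altloc, b.chain,
                 b.residue_number, b.component_id)
            assert np.allclose(a.coords, b.coords, atol=1e-3)
            assert np.isclose(a.occupancy, b.occupancy)

    def test_altlocs_both_returned(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        atoms = parse_structure(path, fmt="PDB")[0]
        assert len(atoms) == 3
        c1 = [a for a in atoms if a.name == "C1"]
        assert sorted(a.altloc for a in c1) == ["A", "B"]
        assert np.isclose(sum(a.occupancy for a in c1), 1.0)

    def test_garbled_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\nloop_\n_atom_site.id\n'unterminated\n")
        with pytest.raises(ParseError):
            parse_structure(bad, fmt="mmCIF")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ParseError):
            parse_structure(tmp_path / "nope.pdb")


@pytest.fixture(scope="module")
def dictionary(tmp_path_factory):
    path = tmp_path_factory.mktemp("dict") / "components.cif"
    tables = [fixtures.component_table("cyclohexane"),
              fixtures.component_table("benzene"),
              fixtures.naphthalene_like_table()]
    fixtures.write_component_dictionary(tables, path)
    return load_component_bonds(path)


class TestLoadComponentBonds:
    def test_cyclohexane_bonds(self, dictionary):
        table = dictionary["CHX"]
        assert len(table.bonds) == 6
        assert all(order == "single" and not aromatic
                   for order, aromatic in table.bonds.values())

    def test_benzene_bonds_aromatic(self, dictionary):
        table = dictionary["BNZ"]
        assert len(table.bonds) == 6
        assert all(aromatic for _, aromatic in table.bonds.values())
        orders = {order for order, _ in table.bonds.values()}
        assert orders == {"single", "double"}  # Kekulé alternation

    def test_fused_component_counts(self, dictionary):
        table = dictionary["NPH"]
        assert len(table.bonds) == 11
        assert len(table.atom_names) == 10

    def test_missing_component_error(self, dictionary):
        with pytest.raises(MissingComponentError) as err:
            require_components(dictionary, ["CHX", "XYZ"])
        assert "XYZ" in str(err.value)


def _records(coords, names, component_id="LIG"):
    from ringconf.extraction import AtomRecord
    return [AtomRecord(serial=i + 1, name=n, element="C", coords=c,
                       component_id=component_id, entry_id="test",
                       chain="A", residue_number=1)
            for i, (n, c) in enumerate(zip(names, coords))]


def brute_force_cycles(table, lengths=(5, 6)):
    """Exhaustive chordless-cycle enumeration by permutation, as an oracle."""
    names = sorted(table.atom_names)
    found = set()
    for k in lengths:
        for combo in itertools.combinations(names, k):
            for perm in itertools.permutations(combo[1:]):
                cycle = (combo[0],) + perm
                if all(table.bond(cycle[i], cycle[(i + 1) % k])
                       for i in range(k)):
                    edges = sum(1 for a, b in itertools.combinations(cycle, 2)
                                if table.bond(a, b))
                    if edges == k:  # chordless
                        found.add(frozenset(cycle))
                    break
    return found


class TestFindCarbonRings:
    def test_cyclohexane_single_ring(self):
        table = fixtures.component_table("cyclohexane")
        coords = fixtures.make_conformer(
            fixtures.ConformerSpec("cyclohexane", "chair"))
        rings = find_carbon_rings(_records(coords, fixtures.atom_names(6)),
                                  table)
        assert len(rings) == 1
        assert sorted(rings[0].atom_names) == fixtures.atom_names(6)

    def test_fused_pair_matches_brute_force(self):
        table = fixtures.naphthalene_like_table()
        coords, names = fixtures.naphthalene_like_coords()
        rings = find_carbon_rings(_records(coords, names), table)
        got = {frozenset(r.atom_names) for r in rings}
        assert got == brute_force_cycles(table)
        assert len(got) == 2
        shared = set.intersection(*(set(s) for s in got))
        assert shared == {"C1", "C6"}  # one shared edge

    def test_two_separate_rings_in_one_ligand(self):
        table = ComponentBondTable("TWO")
        six = [f"C{i}" for i in range(1, 7)]
        five = [f"C{i}" for i in range(7, 12)]
        for ring in (six, five):
            for i in range(len(ring)):
                table.add_bond(ring[i], ring[(i + 1) % len(ring)],
                               "single", False)
        table.add_bond("C1", "C7", "single", False)
        hexa = fixtures.regular_polygon(6, 1.54)
        penta = fixtures.regular_polygon(5, 1.54) + np.array([8.0, 0, 0])
        records = _records(np.vstack([hexa, penta]), six + five)
        rings = find_carbon_rings(records, table)
        assert sorted(len(r) for r in rings) == [5, 6]

    def test_ring_with_heteroatom_excluded(self):
        table = fixtures.component_table("cyclohexane")
        coords = fixtures.make_conformer(
            fixtures.ConformerSpec("cyclohexane", "chair"))
        records = _records(coords, fixtures.atom_names(6))
        records[2].element = "O"
        assert find_carbon_rings(records, table) == []

    def test_atoms_missing_from_structure_skip_ring(self, caplog):
        table = fixtures.component_table("cyclohexane")
        coords = fixtures.make_conformer(
            fixtures.ConformerSpec("cyclohexane", "chair"))
        records = _records(coords[:5], fixtures.atom_names(6)[:5])
        with caplog.at_level("WARNING"):
            assert find_carbon_rings(records, table) == []
        assert "absent" in caplog.text

    def test_every_ring_is_a_closed_cycle(self):
        table = fixtures.naphthalene_like_table()
        coords, names = fixtures.naphthalene_like_coords()
        for ring in find_carbon_rings(_records(coords, names), table):
            n = len(ring)
            for i in range(n):
                assert table.bond(ring.atom_names[i],
                                  ring.atom_names[(i + 1) % n])

    def test_altloc_default_keeps_a_conformer(self):
        table = fixtures.component_table("cyclohexane")
        coords = fixtures.make_conformer(
            fixtures.ConformerSpec("cyclohexane", "chair"))
        records = _records(coords, fixtures.atom_names(6))
        records[0].altloc = "A"
        dup = _records(coords + 0.4, fixtures.atom_names(6))[0]
        dup.altloc = "B"
        rings = find_carbon_rings(records + [dup], table, altloc="A")
        assert len(rings) == 1
        rings_b = find_carbon_rings(records + [dup], table, altloc="B")
        assert len(rings_b) == 1


class TestClassifyRingType:
    def _ring(self, names, coords=None):
        n = len(names)
        if coords is None:
            coords = fixtures.regular_polygon(n, 1.5)
        return RingInstance(atoms=_records(coords, names))

    def test_benzene_by_aromatic_flag(self):
        table = fixtures.component_table("benzene")
        ring = self._ring(fixtures.atom_names(6))
        assert classify_ring_type(ring, table, "aromatic_flag") == "benzene"

    def test_plain_rings(self):
        for ring_type, n in (("cyclohexane", 6), ("cyclopentane", 5)):
            table = fixtures.component_table(ring_type)
            ring = self._ring(fixtures.atom_names(n))
            assert classify_ring_type(ring, table) == ring_type

    def test_fused_aromatic_omitted_in_replication_mode(self):
        table = fixtures.naphthalene_like_table()
        coords, names = fixtures.naphthalene_like_coords()
        rings = find_carbon_rings(_records(coords, names), table)
        assert len(rings) == 2
        for ring in rings:
            assert classify_ring_type(ring, table,
                                      "paper_replication") == "other"
            assert classify_ring_type(ring, table,
                                      "aromatic_flag") == "benzene"

    def test_exocyclic_double_bond_still_cyclohexane(self):
        table = fixtures.component_table("cyclohexane")
        table.add_bond("C1", "O1", "double", False)
        ring = self._ring(fixtures.atom_names(6))
        assert classify_ring_type(ring, table) == "cyclohexane"

    def test_mixed_orders_are_other(self):
        table = ComponentBondTable("DIE")  # cyclohexadiene-like
        names = fixtures.atom_names(6)
        orders = ["double", "single", "double", "single", "single", "single"]
        for i, order in enumerate(orders):
            table.add_bond(names[i], names[(i + 1) % 6], order, False)
        ring = self._ring(names)
        assert classify_ring_type(ring, table) == "other"

    def test_invariant_to_ring_rotation_and_reflection(self):
        table = fixtures.component_table("benzene")
        names = fixtures.atom_names(6)
        coords = fixtures.regular_polygon(6, 1.39)
        expected = classify_ring_type(self._ring(names, coords), table)
        for start in range(6):
            for step in (1, -1):
                idx = [(start + step * i) % 6 for i in range(6)]
                ring = self._ring([names[i] for i in idx], coords[idx])
                assert classify_ring_type(ring, table) == expected


def test_ring_pdb_export_roundtrip(tmp_path):
    table = fixtures.component_table("cyclopentane")
    coords = fixtures.make_conformer(
        fixtures.ConformerSpec("cyclopentane", "envelope"))
    ring = find_carbon_rings(_records(coords, fixtures.atom_names(5),
                                      component_id="CPN"), table)[0]
    out = tmp_path / "ring.pdb"
    write_ring_pdb(ring, out)
    atoms = parse_structure(out, fmt="PDB")[0]
    assert sorted(a.name for a in atoms) == sorted(ring.atom_names)
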