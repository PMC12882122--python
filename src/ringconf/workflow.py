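"""End-to-end orchestration: structures + dictionary (+ maps, resolutions)
-> classified, coverage-annotated report rows.

Thin glue over the stage modules; each stage remains usable on its own.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import density, extraction, ordering, pucker, report

logger = logging.getLogger(__name__)

__all__ = ["analyze_ring", "extract_rings", "analyze_structure"]

TARGET_RING_TYPES = ("cyclohexane", "cyclopentane", "benzene")


def analyze_ring(ring):
    """Order a ring, compute its flap angles, and classify it.

    Returns ``(theta, assignment)`` with theta sign-normalized, in
    degrees.
    """
    ordered = ordering.order_ring(ring.coords, ring.serials)
    params = pucker.normalize_sign(pucker.compute_parameters(ordered))
    assignment = pucker.classify(params, ring.ring_type)
    return params.theta, assignment


def extract_rings(structure_path, bond_tables, fmt="auto",
                  mode="aromatic_flag", altloc="A",
                  keep_other=False) -> list:
    """Extract and type-classify the carbon rings of every ligand.

    ``bond_tables`` is the mapping returned by
    `extraction.load_component_bonds`.  Ligands whose component is not in
    the dictionary are skipped with a log message.  Rings classified
    "other" are dropped unless ``keep_other``.
    """
    groups = extraction.parse_structure(structure_path, fmt)
    rings = []
    for atoms in groups:
        comp = atoms[0].component_id
        table = bond_tables.get(comp)
        if table is None:
            logger.warning("component %s absent from dictionary; ligand "
                           "%s skipped", comp, atoms[0].entry_id)
            continue
        for ring in extraction.find_carbon_rings(atoms, table, altloc=altloc):
            ring.ring_type = extraction.classify_ring_type(ring, table, mode)
            if ring.ring_type in TARGET_RING_TYPES or keep_other:
                rings.append(ring)
    return rings


def analyze_structure(structure_path, dictionary_path, map_path=None,
                      resolution=None, fmt="auto", mode="aromatic_flag",
                      altloc="A",
                      threshold_sigma=density.DEFAULT_THRESHOLD_SIGMA) -> list:
    """Run the full analysis for one structure file.

    Returns a list of `report.RingReportRow`.  Without a map, coverage
    fields are zero/false and the ring cannot be flagged as supported.
    """
    bond_tables = extraction.load_component_bonds(dictionary_path)
    rings = extract_rings(structure_path, bond_tables, fmt=fmt, mode=mode,
                          altloc=altloc)
    dmap = density.load_map(map_path) if map_path is not None else None
    rows = []
    for ring in rings:
        theta, assignment = analyze_ring(ring)
        coverage = (density.ring_coverage(ring, dmap, threshold_sigma)
                    if dmap is not None else None)
        rows.append(report.build_row(ring, theta, assignment, coverage,
                                     resolution))
    return rows


def analyze_bundle(structure_paths, dictionary_path, map_paths=None,
                   resolution_table=None, **kwargs) -> list:
    """Analyse several structures; map_paths/resolutions matched by entry id.

    ``map_paths`` maps entry id -> CCP4 file; ``resolution_table`` maps
    entry id -> Å (see `report.read_resolution_table`).
    """
    map_paths = map_paths or {}
    resolution_table = resolution_table or {}
    rows = []
    for path in structure_paths:
        entry_id = Path(path).stem.lower()
        rows.extend(analyze_structure(
            path, dictionary_path,
            map_path=map_paths.get(entry_id),
            resolution=resolution_table.get(entry_id),
            **kwargs))
    return rows
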