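"""Per-ring report rows, experimental-support flags, and summary tables.

A ring conformation counts as supported by experimental data when the
structure was refined at 2.0 Å resolution or better (inclusive) and
every ring atom is covered by electron density at the chosen sigma
threshold.  Summaries count conformations per ring type, with
occurrence percentages relative to the ring-type total (also for the
supported subset) and subtotals for energetically favourable versus
unfavourable conformations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import ResolutionTableError
from .pucker import FAVOURABLE, RING_TYPES, reference_conformers

__all__ = ["RingReportRow", "is_supported", "build_row", "aggregate_report",
           "write_csv", "read_csv", "read_resolution_table",
           "RESOLUTION_CUTOFF", "CSV_COLUMNS"]

RESOLUTION_CUTOFF = 2.0

CSV_COLUMNS = ["entry_id", "component_id", "chain", "residue_number",
               "altloc", "ring_type", "atom_names",
               "theta_1", "theta_2", "theta_3",
               "conformation", "distance_deg", "unfavourable",
               "resolution_A", "atoms_covered", "all_covered", "supported"]


@dataclass
class RingReportRow:
    """One analysed ring with its classification and support evidence."""

    entry_id: str
    component_id: str
    chain: str
    residue_number: int
    altloc: str
    ring_type: str
    atom_names: list
    theta: list
    conformation: str
    distance: float
    energetically_unfavourable: bool
    resolution: float | None
    atoms_covered: int
    all_covered: bool
    supported: bool
    missing_metadata: bool = False


def is_supported(resolution: float | None, coverage) -> bool:
    """True iff resolution <= 2.0 Å (inclusive) and all ring atoms covered.

    ``coverage`` may be a CoverageResult or a plain boolean all-covered
    flag.  A missing resolution makes the ring unsupported.
    """
    all_covered = getattr(coverage, "all_covered", coverage)
    if resolution is None:
        return False
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    return bool(resolution <= RESOLUTION_CUTOFF and all_covered)


def build_row(ring, theta, assignment, coverage=None,
              resolution=None) -> RingReportRow:
    """Assemble a report row from the pieces the pipeline produced."""
    entry_id, component_id, chain, residue_number, altloc = ring.provenance
    n_cov = int(coverage.covered.sum()) if coverage is not None else 0
    all_cov = bool(coverage.all_covered) if coverage is not None else False
    return RingReportRow(
        entry_id=entry_id, component_id=component_id, chain=chain,
        residue_number=residue_number, altloc=altloc,
        ring_type=ring.ring_type, atom_names=list(ring.atom_names),
        theta=[float(t) for t in np.asarray(theta)],
        conformation=assignment.name,
        distance=float(assignment.distance),
        energetically_unfavourable=assignment.energetically_unfavourable,
        resolution=resolution, atoms_covered=n_cov, all_covered=all_cov,
        supported=is_supported(resolution, all_cov) if resolution else False,
        missing_metadata=resolution is None,
    )


def _pct(part: int, whole: int) -> float:
    if whole == 0:
        return 0.0
    frac = Decimal(part) / Decimal(whole) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aggregate_report(rows) -> pd.DataFrame:
    """Summarise report rows per ring type and conformation.

    For each ring type the table lists every observed conformation with
    its count and occurrence percentage (relative to the ring-type
    total), the same restricted to supported rings, then favourable and
    unfavourable subtotals and the ring-type total.  Percentages are
    rounded half-up to two decimals; on an empty input the table is
    empty.
    """
    records = []
    rows = list(rows)
    for ring_type in RING_TYPES:
        sub = [r for r in rows if r.ring_type == ring_type]
        total = len(sub)
        if total == 0:
            continue
        total_supported = sum(r.supported for r in sub)
        known = [rc.name for rc in reference_conformers(ring_type)]
        conf_order = list(dict.fromkeys(
            known + sorted({r.conformation for r in sub})))
        for conf in conf_order:
            group = [r for r in sub if r.conformation == conf]
            if not group:
                continue
            n_sup = sum(r.supported for r in group)
            records.append((ring_type, conf, len(group), _pct(len(group), total),
                            n_sup, _pct(n_sup, total)))
        fav = [r for r in sub if not r.energetically_unfavourable]
        unf = [r for r in sub if r.energetically_unfavourable]
        for label, group in (("favourable", fav), ("unfavourable", unf)):
            n_sup = sum(r.supported for r in group)
            records.append((ring_type, f"energetically {label}", len(group),
                            _pct(len(group), total), n_sup, _pct(n_sup, total)))
        records.append((ring_type, "total", total, _pct(total, total),
                        total_supported, _pct(total_supported, total)))
    return pd.DataFrame(records, columns=[
        "ring_type", "conformation", "count_all", "pct_all",
        "count_supported", "pct_supported"])


def _row_to_csv(row: RingReportRow) -> list:
    theta = list(row.theta) + [""] * (3 - len(row.theta))
    return [row.entry_id, row.component_id, row.chain, row.residue_number,
            row.altloc, row.ring_type, ",".join(row.atom_names),
            *[("" if t == "" else repr(float(t))) for t in theta],
            row.conformation, repr(float(row.distance)),
            row.energetically_unfavourable,
            "" if row.resolution is None else repr(float(row.resolution)),
            row.atoms_covered, row.all_covered, row.supported]


def write_csv(rows, path) -> None:
    """Write report rows as CSV with a fixed column order.

    The atom-name list is a comma-joined field and is quoted by the CSV
    writer; floats are written with full precision so a read-back
    reproduces the rows exactly.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for row in rows:
            writer.writerow(_row_to_csv(row))


def read_csv(path) -> list:
    """Read back a report CSV written by `write_csv`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_COLUMNS:
            raise ResolutionTableError(
                f"unexpected report columns in {path}: {reader.fieldnames}")
        for rec in reader:
            theta = [float(rec[f"theta_{i}"]) for i in (1, 2, 3)
                     if rec[f"theta_{i}"] != ""]
            resolution = float(rec["resolution_A"]) if rec["resolution_A"] else None
            out.append(RingReportRow(
                entry_id=rec["entry_id"], component_id=rec["component_id"],
                chain=rec["chain"], residue_number=int(rec["residue_number"]),
                altloc=rec["altloc"], ring_type=rec["ring_type"],
                atom_names=rec["atom_names"].split(","), theta=theta,
                conformation=rec["conformation"],
                distance=float(rec["distance_deg"]),
                energetically_unfavourable=rec["unfavourable"] == "True",
                resolution=resolution,
                atoms_covered=int(rec["atoms_covered"]),
                all_covered=rec["all_covered"] == "True",
                supported=rec["supported"] == "True",
                missing_metadata=resolution is None,
            ))
    return out


def read_resolution_table(path) -> dict:
    """Read a two-column (entry_id, resolution in Å) CSV into a dict.

    A header row is accepted and skipped.  Duplicate entry ids are an
    error: resolution is a per-entry property and conflicting values
    would silently corrupt support flags.
    """
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for i, rec in enumerate(csv.reader(fh)):
            if not rec or (i == 0 and rec[0].strip().lower() == "entry_id"):
                continue
            entry = rec[0].strip().lower()
            if entry in table:
                raise ResolutionTableError(
                    f"duplicate entry id {entry!r} in {path}")
            table[entry] = float(rec[1])
    return table
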