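"""Electron-density maps, trilinear interpolation, and atom coverage.

An atom is "covered" by electron density when the map value interpolated
at its centre, expressed in sigma units (RMS deviation about the grid
mean), exceeds a threshold — 1.5 sigma by default, a contour level
commonly used in molecular viewers.  A ring is fully covered when every
ring atom is.  Interpolation is the trilinear blend of the eight grid
nodes surrounding the atom centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import MapFormatError, OutOfBoundsError

__all__ = ["DensityMap", "CoverageResult", "load_map", "write_map",
           "interpolate_sigma", "ring_coverage", "DEFAULT_THRESHOLD_SIGMA"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_SIGMA = 1.5


@dataclass
class DensityMap:
    """A density grid covering the full unit cell in canonical X,Y,Z order.

    ``grid[i, j, k]`` samples the point with fractional coordinates
    ``(i/nx, j/ny, k/nz)``.  Maps that cover only a box within the cell
    are stored padded with NaN; interpolation touching the padding raises
    OutOfBoundsError.  ``mean`` and ``rms`` are computed over the finite
    grid values and define the sigma scale.
    """

    grid: np.ndarray
    cell: tuple                    # (a, b, c, alpha, beta, gamma)
    periodic: bool = True
    mean: float = field(init=False)
    rms: float = field(init=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 nodes per axis")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size == 0:
            raise ValueError("grid has no finite values")
        self.mean = float(finite.mean())
        self.rms = float(np.sqrt(np.mean((finite - self.mean) ** 2)))
        if self.rms <= 0:
            raise ValueError("grid is constant; sigma scale undefined")
        a, b, c, al, be, ga = self.cell
        self._frac_mat = np.array(
            gemmi.UnitCell(a, b, c, al, be, ga).frac.mat.tolist())

    def fractionalize(self, position) -> np.ndarray:
        return self._frac_mat @ np.asarray(position, dtype=float)


@dataclass
class CoverageResult:
    """Per-atom sigma values and coverage flags for one ring."""

    values_sigma: np.ndarray
    covered: np.ndarray
    all_covered: bool
    threshold_sigma: float


def load_map(path) -> DensityMap:
    """Read a CCP4/MRC map file.

    The grid is reordered to canonical X,Y,Z axis order and, for
    crystallographic maps, expanded to the full unit cell; regions the
    file does not cover become NaN and make the map non-periodic.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    periodic = bool(np.all(np.isfinite(grid)))
    return DensityMap(grid=grid,
                      cell=(cell.a, cell.b, cell.c,
                            cell.alpha, cell.beta, cell.gamma),
                      periodic=periodic)


def write_map(dmap: DensityMap, path) -> None:
    """Write a DensityMap as a standard CCP4 map file (P1, full cell)."""
    g = gemmi.FloatGrid(*dmap.grid.shape)
    g.set_unit_cell(gemmi.UnitCell(*dmap.cell))
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    np.array(g, copy=False)[:] = dmap.grid.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def interpolate_sigma(dmap: DensityMap, position) -> float:
    """Sigma-scaled trilinear interpolation at a Cartesian position (Å).

    The eight grid nodes around the position are blended with trilinear
    weights; the result is ``(value - mean) / rms``.  Crystallographic
    (periodic) maps wrap the position into the cell; touching an
    uncovered (NaN) node of a box map raises OutOfBoundsError.
    """
    shape = np.array(dmap.grid.shape)
    t = dmap.fractionalize(position) * shape
    if dmap.periodic:
        t = np.mod(t, shape)
        i0 = np.floor(t).astype(int) % shape
        i1 = (i0 + 1) % shape
    else:
        if np.any(t < -1e-9) or np.any(t > shape - 1 + 1e-9):
            raise OutOfBoundsError(
                f"position {np.asarray(position)} outside non-periodic map")
        t = np.clip(t, 0, shape - 1)
        i0 = np.minimum(np.floor(t).astype(int), shape - 2)
        i1 = i0 + 1
    f = t - np.floor(t) if dmap.periodic else t - i0

    value = 0.0
    for dx, wx in ((0, 1 - f[0]), (1, f[0])):
        for dy, wy in ((0, 1 - f[1]), (1, f[1])):
            for dz, wz in ((0, 1 - f[2]), (1, f[2])):
                node = dmap.grid[
                    i1[0] if dx else i0[0],
                    i1[1] if dy else i0[1],
                    i1[2] if dz else i0[2],
                ]
                value += wx * wy * wz * node
    if not np.isfinite(value):
        raise OutOfBoundsError(
            f"position {np.asarray(position)} touches uncovered map region")
    return (value - dmap.mean) / dmap.rms


def ring_coverage(ring, dmap: DensityMap,
                  threshold_sigma: float = DEFAULT_THRESHOLD_SIGMA,
                  strict: bool = False) -> CoverageResult:
    """Evaluate per-atom density coverage of a ring.

    An atom is covered iff its interpolated sigma value is strictly
    greater than the threshold.  Interpolation failures (atom outside a
    box map) mark the atom as not covered and are logged, unless
    ``strict`` re-raises them.

    Parameters
    ----------
    ring : RingInstance or (N, 3) coordinate array.
    dmap : the density map.
    threshold_sigma : contour level in sigma units (default 1.5).
    """
    coords = ring.coords if hasattr(ring, "coords") else np.asarray(ring, float)
    values = np.full(len(coords), np.nan)
    covered = np.zeros(len(coords), dtype=bool)
    for i, pos in enumerate(coords):
        try:
            values[i] = interpolate_sigma(dmap, pos)
        except OutOfBoundsError:
            if strict:
                raise
            logger.warning("atom %d of ring outside map; marked not covered", i)
            continue
        covered[i] = values[i] > threshold_sigma
    return CoverageResult(values_sigma=values, covered=covered,
                          all_covered=bool(covered.all()),
                          threshold_sigma=threshold_sigma)
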