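"""Choice of the initial (C1) and following (C2) ring atoms.

Hill-Reilly flap angles are defined for a ring whose atoms carry a fixed
sequence.  Heterocycles inherit that sequence from the heteroatom; a
homocyclic carbon ring has no such anchor, so the sequence is derived from
the ring geometry itself:

1. fit a plane to the ring carbons (orthogonal least squares),
2. take the signed distance SD of each carbon from the plane,
3. for each ring bond compute the neighbour deviation
   ``SDdev(x, x+1) = |SD(x) - SD(x+1)|`` and for each carbon the sum of its
   two neighbour deviations ``SDsum(x)``,
4. the carbon with the largest SDsum becomes the initial atom C1, and the
   neighbour of C1 with the larger SDdev becomes the following atom C2.

Because SDdev/SDsum use absolute differences they do not depend on which
side of the plane is called "above"; any deterministic orientation of the
plane normal gives the same C1/C2.  Ties (a perfect chair or a flat ring
makes every SDsum equal) are broken by the lowest file serial so that
repeated runs produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["PlaneFit", "OrderedRing", "fit_plane", "compute_sd_statistics",
           "select_initial_following", "order_ring"]

#: Two SDsum/SDdev values closer than this (Å) are treated as tied.
TIE_TOLERANCE = 1e-9


@dataclass
class PlaneFit:
    """Best-fit plane of a ring plus the derived per-atom SD statistics.

    ``sd_dev[i]`` is the deviation for the bond between ring positions
    ``i`` and ``i+1`` (cyclic); ``sd_sum[i]`` is the sum of the two
    deviations involving position ``i``.
    """

    normal: np.ndarray
    centroid: np.ndarray
    sd: np.ndarray
    sd_dev: np.ndarray | None = None
    sd_sum: np.ndarray | None = None


@dataclass
class OrderedRing:
    """A ring re-indexed so that C1 is first and traversal runs toward C2."""

    coords: np.ndarray          # (N, 3), re-indexed
    indices: np.ndarray         # permutation into the input ordering
    origin_index: int           # index of C1 in the input ordering
    direction: int              # +1 or -1 traversal sense in the input ordering
    serials: np.ndarray = field(default=None)  # re-indexed serials, if given


def fit_plane(coords: np.ndarray) -> PlaneFit:
    """Fit the least-squares plane through ring coordinates.

    The plane passes through the centroid and its normal minimises the sum
    of squared perpendicular distances (smallest principal axis of the
    centred coordinates).  The normal sign is fixed so that the first atom
    with a nonzero signed distance lies on the positive side.

    Parameters
    ----------
    coords : (N, 3) array of Cartesian coordinates in Å, N in {5, 6}.

    Raises
    ------
    DegenerateGeometryError
        If the points are collinear or coincident, so no unique plane exists.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError(f"expected (N, 3) coordinates with N >= 3, got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")

    centroid = coords.mean(axis=0)
    centered = coords - centroid
    # Smallest right singular vector = direction of least variance = normal.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] <= 1e-10 * scale:
        raise DegenerateGeometryError("ring atoms are collinear or coincident")
    normal = vt[2]
    sd = centered @ normal
    # Deterministic orientation: first nonzero SD is positive.
    nz = np.nonzero(np.abs(sd) > TIE_TOLERANCE)[0]
    if nz.size and sd[nz[0]] < 0:
        normal = -normal
        sd = -sd
    return PlaneFit(normal=normal, centroid=centroid, sd=sd)


def compute_sd_statistics(plane: PlaneFit) -> PlaneFit:
    """Fill the cyclic neighbour deviations SDdev and per-atom sums SDsum."""
    sd = plane.sd
    plane.sd_dev = np.abs(sd - np.roll(sd, -1))
    plane.sd_sum = plane.sd_dev + np.roll(plane.sd_dev, 1)
    return plane


def _argmax_with_tiebreak(values: np.ndarray, serials: np.ndarray) -> int:
    """Index of the maximum; near-ties resolved by lowest serial."""
    best = values.max()
    tied = np.nonzero(values >= best - TIE_TOLERANCE)[0]
    return int(tied[np.argmin(serials[tied])])


def select_initial_following(plane: PlaneFit,
                             serials: np.ndarray | None = None) -> tuple[int, int]:
    """Pick the positions of C1 (max SDsum) and C2 (C1's higher-SDdev neighbour).

    Returns ``(i1, direction)`` where ``i1`` indexes C1 in the input cyclic
    order and ``direction`` is +1 if C2 is at ``i1 + 1`` or -1 if at
    ``i1 - 1``.
    """
    if plane.sd_sum is None:
        compute_sd_statistics(plane)
    n = len(plane.sd)
    if serials is None:
        serials = np.arange(n)
    serials = np.asarray(serials)

    i1 = _argmax_with_tiebreak(plane.sd_sum, serials)
    # sd_dev[i] belongs to the bond (i, i+1): the bond toward the successor
    # of C1 is sd_dev[i1], the bond toward the predecessor is sd_dev[i1-1].
    dev_next = plane.sd_dev[i1]
    dev_prev = plane.sd_dev[(i1 - 1) % n]
    if dev_next > dev_prev + TIE_TOLERANCE:
        direction = 1
    elif dev_prev > dev_next + TIE_TOLERANCE:
        direction = -1
    else:  # tie: lower serial neighbour wins
        s_next = serials[(i1 + 1) % n]
        s_prev = serials[(i1 - 1) % n]
        direction = 1 if s_next <= s_prev else -1
    return i1, direction


def sd_statistics_table(plane: PlaneFit, serials=None):
    """SD/SDdev/SDsum per ring position as a DataFrame (debug dump).

    Handy for plotting the selection procedure; write with
    ``table.to_csv(path, index=False)``.
    """
    import pandas as pd

    if plane.sd_sum is None:
        compute_sd_statistics(plane)
    n = len(plane.sd)
    return pd.DataFrame({
        "position": np.arange(n),
        "serial": np.arange(n) if serials is None else np.asarray(serials),
        "sd": plane.sd,
        "sd_dev_next": plane.sd_dev,
        "sd_sum": plane.sd_sum,
    })


def order_ring(coords: np.ndarray,
               serials: np.ndarray | None = None) -> OrderedRing:
    """Run the full C1/C2 selection and return the re-indexed ring.

    Convenience wrapper: plane fit, SD statistics, C1/C2 choice, and the
    rotation/reflection of the input cycle that puts C1 first travelling
    toward C2.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if serials is None:
        serials = np.arange(n)
    serials = np.asarray(serials)

    plane = compute_sd_statistics(fit_plane(coords))
    i1, direction = select_initial_following(plane, serials)
    indices = (i1 + direction * np.arange(n)) % n
    return OrderedRing(
        coords=coords[indices],
        indices=indices,
        origin_index=i1,
        direction=direction,
        serials=serials[indices],
    )
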