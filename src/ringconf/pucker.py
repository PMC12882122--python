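"""Hill-Reilly flap angles and conformer classification.

A monocyclic N-ring is decomposed into a central reference triangle and
N - 3 flap triangles hinged on its edges.  For a six-ring ordered
C1..C6 the reference plane passes through C2, C4, C6 and the flaps are
(C2, C3, C4), (C4, C5, C6) and (C6, C1, C2), giving flap angles with
apices C3, C5 and C1 in that order; for a five-ring C1..C5 the reference
plane passes through C1, C2, C4 and the flaps are (C2, C3, C4) and
(C4, C5, C1), with apices C3 and C5.  This assignment is the one that
reproduces the published reference angle table for all nine conformers
(chair exactly; the crude single-amplitude shapes land within a few
degrees elsewhere).  Each flap angle theta_j is the signed dihedral
between the flap plane and the reference plane about their shared hinge;
a flap apex on the positive side of the oriented reference normal gives a
positive angle.

Mirror-inverted rings produce sign-flipped angle vectors.  Enantiomers are
not distinguished here, so the vector is sign-normalized: if the last
angle is negative the whole vector is negated.  Classification assigns
the nearest reference conformer by Euclidean distance in theta space.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from .ordering import OrderedRing

__all__ = [
    "PuckerParameters", "ReferenceConformer", "ConformationAssignment",
    "compute_parameters", "normalize_sign", "classify",
    "load_reference_table", "reference_conformers", "FAVOURABLE",
]

# Reference-plane atom positions and (hinge_start, apex, hinge_end) flap
# triples, as 0-based indices into the ordered ring (C1 = index 0).
_DECOMPOSITION = {
    6: {"reference": (1, 3, 5), "flaps": ((1, 2, 3), (3, 4, 5), (5, 0, 1))},
    5: {"reference": (0, 1, 3), "flaps": ((1, 2, 3), (3, 4, 0))},
}

#: Conformations that are low-energy for the unsubstituted ring.  Everything
#: else counts as energetically unfavourable.
FAVOURABLE = {
    "cyclohexane": {"chair"},
    "cyclopentane": {"half-chair", "envelope"},
    "benzene": {"flat"},
}

RING_TYPES = ("cyclohexane", "cyclopentane", "benzene")


@dataclass
class PuckerParameters:
    """N - 3 flap angles in degrees, optionally sign-normalized."""

    theta: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass(frozen=True)
class ReferenceConformer:
    ring_type: str
    name: str
    theta_ref: tuple


@dataclass
class ConformationAssignment:
    name: str
    distance: float
    runner_up: str | None
    runner_up_distance: float | None
    energetically_unfavourable: bool


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise DegenerateGeometryError(f"degenerate {what}: collinear atoms")
    return v / n


def compute_parameters(ring: OrderedRing | np.ndarray) -> PuckerParameters:
    """Compute the (unnormalized) Hill-Reilly flap angles of an ordered ring.

    Parameters
    ----------
    ring : OrderedRing or (N, 3) array
        Ring coordinates already sequenced C1, C2, ... by `ordering.order_ring`.

    Returns
    -------
    PuckerParameters with ``theta`` in degrees, in flap order
    (theta1, theta2, theta3) for six-rings or (theta1, theta2) for
    five-rings, each in (-180, 180].
    """
    coords = ring.coords if isinstance(ring, OrderedRing) else np.asarray(ring, float)
    n = coords.shape[0]
    if n not in _DECOMPOSITION:
        raise ValueError(f"ring size must be 5 or 6, got {n}")
    scheme = _DECOMPOSITION[n]

    r1, r2, r3 = (coords[i] for i in scheme["reference"])
    n_ref = _unit(np.cross(r2 - r1, r3 - r1), "reference plane")

    theta = []
    for a, apex, b in scheme["flaps"]:
        hinge = _unit(coords[b] - coords[a], "hinge")
        n_flap = _unit(np.cross(coords[apex] - coords[a], coords[b] - coords[a]),
                       "flap plane")
        # Both normals are perpendicular to the hinge (its endpoints lie in
        # the reference plane), so this is the dihedral about the hinge.
        angle = np.degrees(np.arctan2(np.dot(np.cross(n_ref, n_flap), hinge),
                                      np.dot(n_ref, n_flap)))
        theta.append(angle)
    return PuckerParameters(theta=np.array(theta), normalized=False)


def normalize_sign(p: PuckerParameters) -> PuckerParameters:
    """Negate the whole angle vector if its last component is negative.

    Removes the mirror-image sign ambiguity; idempotent.
    """
    theta = p.theta if p.theta[-1] >= 0 else -p.theta
    return PuckerParameters(theta=theta, normalized=True)


def load_reference_table(path=None) -> pd.DataFrame:
    """Load the reference conformer table (packaged constants by default).

    The table is columnar text with columns ring_type, conformation,
    theta1..theta3 (theta3 blank for five-rings).  A user-supplied file with
    the same layout can override the packaged one, e.g. to extend the
    method to other ring types.
    """
    if path is None:
        ref = importlib.resources.files("ringconf") / "data" / "reference_conformers.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"ring_type", "conformation", "theta1", "theta2"}
    if not required.issubset(table.columns):
        raise ValueError(f"reference table missing columns {required - set(table.columns)}")
    return table


_REFERENCE_CACHE: dict = {}


def reference_conformers(ring_type: str, table: pd.DataFrame | None = None
                         ) -> list[ReferenceConformer]:
    """Candidate reference conformers for a ring type, in table row order.

    Benzene is nominally restricted to the flat conformation; to let
    distorted "benzenes" be described, the candidate set is expanded with
    the four cyclohexane conformers (chair, half-chair, boat, twist-boat)
    at their standard parameters.
    """
    if ring_type not in RING_TYPES:
        raise ValueError(f"unknown ring type {ring_type!r}")
    cache_key = ring_type if table is None else None
    if cache_key is not None and cache_key in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[cache_key]
    if table is None:
        table = load_reference_table()

    def rows_for(rt):
        sub = table[table.ring_type == rt]
        out = []
        for _, row in sub.iterrows():
            theta = [row.theta1, row.theta2]
            if not pd.isna(row.get("theta3", np.nan)):
                theta.append(row.theta3)
            out.append(ReferenceConformer(rt, row.conformation, tuple(theta)))
        return out

    refs = rows_for(ring_type)
    if ring_type == "benzene":
        refs += [r for r in rows_for("cyclohexane") if r.name != "flat"]
    if cache_key is not None:
        _REFERENCE_CACHE[cache_key] = refs
    return refs


def classify(p: PuckerParameters, ring_type: str,
             table: pd.DataFrame | None = None) -> ConformationAssignment:
    """Assign the nearest reference conformation by Euclidean theta distance.

    ``p`` should be sign-normalized; ties are broken by reference table
    row order.  The unfavourable flag marks conformations that are
    transition states or high-energy forms for the unsubstituted ring.
    """
    if not p.normalized:
        p = normalize_sign(p)
    refs = reference_conformers(ring_type, table)
    dims = {len(r.theta_ref) for r in refs}
    if dims != {len(p.theta)}:
        raise ValueError(
            f"parameter dimension {len(p.theta)} does not match references {dims}")
    dists = [float(np.linalg.norm(p.theta - np.asarray(r.theta_ref))) for r in refs]
    order = sorted(range(len(refs)), key=lambda i: (dists[i], i))
    best = order[0]
    second = order[1] if len(order) > 1 else None
    return ConformationAssignment(
        name=refs[best].name,
        distance=dists[best],
        runner_up=refs[second].name if second is not None else None,
        runner_up_distance=dists[second] if second is not None else None,
        energetically_unfavourable=refs[best].name not in FAVOURABLE[ring_type],
    )
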