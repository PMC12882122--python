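"""Compute Hill-Reilly flap angles for ideal ring conformers.

Builds each calibrated synthetic conformer, runs the plane-fit atom
ordering and the flap-angle computation, and prints the sign-normalized
angles next to the packaged reference values.  Matching rows mean the
geometry generator and the angle pipeline agree on what "chair",
"boat", etc. look like in flap-angle space.
"""

import numpy as np

from ringconf import compute_parameters, normalize_sign, order_ring
from ringconf.fixtures import CONFORMATIONS, ConformerSpec, make_conformer
from ringconf.pucker import reference_conformers

for ring_type, confs in CONFORMATIONS.items():
    refs = {r.name: r.theta_ref for r in reference_conformers(ring_type)}
    for conf in confs:
        coords = make_conformer(ConformerSpec(ring_type, conf,
                                              pose="random", seed=1))
        theta = normalize_sign(compute_parameters(order_ring(coords))).theta
        print(f"{ring_type:12s} {conf:10s} "
              f"theta = {np.round(theta, 1)}  reference = {refs[conf]}")
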