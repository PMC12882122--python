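"""Decide electron-density coverage of a ring from a CCP4 map.

Builds a Gaussian-atom density map for a chair cyclohexane, removes the
peak of one atom, and evaluates per-atom coverage at the 1.5-sigma
contour.  The sigma values are the map density interpolated at each atom
centre in units of the map's RMS deviation; an atom is covered when its
value exceeds the threshold, and one missing peak makes the ring not
fully covered.
"""

import numpy as np

from ringconf import ring_coverage
from ringconf.fixtures import ConformerSpec, make_conformer, make_density_map

coords = make_conformer(ConformerSpec("cyclohexane", "chair"))

for drop, label in [((), "all atoms have density"),
                    ({2}, "atom C3's peak removed")]:
    dmap, _ = make_density_map(coords, peak_amplitude=3.0, drop_atoms=drop,
                               seed=4)
    cov = ring_coverage(coords, dmap, threshold_sigma=1.5)
    print(f"{label}:")
    print(f"  sigma values = {np.round(cov.values_sigma, 2)}")
    print(f"  covered      = {cov.covered.tolist()}")
    print(f"  all covered  = {cov.all_covered}")
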