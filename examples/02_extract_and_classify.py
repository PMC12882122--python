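"""Extract rings from a structure file and classify their conformation.

Writes a small synthetic ligand (a twist-boat cyclohexane) as a PDB file
plus its component dictionary, re-reads both, finds the carbon ring from
the dictionary bond graph, and assigns the nearest reference
conformation.  The printed distance is the Euclidean distance in
flap-angle space (degrees): small means a confident assignment.
"""

import tempfile
from pathlib import Path

import numpy as np

from ringconf import analyze_ring, extract_rings, load_component_bonds
from ringconf.fixtures import (ConformerSpec, atom_names, component_table,
                               make_conformer, write_component_dictionary,
                               write_structure_files)

tmp = Path(tempfile.mkdtemp())
coords = make_conformer(ConformerSpec("cyclohexane", "twist-boat",
                                      pose="random", seed=3))
pdb, _ = write_structure_files("demo", "CHX", coords, atom_names(6), tmp)
write_component_dictionary([component_table("cyclohexane")],
                           tmp / "components.cif")

bonds = load_component_bonds(tmp / "components.cif")
for ring in extract_rings(pdb, bonds):
    theta, assignment = analyze_ring(ring)
    print(f"{ring.ring_type} ring {'-'.join(ring.atom_names)}:")
    print(f"  theta = {np.round(theta, 1)} deg")
    print(f"  conformation = {assignment.name} "
          f"(distance {assignment.distance:.2f} deg, runner-up "
          f"{assignment.runner_up} at {assignment.runner_up_distance:.2f})")
    print(f"  energetically unfavourable = "
          f"{assignment.energetically_unfavourable}")
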