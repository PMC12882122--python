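# ringconf

Conformational analysis of cyclohexane, cyclopentane and benzene rings in
the ligands of macromolecular crystal structures.

Ligand rings in deposited structure models are not always in the shape the
experimental data say they are: a cyclohexane refined flat, or a "benzene"
in a chair, usually signals wrong restraints or an annotation error rather
than real chemistry.  `ringconf` detects the carbocyclic 5- and 6-rings of
ligand residues, quantifies each ring's pucker with Hill–Reilly flap
angles, assigns the nearest named conformation, and checks whether that
assignment is *supported by experimental data*: the structure must be
refined at ≤ 2 Å resolution and every ring atom must be covered by
electron density at a σ contour.  It is written for structural
bioinformaticians and model validators working with PDB-style inputs
(mmCIF/PDB coordinates, CCD-style component dictionaries, CCP4/MRC maps).

## Method

For a ring of *N* carbons the analysis runs in four stages:

1. **Ring extraction.** Connectivity comes from the component dictionary
   (never from distances).  Chordless cycles of length 5 or 6 whose members
   are all carbon are kept, and typed from the ring-internal bonds: all
   single → cyclohexane/cyclopentane, all aromatic → benzene, anything
   else → other.
2. **Atom ordering.** Flap angles need a starting atom (C1) and a
   direction (C2).  A least-squares plane is fitted through the ring
   carbons, each carbon gets a signed distance *SD* from it, and for
   neighbouring carbons

   SDdev(x, x+1) = |SD(x) − SD(x+1)|,  SDsum(x) = SDdev(x−1, x) + SDdev(x, x+1).

   C1 is the carbon with the largest SDsum; C2 is the neighbour of C1 with
   the larger SDdev (ties broken by lowest serial).
3. **Flap angles.** The ring is decomposed into a central reference
   triangle and *N* − 3 flaps.  For 6-rings the reference plane passes
   through C2, C4, C6 with flap apices C3, C5, C1; for 5-rings through
   C1, C2, C4 with apices C3, C5.  θ<sub>j</sub> is the signed dihedral
   between flap and reference plane about their shared hinge.  Because
   mirror images only flip signs, the vector is normalized (negated if the
   last θ is negative) and the nearest reference conformer by Euclidean
   distance in θ-space is assigned.  Distorted "benzenes" are compared
   against the cyclohexane conformers too.
4. **Experimental support.** Map values are interpolated trilinearly at
   each atom centre, expressed in σ units ((ρ − mean)/rms over the grid),
   and compared to a threshold (default 1.5 σ, strict `>`).  A ring is
   supported iff resolution ≤ 2.0 Å and all atoms are covered.

Reference flap angles (degrees), shipped as package data:

| ring | conformation | θ1 | θ2 | θ3 |
|------|--------------|------|------|------|
| cyclohexane | chair | 32.2 | 32.2 | 32.2 |
| cyclohexane | half-chair | 16.1 | −20.9 | 53.0 |
| cyclohexane | boat | −30.8 | −31.7 | 64.4 |
| cyclohexane | twist-boat | −0.7 | −57.4 | 58.2 |
| cyclohexane | flat | 0.1 | −0.0 | 0.4 |
| cyclopentane | half-chair | −33.2 | 36.2 | |
| cyclopentane | envelope | −25.9 | 40.7 | |
| cyclopentane | flat | −0.2 | 0.2 | |
| benzene | flat | 0.0 | 0.0 | 0.0 |

## Worked example

`examples/02_extract_and_classify.py` writes a twist-boat cyclohexane as
a PDB file with its dictionary, then extracts and classifies it:

```
cyclohexane ring C1-C2-C3-C4-C5-C6:
  theta = [ -0.7 -57.4  58.2] deg
  conformation = twist-boat (distance 0.05 deg, runner-up boat at 40.07)
  energetically unfavourable = True
```

The θ vector lands on the twist-boat reference row to 0.05°, far from the
runner-up, and the conformation is flagged energetically unfavourable
(for unsubstituted cyclohexane only the chair is a low-energy minimum in
this bookkeeping; for cyclopentane, half-chair and envelope; for benzene,
flat).  The other examples cover flap angles for every conformer
(`01`), σ coverage with a deliberately missing density peak (`03`), and
the full bundle workflow with the summary table (`04`).

The same stages are available from a shell:

```sh
ringconf fixtures bundle --seed 7
ringconf analyze bundle/structures/*.pdb -d bundle/components.cif \
    --map-dir bundle/maps --resolutions bundle/resolutions.csv -o report.csv
ringconf report report.csv
```

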