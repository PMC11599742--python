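# lipshell

Annular-lipid shell analysis of membrane-protein crystal structures.

Microbial rhodopsins (seven-transmembrane, retinal-binding pumps and sensors
such as bacteriorhodopsin) are the best-resolved family of membrane proteins,
and their crystal structures routinely contain dozens of partially modeled
lipid fragments — branched archaeal phytanyl chains, linear bacterial or
host-lipid acyl chains, carotenoids, squalene, detergents — hugging the
protein's hydrophobic surface. `lipshell` turns the ad-hoc bookkeeping needed
to study that first shell of *annular lipids* into a tested, reusable
pipeline:

* a curated dictionary of the three-letter chemical-component codes used to
  model lipids in rhodopsin structures, with a geometric branched-vs-linear
  chain classifier (C–C bond graph at a 1.9 Å threshold);
* structure reading (PDB/mmCIF via gemmi), content partitioning into
  protein / retinal / lipid / solvent / other-HET, and an atom-selection
  mini-language (`chain A and resname L2P and resnum 270 and name
  O2+C2+C3+C12-C21+C41-C45+C47-C60`) matching the way published selections
  are printed;
* Kabsch least-squares superposition on backbone + retinal or on helical Cα
  atoms (RMSD = min_R,t sqrt(1/n Σᵢ ‖xᵢ − (R yᵢ + t)‖²)), membrane-frame
  assignment with the z-origin at the bilayer median, and a fallback
  hydrophobic-belt slab estimator for the boundary planes;
* annular-shell extraction (a lipid residue belongs to the shell of a
  protomer iff any heavy atom lies within 5 Å of a protein heavy atom),
  per-atom nearest-surface distance statistics d̄ ± s, and location labels
  (inner-compartment / inter-protomer / peripheral) for lipids in oligomers;
* bilayer-depth profiles: histograms of lipid-carbon and noble-gas atom
  depths between the boundaries, with moving-average mode detection;
* per-protomer lipid censuses kept as exact rationals (2 glycolipids in a
  trimer render as "2/3") and derived trimer lipid budgets;
* a fully deterministic synthetic-scene generator (C3 trimer of idealized
  helix bundles, lipid chains planted at exact nearest-surface distances,
  noble-gas depths drawn from a Gaussian mixture) so every stage is testable
  without downloading anything.

## Worked example

```python
import numpy as np
from lipshell import (assign_frame, classify_location, depths_of, extract_shell,
                      lipid_census, make_histogram, nearest_surface_distances,
                      partition, trimer_lipid_budget)
from lipshell.synth import GasMixtureSpec, LipidSpec, SceneSpec, build_scene

spec = SceneSpec(seed=42, lipids=(
    LipidSpec(location="inner_compartment", lipid_class="archaeal_diphytanyl", d0=4.0),
    LipidSpec(location="inter_protomer", d0=4.0),
    LipidSpec(location="peripheral", d0=4.0),
), gas=GasMixtureSpec(n_atoms=2000))
scene, truth = build_scene(spec)

frame = assign_frame(scene, estimate=True)
part = partition(scene)

shell = extract_shell(scene, ["A", "B", "C"], cutoff=5.0)
summary = nearest_surface_distances(part.lipid, part.protein)
print(f"mean = {summary.mean:.2f} +/- {summary.sd:.2f} A over {summary.n_atoms} atoms")

for key, atoms in part.lipid.by_residue().items():
    print(key.residue_name, key.residue_number,
          classify_location(atoms, scene, frame, part=part).label)

gas = scene.atoms.filter(lambda a: a.element == "KR")
print("gas modes (A):", make_histogram(depths_of(gas, frame), frame, bin_width=2.0).modes)
print("budget:", trimer_lipid_budget(28, extra_per_protomer=1))
```

prints

```
mean = 4.39 +/- 0.41 A over 48 atoms
L2P 201 inner_compartment
OLC 202 inter_protomer
OLC 203 peripheral
gas modes (A): (-11.0, 1.0, 9.0)
budget: 87
```

All three planted lipids are in the 5 Å shell at their exact planted
nearest-approach distance of 4.0 Å; the location labels reproduce the planted
ground truth; the three gas depth modes land within one 2 Å bin of the
mixture means (−10, 0, +10); and a trimer carrying 28 annular fragments per
protomer plus one retinal-site molecule per protomer needs 3 × (28 + 1) = 87
lipid placements.

The same stages are available from the shell:

```sh
lipshell simulate --seed 42 --out scene.pdb
lipshell shell    --input scene.pdb --chains A,B,C --out shell.tsv
lipshell locate   --input scene.pdb --boundaries -16 16 --out locations.json
lipshell zprofile --input scene.pdb --boundaries -16 16 --gas-element KR --out profile.json
lipshell census   --input scene.pdb --n-protomers 3 --out census.json
```

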