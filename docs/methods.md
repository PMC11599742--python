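# Methods

This note documents the models, conventions and parameter choices behind
`lipshell`, and what the synthetic tests do and do not demonstrate about real
crystallographic data.

## Component dictionary and chain geometry

Deposited rhodopsin models represent lipids and amphiphiles as HET residues
under three-letter chemical-component codes. The shipped table
(`src/lipshell/data/lipid_components.tsv`) classifies 39 such codes into
eight classes: `archaeal_diphytanyl` (L2P, L3P, L4P, PH1, ARC),
`isoprenoid_squalene` (SQL, SQU), `carotenoid` (SXN),
`sugar_headgroup_fragment` (GLC, MAN, NAG, SGA), `detergent` (CPS),
`small_amphiphile_or_cryo` (GOL, PCA), `linear_acyl` (the remainder), and
`unknown` for anything unlisted. Class assignments follow standard
chemical-component definitions where those are unambiguous; where a code's
chemistry is debatable (e.g. DPG), the shipped default is `linear_acyl` and
the table is data, overridable per run via an extension TSV rather than code.
Classification is total: well-formed unlisted codes map to `unknown`, never
to an error; malformed identifiers (wrong length or characters) are rejected.

Branched (phytanyl-like) versus linear (acyl-like) chains are distinguished
geometrically: carbon–carbon bonds are inferred at a 1.9 Å distance
threshold — generous around the 1.53 Å covalent distance to absorb
refinement noise, while staying well below the ≥ 2.5 Å 1–3 separation of sp³
chains — and a *branch point* is a carbon bonded to at least three other
carbons. A residue is `branched` iff it has ≥ 1 branch point and ≥ 4 carbons;
below 4 carbons the verdict is `undetermined`. The production path finds
bonded pairs with a k-d tree; the test suite checks it against an exhaustive
O(n²) oracle and verifies invariance under rigid motion and atom-order
permutation.

## Structure model

Parsing is delegated to gemmi (PDB and mmCIF). Conventions:

* **Altlocs**: the highest-occupancy conformer is kept per atom name; ties go
  to altloc "A".
* **Models**: the first model only (crystal structures).
* **Hydrogens**: retained but flagged; every downstream geometric operation
  uses heavy atoms only, because the analysed structures are X-ray models
  whose printed distances are between modeled heavy atoms.
* **Numbering**: author residue numbering throughout; the selection grammar
  is 1-based with inclusive name ranges (`C12-C21` is ten names).

Partitioning assigns each residue to exactly one of five buckets: protein
(tabulated amino acids, including modified ones), retinal (`RET`), lipid
(component code classifying to any lipid class other than `unknown` or
`small_amphiphile_or_cryo` — sugars and detergents deliberately count, since
glycolipid and detergent fragments are part of the amphiphile shell), solvent
(waters), and other-HET (cryo agents, ions, unlisted codes). The partition is
a disjoint cover of all retained atoms, asserted on every fixture.

Assembly expansion applies deposited operators or explicit transforms
(convenience constructor for C3 about the global z axis); generated copies
receive fresh chain identifiers.

## Superposition and the membrane frame

Optimal rigid superposition is the SVD-based Kabsch algorithm with the usual
determinant correction; Horn's closed-form quaternion method is implemented
independently and the two are cross-checked to 1e-9 on a thousand random
instances. Fewer than three correspondence points, or collinear point sets,
raise an under-determination error rather than returning an arbitrary
rotation. Structure-level correspondences pair backbone N/CA/C/O atoms on
shared (chain, residue-number) keys plus retinal atoms on shared names, with
a residue-number-only fallback when chain identifiers differ between entries.
Helix-restricted RMSD uses deposited helix annotations by default (real
entries rarely print their helix ranges) or an explicit range list.

The membrane frame carries a unit normal, a z-origin at the bilayer median,
and boundary depths `z_lower < 0 < z_upper`. Boundary planes are expected as
*input* (they come from dedicated hydrophobic-boundary methods, which this
package deliberately does not reimplement); the z-origin is the midpoint of
the supplied boundaries. Two estimators exist for when no boundaries are
available:

* **Normal**: the dominant eigenvector of the orientation tensor of Cα
  i → i+4 displacement vectors (the local α-helix rise direction). A plain
  principal axis of the coordinates fails for trimers, which are wider than
  they are tall; the rise-vector tensor stays aligned with the helix axes
  regardless of the assembly's aspect ratio. Segments with implausible rise
  (outside 3–9 Å over four residues) are ignored.
* **Boundaries** (fallback, used for synthetic tests): slide a slab of width
  24–36 Å along the normal maximizing (hydrophobic − polar) Cα count inside,
  with Kyte–Doolittle > 0 defining hydrophobic; ties prefer the tighter slab.
  Requires ≥ 50 protein residues. On synthetic bundles with a planted ±16 Å
  belt the estimate lands within 2 Å; on real proteins this is a coarse
  stand-in for a proper boundary calculation and is labelled as such in
  outputs.

Frames co-transform with structures (depth of every atom is preserved under
a common rigid motion), which is how a reference frame is transferred to
other entries after superposition.

## Annular shell, distances, locations

* **Shell rule**: a lipid residue belongs to a protomer's annular shell iff
  at least one heavy atom lies within the cutoff (default 5.0 Å — the one
  cutoff the source analyses state) of any protein heavy atom of that
  protomer. The boundary is inclusive; members are sorted by minimum
  distance. Shells are monotone in the cutoff and invariant under global
  rigid motion.
* **Surface distances**: per lipid heavy atom, the distance to the nearest
  protein heavy atom. "Hydrophobic surface" is operationalized as *all*
  protein heavy atoms by default; a stricter apolar variant (C and S atoms
  only) is available behind a flag, and the spread is reported as the sample
  standard deviation (n−1) with a population-sd flag. Published distance
  means rarely state either convention, so both variants are first-class.
  The nearest-neighbour query runs on a k-d tree, but each reported distance
  is recomputed from the matched pair with the plain elementwise formula, so
  results are bit-identical to an exhaustive all-pairs scan (asserted in the
  tests). Occupancy-weighted atoms count as unit atoms: distances, not
  densities, are analysed.
* **Location labels**: protomers with any protein heavy atom within the
  contact cutoff (default 4.5 Å) of the lipid are *contacts*. A lipid with
  ≥ 2 contacts whose membrane-plane centroid projection falls inside the
  polygon of protomer centroids is `inner_compartment`; ≥ 2 contacts
  otherwise is `inter_protomer`; anything else `peripheral`. Monomeric
  assemblies yield `peripheral` with a warning. The 4.5 Å contact cutoff is
  a design choice (slightly inside the 5 Å shell cutoff) that reproduces the
  qualitative placements of known glycolipid and inter-protomer lipids with
  a testable geometric rule.

## Depth profiles

Depth is the signed projection onto the membrane normal minus the bilayer
median. The lipid profile counts *carbon* atoms of lipid residues whose
nearest protein heavy atom is within the proximity cutoff (default 5.0 Å,
reusing the shell cutoff) and whose depth lies within the boundaries; polar
headgroup atoms outside the slab are excluded by construction. Gas profiles
count all atoms of the requested element. Histograms use uniform bins
(default 2 Å) spanning exactly the boundary slab; an empty depth list is an
all-zero histogram, not an error. Modes are local maxima of the
moving-average-smoothed counts (window default 3 bins — the minimal smoothing
that passes the synthetic mode-recovery property), with plateaus attributed
to their lowest-depth bin. No kernel density estimation: the binned counts
are the analysed object.

## Census and budgets

A lipid *fragment* is one HET residue classifying to a lipid class;
multi-residue lipids are not merged, matching the granularity at which
deposited models are counted. Cryo agents and unknown codes are excluded from
lipid counts but tallied separately. Per-protomer values are exact
`Fraction`s so that totals reconstruct exactly under symmetry expansion and
render in the conventional style ("2/3", "10/3"). The trimer budget is
`n_protomers × (per_protomer + extra_per_protomer)`; with 28 annular
fragments and one retinal-site molecule per protomer across three protomers
this is 87.

## Synthetic scenes

The generator emulates the statistical structure the pipeline measures, not
protein physics:

* an idealized α-helical bundle (Cα spiral: 1.5 Å rise, 100°/residue, 2.3 Å
  radius; N/C/O placed on offset spirals; Cβ pseudo-atoms radially outward),
  7 helices of 22 residues by default on a 10 Å bundle circle, with leucines
  inside the planted ±16 Å hydrophobic belt and serines outside, and a
  15-carbon retinal-like polyene in the core;
* a C3 trimer built by exact symmetry operators; the protomer ring radius is
  *solved* so that an on-axis inner-compartment chain's nearest approach to
  each protomer equals its target d₀ (inner chains are kept straight and
  unbranched because any lateral decoration breaks the three-fold symmetry
  that makes them equidistant from all protomers);
* lipid chains placed by root-finding, not sampling: rigid placement slides
  the ideal chain along a ray until its *minimum* distance to the protein
  heavy atoms equals d₀ exactly; surface-tracking placement (default for
  linear peripheral chains) slides each atom independently so *every* atom
  sits at d₀ — the idealization of an annular chain hugging the surface —
  at the cost of mildly distorted bond geometry. Inter-protomer chains are
  additionally equalized between the two flanking protomers by bisection on
  the placement azimuth. Per-atom Gaussian jitter is applied after exact
  placement. Branched chains carry methyl carbons on every 4th internal
  backbone carbon (phytanyl-like);
* noble-gas atoms on a cylinder just outside the protein with depths drawn
  from a stated Gaussian mixture (defaults: weights 0.3/0.4/0.3, means
  −10/0/+10 Å, σ 3 Å — a bilayer core component flanked by two interface
  layers).

Scenes are deterministic: identical specs (seed included) regenerate
byte-identical PDB fixtures, and ground truth (frame, solved radius,
per-lipid labels and distances, mixture parameters) is returned and written
as a JSON sidecar.

What passing synthetic tests shows: the geometry code (shells, distances,
labels, depths, censuses, superposition) is correct against independent
oracles and planted ground truth. What it does not show: anything about
crystallographic reality — disorder, partial occupancy, alternate
conformations, non-ideal helices, crystal contacts, or the chemistry of real
lipid fragments. The published-value checks on real PDB entries cover that
end; they require the entries to be present under `data/pdb/` or
downloadable.

## Numerical choices and degenerate inputs

* C–C bond threshold 1.9 Å; shell cutoff 5.0 Å (inclusive); contact cutoff
  4.5 Å; proximity cutoff 5.0 Å; bin width 2.0 Å; smoothing window 3 bins;
  all configurable.
* Root-finding tolerances: 1e-12 Å on placement distances (hence planted
  minimum distances are exact to well below 1e-9 Å).
* Superposition requires n ≥ 3 non-collinear points; collinearity is detected
  on the second singular value.
* Empty selections warn but are legal; empty atom sets in distance
  computations raise; an empty depth list yields a zero histogram; an
  all-zero histogram has no modes.
* Ties: altloc ties go to "A"; plateau modes to the lower depth; slab-search
  ties to the tighter slab; shell ordering ties broken by residue key.

## Known limitations

* Boundary estimation is a hydrophobic-belt heuristic, not an anisotropic
  solvation model; for real entries externally computed boundaries should be
  supplied.
* The location rule is purely geometric; it does not distinguish
  crystal-contact lipids from biologically placed ones.
* The component dictionary covers the codes observed in rhodopsin
  structures; other families will need extension tables.
* Multi-residue lipids (e.g. a glycolipid modeled as sugar rings plus
  separate chains) are counted as separate fragments by design.
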