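# Methods

`hydromoment` profiles how hydrophobicity is distributed between the
buried core and the solvent-exposed surface of a globular protein.  This
note records the model, the numerical choices, and what the synthetic
test fixtures do and do not show.

## The second-order hydrophobic moment

For a chain of N_r residues with centroids **r**_i and centre of mass
**r**_CM = (1/N_r) Σ **r**_i, the per-residue second-order (quadrupole-
like) hydrophobic moment of a residue subset is

    H2 = (1/n_p) Σ_i h'_i d_i² ,

where d_i = |**r**_i − **r**_CM| and h'_i is the residue's hydrophobicity
standardised over the whole chain (mean 0, sd 1).  The subset at cutoff
p collects every residue whose percentage solvent accessibility is ≤ p,
so sweeping p from 0 to 100% grows a "shell" from the completely buried
core outward.  Hydrophobic-core-dominated sets give H2 > 0; as polar
surface residues (large d, negative h') accumulate, the profile turns
negative.  The transition point p\* is the smallest cutoff from which H2
is negative at every later grid point ("vanishes and stays negative"); a
first-negative-crossing rule is available as an option.  d̄\* is the mean
centroid distance over **all** residues collected at p\* (not only those
added near p\*).

The default cutoff grid is 0%, then 1, 3, 5, … 99% (2% resolution), then
100%.  Grid points that have collected no residue are reported as
undefined (NaN), never as zero.  Relative accessibilities above 100%
(possible for strained conformations) are not clamped; the 100% grid
point uses a closed top bin so the final set is always the whole chain.

## Solvent accessibility

Per-atom accessible areas are computed Shrake–Rupley style: each atom's
sphere is inflated by the probe radius (default 1.4 Å), sampled with a
deterministic golden-section spiral lattice (default 960 points — no
random numbers, so results are bit-reproducible), and a lattice point is
accessible when outside every neighbour's inflated sphere.  Neighbour
recovery is exact, via a KD-tree queried at the maximal contact
distance.  An independent Monte-Carlo surface-sampling oracle (random
points instead of the lattice) and the spherical-cap closed form for two
intersecting spheres validate the engine to within 1% in the test suite;
doubling the lattice density changes whole-structure totals by < 0.5%.

Relative accessibility follows the extended-tripeptide convention:
p = 100 · ASA(X, folded) / ASA(X, Gly-X-Gly).  The reference
conformation is built programmatically: ideal backbone geometry
(Engh–Huber-style bonds/angles) with all φ = ψ = ω = 180°, side chains
taken from idealised residue templates rigidly fitted to each N/CA/C
frame (an extended rotamer), carbonyl oxygens placed from internal
coordinates, and a terminal OXT on the last residue.  The flanking
glycines supply the steric screening that defines the standard "extended
state" reference.  The package computes its own 20-entry reference table
at analysis time (`reference_mode = "computed"`); a published ASC-derived
table is packaged as an alternative (`"published"`), and the two agree
within 8% for every residue type (mean deviation ≈ 2.7%).

## Hydrophobicity scales

Two independent per-residue scales:

* **Consensus** — the Eisenberg consensus value per residue type
  (packaged table).
* **Charge-derived** — h = (ASA_apo − ASA_po)/(ASA_apo + ASA_po), with an
  atom polar when |q| ≥ threshold (defaults sweep 0.25, 0.27, 0.3 e).
  Bounded in [−1, 1].  Residues with zero accessible area carry no
  surface evidence and get h = 0 (kept in the moment sums) — this is the
  regime where the denominator makes the scale unreliable anyway.

Both scales are standardised per protein with the **sample** standard
deviation (n − 1); the population variant differs only by the global
factor √(n/(n−1)).  Per-protein standardisation makes h' composition-
dependent by design.  Partial charges come from a packaged united-atom
(extended-atom, CHARMM19-style) protein charge table defined on heavy
atoms — the natural choice for hydrogen-free crystal structures, and the
one under which aliphatic carbons are apolar at every threshold while
carbonyl/amide/hydroxyl groups are polar.  Internal-residue charges are
used at chain termini (no terminal patches).  Van der Waals radii are a
Chothia/NACCESS-style united-atom set; both tables are plain TSV package
data and selectable by name.

## Shape metrics

The gyration tensor T = (1/N_r) Σ (**r**_i−**r**_CM)(**r**_i−**r**_CM)ᵀ is
computed over residue centroids (geometric mean of heavy-atom
coordinates by default; mass-weighted optional).  Its ascending
eigenvalues α₁ ≤ α₂ ≤ α₃ give the asphericity δ = 1 − 3(α₁α₂ + α₂α₃ +
α₁α₃)/(Σα)², the shape parameter S = 27 Π(αᵢ−ᾱ)/(Σα)³, semiaxes
a = √(5(α₁+α₂)/2), b = √(5α₃), and R_g² = Σαᵢ (trace identity, asserted
on every input).  Distance distributions use 10 equal-width bins over
[0, max d] with a right-closed final bin; the fluctuation summary
d̄ ± δd is the sample mean ± sample standard deviation of the distance
set, with the histogram mode reported alongside (the breadth measure is
not uniquely defined by the convention this reproduces; the sample sd is
the most defensible estimator for the near-Gaussian unimodal
distributions observed).  Flory fits are ordinary least squares of
log R_g on log N; the exponent is undefined (NaN, with a warning) when
all chains have equal length.

## Synthetic data

`make_globule` emulates the statistical geometry the analysis assumes:
residues sampled uniformly inside an ellipsoid sized for a compact-
protein density (≈165 Å³/residue, giving realistic R_g for a given N), a
minimum centre separation of 3.6 Å, natural residue-type frequencies,
and hydrophobic types (consensus h > 0) committed to the innermost radial
positions at rate `core_fraction`.  Each residue is a single 3.0 Å
pseudo-sphere carrying an override radius/charge (polar pseudo-charge
0.55 e for consensus-hydrophilic types, 0.05 e otherwise), so SASA,
charge thresholds and both scales remain meaningful without side chains;
the fully-exposed reference for pseudo-residues is the isolated-sphere
area.  Fixtures are written as genuine PDB files so the whole
parse → SASA → moments pipeline is exercised end to end.

What the generator does **not** emulate: chain connectivity, secondary
structure, side-chain packing, and realistic atom-level surface texture.
Passing synthetic tests therefore demonstrates the correctness of the
geometry, accessibility and moment machinery and the qualitative
positive-to-negative H2 profile of a hydrophobic-core globule — not
quantitative agreement with any particular crystal structure, which
requires real PDB input.

## Numerical and design choices

* Sphere lattice 960 points: isolated-sphere areas are exact by
  construction; cluster areas agree with the Monte-Carlo oracle to < 1%.
* Alternate locations resolve to highest occupancy (ties: first
  conformer); insertion-coded residues keep author order; hydrogens,
  waters, ligands and non-standard residues are excluded (non-standard
  with a logged warning).
* The polar/apolar split partitions each residue's area exactly by
  construction (same atom partition).
* A polar-atom threshold that classifies every atom identically makes
  the charge-derived scale constant; standardisation then raises a
  degenerate-scale error rather than producing a meaningless profile.
* Profile Pearson correlations standardise both H2 series over grid
  points first; Pearson's R is invariant to this (asserted in a test),
  so the step is kept purely for procedural fidelity.
* Problem sizes in the test suite (globules of 50–400 residues, clusters
  of 5–30 atoms, 480–960 lattice points) are chosen so the whole suite
  runs in well under a minute of compute per module while every
  tolerance above is still meaningfully exercised.

## Known limitations

* Reproduction of published per-structure numbers (shape rows, moment
  profiles, transition points of the fifteen-chain study set) requires
  the corresponding PDB entries under `data/structures/`; they are not
  redistributed with the package, and the related acceptance tests fail
  with an explicit message until the files are supplied.
* Exact ASC program defaults (radius set, point density) behind the
  published reference ASA values are not reproducible; the computed
  reference therefore carries the ±8% tolerance above.
* mmCIF input, NMR ensembles, biological assemblies and Connolly
  (molecular) surfaces are out of scope.
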