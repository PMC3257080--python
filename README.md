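# hydromoment

Second-order hydrophobic moment analysis of globular protein structures.

Globular proteins bury hydrophobic residues in their core and expose
hydrophilic ones to solvent.  `hydromoment` quantifies that radial
organisation for structural bioinformaticians and protein biophysicists:
starting from a PDB coordinate file it computes, per chain,

* **solvent accessibility** — Shrake–Rupley accessible surface areas
  (deterministic golden-spiral lattice, 1.4 Å probe), converted to
  percentage accessibility *p* against programmatically built extended
  Gly-X-Gly tripeptide references, p = 100·ASA(X, folded)/ASA(X, G-X-G);
* **two hydrophobicity scales** — the Eisenberg consensus scale, and a
  charge-derived scale h = (ASA_apo − ASA_po)/(ASA_apo + ASA_po) in which
  atoms are polar when their partial-charge magnitude meets a threshold
  (0.25 / 0.27 / 0.3 e), both standardised per protein;
* **the spatial moment profile** — the quadrupole-like per-residue moment
  H₂(p) = (1/n_p) Σ h′ᵢ dᵢ² over the n_p residues with accessibility ≤ p
  (dᵢ = distance from the centre of mass to residue i's centroid), the
  hydrophobic→hydrophilic transition point p\* where the profile settles
  negative, and Pearson correlations between the two scales' profiles;
* **shape descriptors** — gyration-tensor eigenvalues, asphericity δ,
  shape parameter S, semiaxes, R_g, distance distributions W(d), and
  Flory scaling fits R_g ∝ N^ν across protein sets.

A synthetic-globule generator produces PDB fixtures with a
hydrophobic-in/hydrophilic-out composition gradient so the entire
pipeline is testable without downloading any structure.

## Worked example

Generate a 120-residue synthetic globule and analyse it:

```sh
hydromoment make-fixtures demo --seeds 0 --n-residues 120
hydromoment analyze demo/globule_0.pdb --pseudo-atoms
```

The report opens with the shape block:

```
# shape
id                    alpha1  alpha2  alpha3  delta   S       a      b      Rg
demo/globule_0.pdb:A  55.25   60.19   66.56   0.0029  0.0001  16.99  18.24  13.49
```

δ ≈ 0.003 and S ≈ 0: the globule is essentially spherical, with
R_g = 13.5 Å — the size of a real ~120-residue protein.  The moment
profile then runs from the buried core to the fully exposed chain:

```
p      n_p  H2_consensus  H2_charge(0.3)
3.0    4      98.07        118.61
...
100.0  120   -46.31        -58.69
```

H₂ is large and positive while only buried residues are collected
(hydrophobic core) and negative once the whole chain is in (hydrophilic
surface), crossing zero for good at the transition point reported in the
summary:

```
p_transition_consensus      39.00
d_bar_transition_consensus  12.28
R_vs_consensus(0.3)         0.9973
```

i.e. the hydrophobic→hydrophilic transition sits at 39% relative
accessibility (mean centroid distance 12.3 Å), and the charge-derived
profile correlates with the consensus-scale profile at R = 0.997.

The same workflow applies to real structures
(`hydromoment analyze 3PYP.pdb --chain A`), and
`hydromoment group manifest.tsv` adds Flory fits and group-level means.
`hydromoment asa` exports per-residue accessibility tables, and
`hydromoment reference-table` prints the extended Gly-X-Gly reference
ASA for all 20 residue types.

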