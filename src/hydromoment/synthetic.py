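"""Synthetic structure generators for testing the full pipeline offline.

Two kinds of fixtures:

* ellipsoidal "globules" of single-pseudo-atom residues with a
  hydrophobic-in / hydrophilic-out radial composition gradient and a
  controllable aspect ratio — these exercise SASA, accessibility,
  hydrophobicity and the moment profile end-to-end and reproduce the
  qualitative positive-to-negative H2 profile of real globular proteins;
* tiny hand-constructed micro-structures (isolated dimers, rings, rods,
  symmetric squares) whose ASA, asphericity and H2 are known in closed
  form, used as oracle fixtures.

Pseudo-atom residues (a single CA sphere of 3.0 A per residue) carry an
explicit radius/charge override table so the charge-threshold machinery
stays meaningful without side chains: residue types that are hydrophilic
on the consensus scale get a polar pseudo-charge, hydrophobic ones an
apolar pseudo-charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hydromoment.structure import (
    AtomSite,
    ResidueUnit,
    StructureModel,
    assign_radii_and_charges,
)
from hydromoment.tables import STANDARD_RESIDUES, eisenberg_scale

__all__ = [
    "GlobuleSpec",
    "DEFAULT_COMPOSITION",
    "pseudo_overrides",
    "make_globule",
    "make_shell_case",
]

# Approximate natural amino-acid frequencies in globular proteins.
DEFAULT_COMPOSITION = {
    "ALA": 0.075, "ARG": 0.057, "ASN": 0.044, "ASP": 0.059, "CYS": 0.014,
    "GLN": 0.037, "GLU": 0.067, "GLY": 0.071, "HIS": 0.022, "ILE": 0.059,
    "LEU": 0.097, "LYS": 0.058, "MET": 0.024, "PHE": 0.040, "PRO": 0.047,
    "SER": 0.066, "THR": 0.054, "TRP": 0.011, "TYR": 0.029, "VAL": 0.069,
}

PSEUDO_RADIUS = 3.0        # A, one sphere standing in for a whole residue
MEAN_RESIDUE_VOLUME = 165  # A^3 per residue inside a compact globule
MIN_SEPARATION = 3.6       # A between pseudo-atom centres


@dataclass
class GlobuleSpec:
    """Recipe for a synthetic globule.

    ``aspect`` gives the relative ellipsoid semiaxes (1,1,1 = sphere,
    1,1,4 = prolate); ``core_fraction`` is the probability that a
    hydrophobic residue (consensus h > 0) is committed to the inner
    radial half of the globule.
    """

    n_residues: int = 100
    aspect: tuple[float, float, float] = (1.0, 1.0, 1.0)
    core_fraction: float = 0.9
    seed: int = 0
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if not set(self.composition) <= STANDARD_RESIDUES:
            raise ValueError("composition contains non-standard residues")
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"composition sums to {total}, expected 1")


def pseudo_overrides() -> dict[tuple[str, str], tuple[float, float]]:
    """(resname, "CA") -> (radius, charge) for pseudo-atom residues.

    Hydrophilic types (consensus h < 0) are polar (|q| = 0.55), the rest
    apolar (|q| = 0.05), so the charge-derived scale recovers the
    hydrophobic/hydrophilic split on synthetic surfaces.
    """
    scale = eisenberg_scale()
    return {
        (res, "CA"): (PSEUDO_RADIUS, -0.55 if scale[res] < 0 else 0.05)
        for res in STANDARD_RESIDUES
    }


def _single_atom_residue(resname, seq_id, coord):
    atom = AtomSite("CA", "C", np.asarray(coord, dtype=float))
    atom.residue_index = seq_id - 1
    return ResidueUnit(resname, seq_id, [atom])


def make_globule(spec: GlobuleSpec, assign_params: bool = True) -> StructureModel:
    """Generate an ellipsoidal globule per ``spec`` (deterministic for a
    fixed seed).

    Residue positions are sampled uniformly inside an ellipsoid sized for
    a compact-protein density, with a minimum pseudo-atom separation;
    hydrophobic residue types are committed to the innermost positions at
    rate ``core_fraction``.  With ``assign_params`` the pseudo-atom
    radius/charge overrides are applied so the structure is ready for
    SASA.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    aspect = np.asarray(spec.aspect, dtype=float)
    scale = (
        3.0 * n * MEAN_RESIDUE_VOLUME / (4.0 * np.pi * np.prod(aspect))
    ) ** (1.0 / 3.0)
    axes = scale * aspect

    # uniform-in-ellipsoid sampling with a soft minimum-separation rule
    coords = np.empty((n, 3))
    placed = 0
    attempts = 0
    while placed < n:
        u = rng.random() ** (1.0 / 3.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        candidate = axes * u * direction
        attempts += 1
        if placed and attempts < 200 * n:
            d = np.linalg.norm(coords[:placed] - candidate, axis=1)
            if d.min() < MIN_SEPARATION:
                continue
        coords[placed] = candidate
        placed += 1

    names = list(spec.composition)
    probs = np.array([spec.composition[k] for k in names])
    types = rng.choice(names, size=n, p=probs / probs.sum())

    # radial ordering: hydrophobic types claim inner slots at rate
    # core_fraction, everything else fills the remainder at random
    h = eisenberg_scale()
    order = np.argsort(np.linalg.norm(coords / axes, axis=1))
    committed = np.array([
        h[t] > 0 and rng.random() < spec.core_fraction for t in types
    ])
    rest = np.flatnonzero(~committed)
    rng.shuffle(rest)
    slot_types = np.empty(n, dtype=object)
    inner = order[: committed.sum()]
    slot_types[inner] = types[committed]
    slot_types[order[committed.sum():]] = types[rest]

    residues = [
        _single_atom_residue(str(slot_types[i]), i + 1, coords[i])
        for i in range(n)
    ]
    model = StructureModel(
        f"globule(n={n},aspect={tuple(aspect)},core={spec.core_fraction},"
        f"seed={spec.seed})",
        residues,
    )
    if assign_params:
        assign_radii_and_charges(model, overrides=pseudo_overrides())
    return model


def make_shell_case(name: str) -> StructureModel:
    """Hand-constructed micro-structures with analytically known
    descriptors.

    ``far_dimer``
        two pseudo-residues 50 A apart: both atoms keep the full
        isolated-sphere ASA.
    ``square``
        four residues on a square, alternating hydrophobic/hydrophilic
        types: H2 cancels to 0 at full collection.
    ``collinear``
        five equally spaced collinear residues: asphericity = 1.
    ``ring``
        twelve residues on a circle of radius 10 A: a single occupied
        distance-distribution bin.
    """
    if name == "far_dimer":
        residues = [
            _single_atom_residue("ALA", 1, (0.0, 0.0, 0.0)),
            _single_atom_residue("ALA", 2, (50.0, 0.0, 0.0)),
        ]
    elif name == "square":
        residues = [
            _single_atom_residue("ILE", 1, (5.0, 5.0, 0.0)),
            _single_atom_residue("ARG", 2, (-5.0, 5.0, 0.0)),
            _single_atom_residue("ILE", 3, (-5.0, -5.0, 0.0)),
            _single_atom_residue("ARG", 4, (5.0, -5.0, 0.0)),
        ]
    elif name == "collinear":
        residues = [
            _single_atom_residue("GLY", i + 1, (4.0 * i, 0.0, 0.0))
            for i in range(5)
        ]
    elif name == "ring":
        residues = [
            _single_atom_residue(
                "ALA", i + 1,
                (10.0 * np.cos(2 * np.pi * i / 12),
                 10.0 * np.sin(2 * np.pi * i / 12), 0.0),
            )
            for i in range(12)
        ]
    else:
        raise ValueError(f"unknown shell case {name!r}")
    model = StructureModel(f"shell:{name}", residues)
    assign_radii_and_charges(model, overrides=pseudo_overrides())
    return model
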