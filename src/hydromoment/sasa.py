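"""Solvent-accessible surface area (Shrake-Rupley) and relative
accessibility.

The accessible surface of an atom is the sphere of radius
``r_vdw + r_probe`` traced by the probe centre; its accessible fraction is
estimated by testing a deterministic golden-section spiral lattice of
points on that sphere against all neighbouring inflated spheres.  With a
fixed lattice the computation is bit-reproducible: no random numbers are
involved.

Relative (percentage) accessibility divides each residue's folded-state
area by the area of the same residue type X in an extended Gly-X-Gly
tripeptide:

    p = 100 * ASA_X,folded / ASA_X,G-X-G   (%)

Values above 100% are possible for distorted conformations and are not
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from hydromoment.structure import (
    StructureModel,
    assign_radii_and_charges,
    build_extended_tripeptide,
)
from hydromoment.tables import STANDARD_RESIDUES, published_reference_asa

__all__ = [
    "AccessibilityProfile",
    "sphere_points",
    "atom_asa",
    "residue_asa_split",
    "reference_asa_table",
    "relative_accessibility",
    "accessibility_profile",
]

DEFAULT_PROBE_RADIUS = 1.4   # A, water-sized probe
DEFAULT_N_POINTS = 960       # lattice points per atom sphere


@dataclass
class AccessibilityProfile:
    """Per-residue absolute and relative solvent accessibility.

    ``per_residue_asa`` rows are (total, polar, apolar) in A^2; the polar
    part is the summed area of atoms whose partial-charge magnitude meets
    the classification threshold.  ``p_percent`` is relative accessibility
    against ``reference_asa`` (extended Gly-X-Gly values).
    """

    structure_id: str
    per_residue_asa: np.ndarray            # (n, 3): total, polar, apolar
    charge_threshold: float
    reference_asa: dict[str, float] | None = None
    p_percent: np.ndarray | None = None

    @property
    def total(self) -> np.ndarray:
        return self.per_residue_asa[:, 0]

    @property
    def polar(self) -> np.ndarray:
        return self.per_residue_asa[:, 1]

    @property
    def apolar(self) -> np.ndarray:
        return self.per_residue_asa[:, 2]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of ``n`` near-uniform
    points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def atom_asa(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Radii must have been assigned (:func:`assign_radii_and_charges`).
    A point on atom *i*'s inflated sphere counts as accessible when it lies
    outside every neighbour's inflated sphere; neighbour recovery is exact
    (KD-tree within the maximal possible contact distance).
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    coords = structure.atom_coords()
    radii = np.array([a.vdw_radius for a in structure.atom_sites()])
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError(
            f"{structure.id}: atoms without assigned vdW radii; run "
            "assign_radii_and_charges first"
        )

    inflated = radii + probe_radius
    lattice = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = inflated.max()

    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + inflated[i] * lattice
        neighbours = tree.query_ball_point(coords[i], inflated[i] + r_max)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
        areas[i] = (
            4.0 * np.pi * inflated[i] ** 2 * accessible.sum() / n_points
        )
    return areas


def residue_asa_split(
    structure: StructureModel,
    atom_areas: np.ndarray,
    charge_threshold: float = 0.3,
) -> AccessibilityProfile:
    """Sum atom areas per residue, split into polar and apolar parts.

    An atom is polar when ``|partial_charge| >= charge_threshold``; the
    polar and apolar parts partition the residue total exactly.
    """
    if charge_threshold <= 0:
        raise ValueError("charge_threshold must be positive")
    sites = structure.atom_sites()
    if len(atom_areas) != len(sites):
        raise ValueError("atom_areas does not match the structure's atoms")
    n = structure.n_residues
    out = np.zeros((n, 3))
    for a, area in zip(sites, atom_areas):
        polar = abs(a.partial_charge) >= charge_threshold
        out[a.residue_index, 0] += area
        out[a.residue_index, 1 if polar else 2] += area
    return AccessibilityProfile(structure.id, out, charge_threshold)


def reference_asa_table(
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radius_set: str = "protein-united",
) -> dict[str, float]:
    """Compute the extended Gly-X-Gly reference ASA (A^2) of the central
    residue X for all 20 residue types."""
    table = {}
    for resname in sorted(STANDARD_RESIDUES):
        tri = assign_radii_and_charges(
            build_extended_tripeptide(resname), radius_set=radius_set
        )
        areas = atom_asa(tri, probe_radius, n_points)
        sites = tri.atom_sites()
        table[resname] = float(
            sum(ar for a, ar in zip(sites, areas) if a.residue_index == 1)
        )
    return table


def relative_accessibility(
    structure: StructureModel,
    profile: AccessibilityProfile,
    reference: dict[str, float] | str = "computed",
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> AccessibilityProfile:
    """Attach percentage solvent accessibility to a profile.

    ``reference`` is either an explicit resname -> A^2 mapping, the string
    ``"computed"`` (build the Gly-X-Gly reference table with the same
    probe/lattice settings) or ``"published"`` (the packaged ASC-derived
    reference values).
    """
    if reference == "computed":
        reference = reference_asa_table(probe_radius, n_points)
    elif reference == "published":
        reference = published_reference_asa()
    missing = {r.resname for r in structure.residues} - set(reference)
    if missing:
        raise KeyError(f"no reference ASA for residue types {sorted(missing)}")
    ref = np.array([reference[r.resname] for r in structure.residues])
    profile.reference_asa = dict(reference)
    profile.p_percent = 100.0 * profile.total / ref
    return profile


def accessibility_profile(
    structure: StructureModel,
    charge_threshold: float = 0.3,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    reference: dict[str, float] | str = "computed",
    atom_areas: np.ndarray | None = None,
) -> AccessibilityProfile:
    """Convenience wrapper: atom ASA -> residue split -> relative
    accessibility in one call."""
    if atom_areas is None:
        atom_areas = atom_asa(structure, probe_radius, n_points)
    profile = residue_asa_split(structure, atom_areas, charge_threshold)
    return relative_accessibility(
        structure, profile, reference, probe_radius, n_points
    )
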