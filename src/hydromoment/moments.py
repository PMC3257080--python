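"""Spatial second-order hydrophobic moment profiles.

At an accessibility cutoff p, collect the n_p residues whose percentage
solvent accessibility is <= p (the cutoff acts as a growing "shell" from
the buried core outward) and evaluate the quadrupole-like per-residue
moment

    H2(p) = (1/n_p) * sum_i h'_i * d_i**2

over the collected set, with h'_i the per-protein-standardised
hydrophobicity and d_i the distance from the chain's centre of mass to
residue i's centroid.  Hydrophobic-core-dominated sets give H2 > 0; as
hydrophilic surface residues accumulate the profile turns negative.  The
cutoff at which it turns negative for good is the hydrophobic ->
hydrophilic transition point p*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hydromoment.hydrophobicity import (
    assign_hydrophobicity,
    normalize,
)
from hydromoment.sasa import AccessibilityProfile, residue_asa_split
from hydromoment.shape import center_of_mass
from hydromoment.structure import StructureModel

__all__ = [
    "MomentProfile",
    "default_p_grid",
    "moment_profile",
    "transition_point",
    "profile_correlation",
    "threshold_sweep",
]


@dataclass
class MomentProfile:
    """H2 profile of one chain on an accessibility grid.

    ``H2`` entries are NaN at grid points where no residue has been
    collected yet (undefined, not zero).  ``p_transition`` is None when
    the profile never settles negative.
    """

    structure_id: str
    scale_name: str
    p_grid: np.ndarray
    n_p: np.ndarray
    H2: np.ndarray
    p_transition: float | None = None
    d_bar_transition: float | None = None


def default_p_grid() -> np.ndarray:
    """Accessibility cutoffs used by default: 0%, odd percentages at 2%
    resolution, and 100% (so the final point collects every residue)."""
    return np.concatenate([[0.0], np.arange(1.0, 100.0, 2.0), [100.0]])


def moment_profile(
    structure: StructureModel,
    accessibility: AccessibilityProfile,
    h_norm: np.ndarray,
    p_grid: np.ndarray | None = None,
    scale_name: str = "",
) -> MomentProfile:
    """Profile H2 against the accessibility cutoff grid.

    Residues with ``p_percent`` exactly at the cutoff are included
    (inclusive comparison: the 0% point collects the completely buried
    residues).  The final grid point must be >= the maximum relative
    accessibility only if the whole chain is to be collected there; with
    the default grid, residues above 100% are swept up by the 100% point
    using a closed top bin.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(np.diff(p_grid) <= 0):
        raise ValueError("p_grid must be strictly ascending")
    p = accessibility.p_percent
    if p is None:
        raise ValueError("accessibility profile lacks p_percent; "
                         "run relative_accessibility first")
    h_norm = np.asarray(h_norm, dtype=float)
    if not (len(p) == len(h_norm) == structure.n_residues):
        raise ValueError("structure / accessibility / h_norm length mismatch")

    d2 = np.sum(
        (structure.centroids() - center_of_mass(structure)) ** 2, axis=1
    )
    n_p = np.empty(len(p_grid), dtype=int)
    H2 = np.full(len(p_grid), np.nan)
    for k, cutoff in enumerate(p_grid):
        collected = p <= cutoff
        if cutoff >= 100.0:
            collected = np.ones_like(collected)  # closed top: p > 100 kept
        n_p[k] = collected.sum()
        if n_p[k] > 0:
            H2[k] = np.sum(h_norm[collected] * d2[collected]) / n_p[k]

    profile = MomentProfile(
        structure.id, scale_name, p_grid, n_p, H2
    )
    p_t, d_t = _locate_transition(profile, p, np.sqrt(d2))
    profile.p_transition, profile.d_bar_transition = p_t, d_t
    return profile


def _locate_transition(profile, p_percent, d, rule: str = "last"):
    """Find the cutoff where H2 turns negative.

    ``rule="last"`` (default): the smallest grid cutoff from which H2 is
    negative at every later defined grid point (the profile vanishes and
    stays negative).  ``rule="first"``: the first negative grid point.
    Returns (None, None) when the profile never settles negative.
    """
    defined = ~np.isnan(profile.H2)
    idx = np.flatnonzero(defined)
    if len(idx) < 2:
        return None, None
    h = profile.H2[idx]
    if rule == "first":
        neg = np.flatnonzero(h < 0)
        k = neg[0] if len(neg) else None
    elif rule == "last":
        k = None
        for j in range(len(h) - 1, -1, -1):
            if h[j] < 0:
                k = j
            else:
                break
    else:
        raise ValueError(f"unknown transition rule {rule!r}")
    if k is None:
        return None, None
    p_star = float(profile.p_grid[idx[k]])
    collected = p_percent <= p_star
    if p_star >= 100.0:
        collected = np.ones_like(collected)
    return p_star, float(d[collected].mean())


def transition_point(
    profile: MomentProfile,
    accessibility: AccessibilityProfile,
    structure: StructureModel,
    rule: str = "last",
) -> tuple[float | None, float | None]:
    """Transition cutoff p* and mean centroid distance d-bar* of the
    residue set collected at p*.  See :func:`_locate_transition` for the
    rule; returns (None, None) if H2 never settles negative."""
    d = np.linalg.norm(
        structure.centroids() - center_of_mass(structure), axis=1
    )
    return _locate_transition(profile, accessibility.p_percent, d, rule)


def profile_correlation(x: MomentProfile, y: MomentProfile) -> float:
    """Pearson correlation of two H2 profiles on the same grid.

    Both series are standardised (per-protein normalisation applied to the
    grid values) before correlating — a no-op for Pearson's R, kept for
    fidelity to the defining procedure.  Only grid points defined in both
    profiles enter.
    """
    if len(x.p_grid) != len(y.p_grid) or np.any(x.p_grid != y.p_grid):
        raise ValueError("profiles are on different grids")
    common = ~np.isnan(x.H2) & ~np.isnan(y.H2)
    if common.sum() < 2:
        raise ValueError("fewer than 2 common defined grid points")
    xv, yv = normalize(x.H2[common]), normalize(y.H2[common])
    return float(np.corrcoef(xv, yv)[0, 1])


def threshold_sweep(
    structure: StructureModel,
    atom_areas: np.ndarray,
    reference: dict[str, float],
    thresholds=(0.25, 0.27, 0.3),
    p_grid: np.ndarray | None = None,
) -> dict[float, float]:
    """Correlate charge-derived moment profiles against the consensus
    profile for several polar-atom charge thresholds.

    ``atom_areas`` and ``reference`` are reused across thresholds (the
    geometry does not change; only the polar/apolar classification does).
    Returns threshold -> Pearson R.
    """
    from hydromoment.sasa import relative_accessibility

    base = residue_asa_split(structure, atom_areas, thresholds[0])
    base = relative_accessibility(structure, base, reference)
    cons = assign_hydrophobicity(structure, "consensus")
    cons_profile = moment_profile(
        structure, base, cons.h_norm, p_grid, cons.scale_name
    )
    out = {}
    for t in thresholds:
        prof = residue_asa_split(structure, atom_areas, t)
        prof = relative_accessibility(structure, prof, reference)
        cd = assign_hydrophobicity(structure, "charge_derived", prof)
        cd_profile = moment_profile(
            structure, prof, cd.h_norm, p_grid, cd.scale_name
        )
        out[t] = profile_correlation(cons_profile, cd_profile)
    return out
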