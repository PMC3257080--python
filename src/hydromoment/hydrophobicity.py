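"""Per-residue hydrophobicity scales and per-protein normalisation.

Two independent scales are provided:

* the Eisenberg consensus scale, a fixed value per residue type;
* a charge-derived scale computed from each residue's polar/apolar
  solvent-accessible surface split,

      h = (ASA_apo - ASA_po) / (ASA_apo + ASA_po),

  where atoms count as polar when their partial-charge magnitude meets a
  threshold.  The ratio is bounded in [-1, 1].

Either scale is standardised per protein (z-score over the chain's
residues) before entering the hydrophobic-moment sums, making the
normalised values composition-dependent by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hydromoment.sasa import AccessibilityProfile
from hydromoment.structure import StructureModel
from hydromoment.tables import eisenberg_scale

__all__ = [
    "HydrophobicityAssignment",
    "DegenerateScaleError",
    "consensus_scale",
    "charge_derived_scale",
    "normalize",
    "assign_hydrophobicity",
]


class DegenerateScaleError(ValueError):
    """Raised when a hydrophobicity vector has zero variance."""


@dataclass
class HydrophobicityAssignment:
    """Raw and per-protein-normalised hydrophobicity for one chain."""

    structure_id: str
    scale_name: str
    h_raw: np.ndarray
    h_norm: np.ndarray


def consensus_scale(structure: StructureModel) -> np.ndarray:
    """Eisenberg consensus hydrophobicity, one value per residue."""
    table = eisenberg_scale()
    try:
        return np.array([table[r.resname] for r in structure.residues])
    except KeyError as err:
        raise KeyError(
            f"{structure.id}: no consensus value for residue {err}"
        ) from None


def charge_derived_scale(profile: AccessibilityProfile) -> np.ndarray:
    """Charge-derived hydrophobicity (apolar - polar)/(apolar + polar).

    Fully buried residues (zero total accessible area) carry no surface
    evidence either way and are assigned h = 0, keeping them in the
    moment sums.
    """
    apo, po = profile.apolar, profile.polar
    total = apo + po
    h = np.zeros(len(total))
    exposed = total > 0
    h[exposed] = (apo[exposed] - po[exposed]) / total[exposed]
    return h


def normalize(h_raw: np.ndarray) -> np.ndarray:
    """Standardise a hydrophobicity vector to mean 0, sample sd 1.

    Uses the sample standard deviation (n - 1 denominator); switch to the
    population estimator only rescales every value by sqrt(n/(n-1)).
    """
    h = np.asarray(h_raw, dtype=float)
    if h.size < 2:
        raise ValueError("normalization needs at least 2 residues")
    sd = h.std(ddof=1)
    if sd == 0:
        raise DegenerateScaleError("zero-variance hydrophobicity vector")
    return (h - h.mean()) / sd


def assign_hydrophobicity(
    structure: StructureModel,
    scale: str = "consensus",
    profile: AccessibilityProfile | None = None,
) -> HydrophobicityAssignment:
    """Build a :class:`HydrophobicityAssignment` for one chain.

    ``scale`` is ``"consensus"`` or ``"charge_derived"``; the latter needs
    an :class:`AccessibilityProfile` computed at the desired polar-atom
    charge threshold.
    """
    if scale == "consensus":
        h_raw = consensus_scale(structure)
        name = "consensus"
    elif scale == "charge_derived":
        if profile is None:
            raise ValueError("charge_derived scale needs an AccessibilityProfile")
        h_raw = charge_derived_scale(profile)
        name = f"charge_derived({profile.charge_threshold:g})"
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return HydrophobicityAssignment(
        structure.id, name, h_raw, normalize(h_raw)
    )
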