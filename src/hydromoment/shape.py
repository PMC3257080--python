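"""Gyration-tensor shape analysis over residue centroids.

The gyration tensor of a chain with residue centroids r_i and centre of
mass r_CM is

    T = (1/N_r) * sum_i (r_i - r_CM)(r_i - r_CM)^T .

Its eigenvalues a1 <= a2 <= a3 (A^2) give

* asphericity        delta = 1 - 3 (a1 a2 + a2 a3 + a1 a3) / (a1+a2+a3)^2
                     (0 for a sphere, 1 for a rod),
* shape parameter    S = 27 * prod(a_i - abar) / (a1+a2+a3)^3
                     (negative oblate, positive prolate),
* semiaxes           a = sqrt(5 (a1+a2)/2),  b = sqrt(5 a3),
* radius of gyration R_g = sqrt(a1 + a2 + a3).

Distance distributions W(d) of centroid distances from the centre of mass
and Flory scaling fits (R_g ~ N^nu) across protein sets complete the
geometric description.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from hydromoment.structure import StructureModel

__all__ = [
    "ShapeSummary",
    "DistanceDistribution",
    "center_of_mass",
    "gyration_tensor",
    "distance_distribution",
    "flory_fit",
]


@dataclass
class ShapeSummary:
    """Shape descriptors of one chain (eigenvalues ascending, A^2)."""

    eigenvalues: tuple[float, float, float]
    asphericity: float
    shape_param: float
    semiaxes: tuple[float, float]
    r_gyration: float


@dataclass
class DistanceDistribution:
    """Histogram of residue-centroid distances from the centre of mass.

    ``mode`` is the centre of the most populated bin; ``mean`` and
    ``half_width`` are the sample mean and sample standard deviation of
    the distance set (the d-bar +/- delta-d fluctuation summary).
    """

    bin_edges: np.ndarray
    proportions: np.ndarray
    mode: float
    mean: float
    half_width: float


def center_of_mass(structure: StructureModel) -> np.ndarray:
    """Unweighted mean of residue centroids (the chain's origin for all
    distance and moment computations)."""
    if structure.n_residues < 1:
        raise ValueError("empty structure")
    return structure.centroids().mean(axis=0)


def gyration_tensor(structure: StructureModel) -> ShapeSummary:
    """Eigen-decompose the gyration tensor and derive shape descriptors."""
    if structure.n_residues < 2:
        raise ValueError("gyration tensor needs at least 2 residues")
    rel = structure.centroids() - center_of_mass(structure)
    T = rel.T @ rel / len(rel)
    eig = np.sort(np.linalg.eigvalsh(T))
    eig = np.clip(eig, 0.0, None)       # numerical negatives near zero
    a1, a2, a3 = eig
    tr = eig.sum()
    delta = 1.0 - 3.0 * (a1 * a2 + a2 * a3 + a1 * a3) / tr**2
    abar = tr / 3.0
    s_param = 27.0 * np.prod(eig - abar) / tr**3
    return ShapeSummary(
        eigenvalues=(float(a1), float(a2), float(a3)),
        asphericity=float(delta),
        shape_param=float(s_param),
        semiaxes=(float(np.sqrt(5.0 * (a1 + a2) / 2.0)),
                  float(np.sqrt(5.0 * a3))),
        r_gyration=float(np.sqrt(tr)),
    )


def distance_distribution(
    structure: StructureModel, n_bins: int = 10
) -> DistanceDistribution:
    """Bin centroid distances from the centre of mass into ``n_bins``
    equal-width bins over [0, max distance] (final bin right-closed)."""
    if structure.n_residues < 2:
        raise ValueError("distance distribution needs at least 2 residues")
    d = np.linalg.norm(
        structure.centroids() - center_of_mass(structure), axis=1
    )
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, d.max()))
    proportions = counts / len(d)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DistanceDistribution(
        bin_edges=edges,
        proportions=proportions,
        mode=float(centers[np.argmax(counts)]),
        mean=float(d.mean()),
        half_width=float(d.std(ddof=1)),
    )


def flory_fit(sizes) -> tuple[float, float, float]:
    """Fit the Flory scaling law R_g = A * N^nu by ordinary least squares
    on the double-logarithmic scale.

    Parameters
    ----------
    sizes
        Iterable of (N, R_g) pairs, N the residue count.

    Returns
    -------
    (nu, prefactor, r)
        Scaling exponent (slope), prefactor A, and the Pearson
        correlation of (log N, log R_g).
    """
    pts = [(float(n), float(rg)) for n, rg in sizes]
    if len({n for n, _ in pts}) < 2:
        raise ValueError("Flory fit needs at least 2 distinct sizes")
    log_n = np.log10([n for n, _ in pts])
    log_rg = np.log10([rg for _, rg in pts])
    fit = stats.linregress(log_n, log_rg)
    return float(fit.slope), float(10.0 ** fit.intercept), float(fit.rvalue)
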