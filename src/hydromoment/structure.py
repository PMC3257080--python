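"""Structure I/O: PDB reading, the internal chain model, extended
Gly-X-Gly tripeptide construction, and per-atom parameter assignment.

The internal model is residue-centric: a :class:`StructureModel` is an
ordered list of :class:`ResidueUnit` (one chain), each holding its heavy
:class:`AtomSite` atoms and a centroid.  All downstream geometry (gyration
tensor, distances, hydrophobic moments) operates on residue centroids;
solvent accessibility operates on the atoms.

Hydrogens are excluded throughout: the crystal structures this analysis
targets are hydrogen-free, and the packaged radius/charge tables are
united-atom sets defined on heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

from hydromoment.tables import STANDARD_RESIDUES, charge_table, radius_table

logger = logging.getLogger(__name__)

__all__ = [
    "AtomSite", "ResidueUnit", "StructureModel",
    "EmptyStructureError", "AnnotationError",
    "read_pdb", "write_pdb", "build_extended_tripeptide",
    "assign_radii_and_charges",
]


class EmptyStructureError(ValueError):
    """Raised when a chain contains no standard amino-acid residues."""


class AnnotationError(KeyError):
    """Raised when atoms cannot be resolved in a radius/charge table."""


@dataclass
class AtomSite:
    """One heavy atom of a protein chain.

    Coordinates are in Angstrom, the partial charge in elementary-charge
    units (signed).  ``vdw_radius`` and ``partial_charge`` are NaN until
    :func:`assign_radii_and_charges` populates them.
    """

    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float = float("nan")
    partial_charge: float = float("nan")
    residue_index: int = -1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")


@dataclass
class ResidueUnit:
    """One amino-acid residue: identity, atoms and centroid."""

    resname: str
    seq_id: int
    atoms: list[AtomSite]
    centroid: np.ndarray = field(default=None)
    ins_code: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"residue {self.resname}{self.seq_id}: no atoms")
        if self.centroid is None:
            self.centroid = np.mean([a.coords for a in self.atoms], axis=0)
        self.centroid = np.asarray(self.centroid, dtype=float)

    def atom(self, name: str) -> AtomSite:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.resname}{self.seq_id} has no atom {name!r}")


@dataclass
class StructureModel:
    """An ordered single chain of standard residues."""

    id: str
    residues: list[ResidueUnit]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def centroids(self) -> np.ndarray:
        """(n_residues, 3) array of residue centroids."""
        return np.array([r.centroid for r in self.residues])

    def atom_sites(self) -> list[AtomSite]:
        return [a for r in self.residues for a in r.atoms]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atom_sites()])


# Atomic masses for the optional mass-weighted centroid policy.
_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _make_residues(groups, centroid_policy: str) -> list[ResidueUnit]:
    residues = []
    for idx, (resname, seq_id, ins_code, atoms) in enumerate(groups):
        for a in atoms:
            a.residue_index = idx
        if centroid_policy == "mass":
            w = np.array([_MASS.get(a.element, 12.0) for a in atoms])
            centroid = (
                np.sum([wi * a.coords for wi, a in zip(w, atoms)], axis=0)
                / w.sum()
            )
        elif centroid_policy == "geometric":
            centroid = np.mean([a.coords for a in atoms], axis=0)
        else:
            raise ValueError(f"unknown centroid_policy {centroid_policy!r}")
        residues.append(
            ResidueUnit(resname, int(seq_id), atoms, centroid, ins_code)
        )
    return residues


def read_pdb(
    path,
    chain: str | None = None,
    centroid_policy: str = "geometric",
) -> StructureModel:
    """Read one chain of a PDB file into a :class:`StructureModel`.

    Only ``ATOM`` records of the 20 standard amino acids are kept: waters,
    ligands and other heteroatoms are dropped, hydrogens are removed, and
    alternate locations are resolved to the highest-occupancy (then
    alphabetically first) conformer.  Non-standard residues are dropped
    with a warning.  The first model is used.

    Parameters
    ----------
    path
        PDB file path.
    chain
        Chain identifier.  ``None`` selects the first chain in the file.
    centroid_policy
        ``"geometric"`` (unweighted mean of heavy-atom coordinates,
        default) or ``"mass"`` (mass-weighted).

    Raises
    ------
    FileNotFoundError
        Missing file.
    KeyError
        Requested chain absent.
    EmptyStructureError
        No standard residues remain after filtering.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")

    chains = list(dict.fromkeys(atoms.chain_id))
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not in {path} (chains: {chains})")

    mask = (
        (atoms.chain_id == chain)
        & ~atoms.hetero
        & (atoms.element != "H")
        & (atoms.element != "D")
    )
    sel = atoms[mask]

    nonstandard = sorted(
        set(sel.res_name[~np.isin(sel.res_name, list(STANDARD_RESIDUES))])
    )
    if nonstandard:
        logger.warning(
            "%s chain %s: dropping non-standard residues %s",
            path, chain, nonstandard,
        )
        sel = sel[np.isin(sel.res_name, list(STANDARD_RESIDUES))]
    if sel.array_length() == 0:
        raise EmptyStructureError(
            f"{path} chain {chain}: no standard amino-acid residues"
        )

    ins = sel.ins_code if "ins_code" in sel.get_annotation_categories() \
        else np.full(sel.array_length(), "")
    groups, seen = [], {}
    for i in range(sel.array_length()):
        key = (int(sel.res_id[i]), str(ins[i]))
        if key not in seen:
            seen[key] = len(groups)
            groups.append((str(sel.res_name[i]), key[0], key[1], []))
        groups[seen[key]][3].append(
            AtomSite(
                name=str(sel.atom_name[i]),
                element=str(sel.element[i]),
                coords=sel.coord[i],
            )
        )
    return StructureModel(
        f"{path}:{chain}", _make_residues(groups, centroid_policy)
    )


def write_pdb(structure: StructureModel, path) -> None:
    """Write a :class:`StructureModel` back out as PDB text (chain A)."""
    sites = structure.atom_sites()
    arr = struc.AtomArray(len(sites))
    for i, a in enumerate(sites):
        res = structure.residues[a.residue_index]
        arr.coord[i] = a.coords
        arr.chain_id[i] = "A"
        arr.res_id[i] = res.seq_id
        arr.ins_code[i] = res.ins_code
        arr.res_name[i] = res.resname
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Extended tripeptide construction
# ---------------------------------------------------------------------------

# Engh-Huber-style ideal backbone geometry (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 117.2, 121.7, 120.8

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _place(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF internal-coordinate placement: position a new atom at distance
    ``bond`` from *c*, angle ``angle`` at c with b, dihedral about b-c
    relative to a."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _fit_rigid(src: np.ndarray, dst: np.ndarray):
    """Rigid (rotation + translation) least-squares fit mapping the point
    set ``src`` onto ``dst`` (Kabsch)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, dc - R @ sc


def _sidechain_template(resname: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of the idealised residue template, keyed by
    atom name (backbone included, for superimposition)."""
    tmpl = struc_info.residue(resname)
    tmpl = tmpl[tmpl.element != "H"]
    return {str(n): c.copy() for n, c in zip(tmpl.atom_name, tmpl.coord)}


def build_extended_tripeptide(central_resname: str) -> StructureModel:
    """Build Gly-X-Gly in the fully extended state (phi = psi = omega =
    180 deg) with ideal backbone geometry.

    The backbone is generated from internal coordinates; side-chain (and
    proline ring) atoms come from idealised residue templates rigidly
    fitted onto each residue's N/CA/C frame, which leaves the side chain
    in an extended rotamer.  The flanking glycines provide the steric
    screening of chain neighbours, so the central residue's accessible
    area is the standard "extended state" reference for that residue
    type.  A terminal OXT is included on the last residue.
    """
    central_resname = central_resname.upper()
    if central_resname not in STANDARD_RESIDUES:
        raise ValueError(f"unknown residue code {central_resname!r}")
    seq = ["GLY", central_resname, "GLY"]

    # backbone trace N-CA-C per residue, all dihedrals 180 deg
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    bb = [[n0, ca0, c0]]
    for _ in range(1, 3):
        n_prev, ca_prev, c_prev = bb[-1]
        n = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, 180.0)   # psi
        ca = _place(ca_prev, c_prev, n, _B_N_CA, _A_C_N_CA, 180.0)      # omega
        c = _place(c_prev, n, ca, _B_CA_C, _A_N_CA_C, 180.0)            # phi
        bb.append([n, ca, c])

    groups = []
    for i, resname in enumerate(seq):
        n, ca, c = bb[i]
        atoms = [
            AtomSite("N", "N", n),
            AtomSite("CA", "C", ca),
            AtomSite("C", "C", c),
        ]
        # carbonyl O: anti to the next residue's N (psi = 180 puts the
        # N(i)-CA-C-O dihedral at 0)
        atoms.append(
            AtomSite("O", "O", _place(n, ca, c, _B_C_O, _A_CA_C_O, 0.0))
        )
        if i == 2:
            atoms.append(
                AtomSite("OXT", "O", _place(n, ca, c, _B_C_O, _A_CA_C_O, 180.0))
            )
        tmpl = _sidechain_template(resname)
        frame_src = np.array([tmpl["N"], tmpl["CA"], tmpl["C"]])
        frame_dst = np.array([n, ca, c])
        R, t = _fit_rigid(frame_src, frame_dst)
        for name, coord in tmpl.items():
            if name in _BACKBONE_NAMES:
                continue
            element = name[0] if name[0] in ("C", "N", "O", "S") else "C"
            atoms.append(AtomSite(name, element, R @ coord + t))
        groups.append((resname, i + 1, "", atoms))

    model = StructureModel(
        f"GLY-{central_resname}-GLY(extended)",
        _make_residues(groups, "geometric"),
    )
    return model


# ---------------------------------------------------------------------------
# Radius / charge assignment
# ---------------------------------------------------------------------------

# historical PDB naming variants -> canonical table keys
_ATOM_ALIASES = {"OT1": "O", "OT2": "OXT", "O1": "O", "O2": "OXT",
                 "OXT": "OXT", "CD": "CD1"}


def _lookup(table, resname, atom_name):
    key = (resname, atom_name)
    if key in table:
        return table[key]
    if atom_name in _ATOM_ALIASES:
        key = (resname, _ATOM_ALIASES[atom_name])
        if key in table:
            return table[key]
    return None


def assign_radii_and_charges(
    structure: StructureModel,
    radius_set: str = "protein-united",
    charge_set: str = "charmm-united",
    overrides: dict | None = None,
) -> StructureModel:
    """Populate ``vdw_radius`` and ``partial_charge`` on every atom.

    ``overrides`` maps ``(resname, atom name)`` to ``(radius, charge)``
    and takes precedence over the named tables; synthetic pseudo-atom
    structures use it to stay meaningful without full side chains.
    Unresolvable atoms raise :class:`AnnotationError` listing all
    offenders.
    """
    radii = radius_table(radius_set)
    charges = charge_table(charge_set)
    overrides = overrides or {}
    missing = []
    for res in structure.residues:
        for a in res.atoms:
            key = (res.resname, a.name)
            if key in overrides:
                a.vdw_radius, a.partial_charge = overrides[key]
                continue
            r = _lookup(radii, *key)
            q = _lookup(charges, *key)
            if r is None or q is None:
                missing.append(f"{res.resname}{res.seq_id}:{a.name}")
                continue
            a.vdw_radius, a.partial_charge = r, q
    if missing:
        raise AnnotationError(
            f"{structure.id}: unresolvable atoms: {', '.join(missing)}"
        )
    return structure
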