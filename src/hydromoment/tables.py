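"""Packaged parameter tables: vdW radii, partial charges, hydrophobicity
scales and reference accessibilities.

All tables are plain tab-separated resources under ``hydromoment/data`` with
the schema ``resname<TAB>atom<TAB>value`` (per-atom tables) or
``resname<TAB>value`` (per-residue tables).  Lines starting with ``#`` are
comments.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = [
    "STANDARD_RESIDUES",
    "load_atom_table",
    "load_residue_table",
    "radius_table",
    "charge_table",
    "eisenberg_scale",
    "published_reference_asa",
]

#: The 20 standard amino acids (three-letter codes).
STANDARD_RESIDUES = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
])

#: Registered per-atom radius sets, name -> resource file.
RADIUS_SETS = {"protein-united": "radii_protein.tsv"}
#: Registered per-atom charge sets, name -> resource file.
CHARGE_SETS = {"charmm-united": "charges_united.tsv"}


def _read_lines(resource: str):
    text = (
        resources.files("hydromoment.data").joinpath(resource).read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


@lru_cache(maxsize=None)
def load_atom_table(resource: str) -> dict[tuple[str, str], float]:
    """Load a (resname, atom) -> value table from package data."""
    return {(f[0], f[1]): float(f[2]) for f in _read_lines(resource)}


@lru_cache(maxsize=None)
def load_residue_table(resource: str) -> dict[str, float]:
    """Load a resname -> value table from package data."""
    return {f[0]: float(f[1]) for f in _read_lines(resource)}


def radius_table(name: str = "protein-united") -> dict[tuple[str, str], float]:
    """Van der Waals radii (A) keyed by (resname, atom name)."""
    try:
        return load_atom_table(RADIUS_SETS[name])
    except KeyError:
        raise KeyError(
            f"unknown radius set {name!r}; available: {sorted(RADIUS_SETS)}"
        ) from None


def charge_table(name: str = "charmm-united") -> dict[tuple[str, str], float]:
    """Partial charges (e) keyed by (resname, atom name).

    The default set is a united/extended-atom protein topology (CHARMM19
    style): hydrogen charges are folded into their bonded heavy atom, so
    the table is meaningful for hydrogen-free crystal structures.
    Internal-residue values are used for chain termini (no terminal
    patches).
    """
    try:
        return load_atom_table(CHARGE_SETS[name])
    except KeyError:
        raise KeyError(
            f"unknown charge set {name!r}; available: {sorted(CHARGE_SETS)}"
        ) from None


def eisenberg_scale() -> dict[str, float]:
    """The Eisenberg consensus hydrophobicity scale, per residue type."""
    return load_residue_table("eisenberg_consensus.tsv")


def published_reference_asa() -> dict[str, float]:
    """Published extended Gly-X-Gly reference ASA values (A^2, ASC program,
    1.4 A probe), usable in place of the self-computed reference table."""
    return load_residue_table("asa_ref_published.tsv")
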