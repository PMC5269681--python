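"""Flipping reaction coordinate from structure coordinates.

The reaction coordinate is a pseudo-dihedral over four *pseudo centers*, each
the center of mass of a user-defined heavy-atom group (for base flipping:
duplex anchor residues on either side, the backbone of the flipping
nucleotides, and the flipping nucleobases).  Distributing the coordinate over
group centers of mass spreads the biasing force over many atoms and avoids
local distortions that single-atom coordinates provoke.

PDB reading is delegated to :mod:`biotite`; atomic masses come from an
embedded standard-atomic-weight table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from fnmatch import fnmatch
from typing import Sequence

import numpy as np
import biotite.structure.io.pdb as _pdb

from flipkin.angles import wrap_angle

#: Standard atomic weights (amu) for elements common in nucleic-acid /
#: protein structures and counter-ions.
ATOMIC_WEIGHTS = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

_TWO_LETTER = {e for e in ATOMIC_WEIGHTS if len(e) == 2}


class PDBParseError(ValueError):
    """Malformed PDB record (message names the offending line)."""


class SelectionError(ValueError):
    """An atom-group selection matched no atoms."""


class DihedralUndefinedError(ValueError):
    """Collinear centers make the dihedral undefined."""


@dataclass
class Structure:
    """A minimal coordinate container: parallel arrays, one entry per atom."""

    atom_name: np.ndarray   # str
    res_id: np.ndarray      # int
    res_name: np.ndarray    # str
    chain_id: np.ndarray    # str
    element: np.ndarray     # str, upper case
    mass: np.ndarray        # amu
    coord: np.ndarray       # (n, 3) Angstrom

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        if self.coord.shape != (n, 3):
            raise ValueError("coord must have shape (n_atoms, 3)")
        if n and not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in structure")
        if n and not np.all(self.mass > 0):
            raise ValueError("non-positive atomic mass in structure")

    def __len__(self) -> int:
        return len(self.atom_name)


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (e.g. ``C1'`` -> C, ``1H5'`` -> H)."""
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise PDBParseError(f"cannot infer element from atom name {atom_name!r}")
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


def _mass_of(element: str, atom_name: str) -> float:
    key = element.upper()
    if key not in ATOMIC_WEIGHTS:
        raise PDBParseError(
            f"unknown element {element!r} for atom {atom_name!r}; "
            f"known: {sorted(ATOMIC_WEIGHTS)}"
        )
    return ATOMIC_WEIGHTS[key]


def parse_pdb(text: str) -> Structure:
    """Parse ATOM/HETATM records of PDB-format ``text`` into a :class:`Structure`.

    The element is taken from columns 77-78 when present, otherwise inferred
    from the atom name.  Malformed fixed-width records raise
    :class:`PDBParseError` naming the line number.
    """
    _check_records(text)
    pdb_file = _pdb.PDBFile.read(io.StringIO(text))
    try:
        arr = pdb_file.get_structure(model=1)
    except Exception as exc:  # no ATOM records at all -> empty structure
        if not any(ln.startswith(("ATOM", "HETATM")) for ln in text.splitlines()):
            empty = np.array([], dtype=object)
            return Structure(
                atom_name=empty, res_id=np.array([], dtype=int), res_name=empty,
                chain_id=empty, element=empty,
                mass=np.array([], dtype=float), coord=np.zeros((0, 3)),
            )
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc
    elements = []
    for el, name in zip(arr.element, arr.atom_name):
        el = str(el).strip().upper()
        elements.append(el if el else infer_element(str(name)))
    masses = np.array(
        [_mass_of(el, nm) for el, nm in zip(elements, arr.atom_name)], dtype=float
    )
    return Structure(
        atom_name=np.asarray(arr.atom_name, dtype=object),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype=object),
        chain_id=np.asarray(arr.chain_id, dtype=object),
        element=np.asarray(elements, dtype=object),
        mass=masses,
        coord=np.asarray(arr.coord, dtype=float),
    )


def _check_records(text: str) -> None:
    # Fixed-width sanity scan so errors can name the offending line; biotite's
    # own exceptions do not carry line numbers.
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(
                f"line {lineno}: ATOM/HETATM record too short for coordinates"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError as exc:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field "
                    f"{line[lo:hi]!r}"
                ) from exc


@dataclass
class GroupSpec:
    """Selection defining one pseudo center.

    ``selectors`` is a list of ``(chain_id, res_id, atom_name_pattern)``
    triples; a pattern is an ``fnmatch`` glob (``"*"`` = every atom of the
    residue).  ``chain_id`` may be ``"*"`` to match any chain.  With
    ``heavy_only`` (default) hydrogens are excluded by element, which name
    patterns alone cannot do robustly (``H5''``, ``1H5'`` ...).
    """

    selectors: Sequence[tuple[str, int, str]]
    mass_weighted: bool = True
    heavy_only: bool = True

    def resolve(self, structure: Structure) -> np.ndarray:
        """Indices of matching atoms; raises :class:`SelectionError` if none."""
        mask = np.zeros(len(structure), dtype=bool)
        for chain, res, pattern in self.selectors:
            sel = structure.res_id == int(res)
            if chain not in ("*", "", None):
                sel &= structure.chain_id == chain
            if pattern not in ("*", "", None):
                sel &= np.array(
                    [fnmatch(str(n), pattern) for n in structure.atom_name]
                )
            mask |= sel
        if self.heavy_only:
            mask &= structure.element != "H"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"no atoms matched {self.selectors!r}")
        return idx


@dataclass
class PseudoDihedralSpec:
    """Four ordered pseudo-center group specs (center 1 -> center 4)."""

    groups: Sequence[GroupSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.groups) != 4:
            raise ValueError(f"exactly four groups required, got {len(self.groups)}")


def center_of_mass(structure: Structure, group: GroupSpec) -> np.ndarray:
    """Mass-weighted mean position (Angstrom) of the atoms selected by ``group``.

    With ``mass_weighted=False`` the unweighted centroid is returned.
    """
    idx = group.resolve(structure)
    coords = structure.coord[idx]
    if not group.mass_weighted:
        return coords.mean(axis=0)
    w = structure.mass[idx]
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def pseudo_dihedral(p1, p2, p3, p4, collinear_tol: float = 1e-10) -> float:
    """Dihedral angle (degrees, wrapped to (-180, 180]) about the p2-p3 axis.

    Sign follows the IUPAC convention (positive = clockwise rotation of the
    p3->p4 bond relative to the p1->p2 bond, looking from p2 towards p3).
    Collinear p1,p2,p3 or p2,p3,p4 (plane normal below ``collinear_tol``
    Angstrom^2) raise :class:`DihedralUndefinedError`.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        raise DihedralUndefinedError("p2 and p3 coincide; axis undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < collinear_tol or np.linalg.norm(n2) < collinear_tol:
        raise DihedralUndefinedError("collinear centers; dihedral undefined")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def pseudo_dihedral_from_structure(
    structure: Structure, spec: PseudoDihedralSpec
) -> float:
    """Evaluate the flipping pseudo-dihedral (degrees) on a structure."""
    indices = [g.resolve(structure) for g in spec.groups]
    for i in range(4):
        for j in range(i + 1, 4):
            if np.intersect1d(indices[i], indices[j]).size:
                warnings.warn(
                    f"pseudo-center groups {i + 1} and {j + 1} share atoms",
                    stacklevel=2,
                )
    centers = [center_of_mass(structure, g) for g in spec.groups]
    return pseudo_dihedral(*centers)
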