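"""Rigid-body superposition of protein-DNA structures and size proxies.

Thin structural layer over :mod:`biotite`: parse and write PDB text,
select ordered atom subsets, fit least-squares (Kabsch) rigid
transforms between matched coordinate lists, compose multi-chain
complexes, and measure a complex's *transverse extent* — the diameter
of its projection onto the plane perpendicular to the DNA axis.  The
transverse extent is the geometric rationale for interpreting gel
mobility: a complex with factors bound on opposite helix faces projects
wider than the same factors stacked on one face, and wider complexes
migrate more slowly in a native gel.

Real crystal structures are supported as plain PDB files supplied by
the caller; nothing is ever downloaded.  The synthetic module builds
toy fixtures with the same reader/writer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io

from .exceptions import (
    CapacityError,
    FormatError,
    InputError,
    NumericalError,
    SelectionError,
)

__all__ = [
    "Structure",
    "RigidTransform",
    "make_structure",
    "parse_structure",
    "read_pdb",
    "write_pdb",
    "concatenate",
    "select_atoms",
    "superpose",
    "apply_transform",
    "compose_complex",
    "transverse_extent",
    "CHAIN_ID_ALPHABET",
]

#: Legal single-character PDB chain identifiers, in assignment order.
CHAIN_ID_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass(frozen=True)
class Structure:
    """An atom array with provenance metadata."""

    atoms: struc.AtomArray
    source: str = ""

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise InputError("structure has no atoms")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise InputError("structure has non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.atoms.coord)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation + translation with the RMSD of the fit."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise InputError(f"rotation must be proper (det 1), got det {det}")
        if self.rmsd < 0:
            raise InputError("rmsd must be >= 0")

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def make_structure(
    coords: np.ndarray,
    chain_id: str = "A",
    atom_name: str = "CA",
    res_name: str = "ALA",
    element: str = "C",
    res_start: int = 1,
    source: str = "generated",
) -> Structure:
    """Build a one-atom-per-residue structure from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be (n, 3)")
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.full(n, chain_id)
    atoms.res_id = np.arange(res_start, res_start + n)
    atoms.res_name = np.full(n, res_name)
    atoms.atom_name = np.full(n, atom_name)
    atoms.element = np.full(n, element)
    atoms.hetero = np.full(n, False)
    return Structure(atoms=atoms, source=source)


def _check_coordinate_fields(pdb_text: str) -> None:
    """Locate the first malformed ATOM/HETATM coordinate, if any."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"line {lineno}: truncated coordinate record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                ) from None


def parse_structure(pdb_text: str, source: str = "") -> Structure:
    """Parse PDB text into a :class:`Structure` (first model only).

    Raises :class:`FormatError` when no ATOM/HETATM records are present
    or a coordinate field cannot be parsed (reported with its line
    number).
    """
    if not any(
        line.startswith(("ATOM", "HETATM")) for line in pdb_text.splitlines()
    ):
        raise FormatError("no ATOM/HETATM records found")
    _check_coordinate_fields(pdb_text)
    try:
        pdb_file = pdb_io.PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb_file.get_structure(model=1)
    except Exception as exc:  # malformed non-coordinate fields
        raise FormatError(f"PDB parse failure: {exc}") from exc
    return Structure(atoms=atoms, source=source)


def read_pdb(path) -> Structure:
    with open(path) as fh:
        return parse_structure(fh.read(), source=str(path))


def write_pdb(structure: Structure) -> str:
    """Render a structure as PDB text (wwPDB fixed-width columns)."""
    pdb_file = pdb_io.PDBFile()
    pdb_file.set_structure(structure.atoms)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()


def concatenate(structures: list[Structure]) -> Structure:
    """Concatenate structures into one (chain ids taken as-is)."""
    if not structures:
        raise InputError("nothing to concatenate")
    atoms = structures[0].atoms
    for s in structures[1:]:
        atoms = atoms + s.atoms
    return Structure(atoms=atoms, source="+".join(s.source for s in structures))


def select_atoms(
    structure: Structure,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: list[str] | None = None,
) -> np.ndarray:
    """Ordered coordinates of a chain/residue-range/atom-name selection.

    Atoms are returned in residue order (then input order within a
    residue).  An empty selection raises :class:`SelectionError`
    naming the criteria.
    """
    atoms = structure.atoms
    mask = np.ones(atoms.array_length(), dtype=bool)
    if chain is not None:
        mask &= atoms.chain_id == chain
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (atoms.res_id >= lo) & (atoms.res_id <= hi)
    if atom_names is not None:
        mask &= np.isin(atoms.atom_name, atom_names)
    if not mask.any():
        raise SelectionError(
            f"empty selection (chain={chain!r}, residues={residue_range!r}, "
            f"atoms={atom_names!r})"
        )
    sub = atoms[mask]
    order = np.argsort(sub.res_id, kind="stable")
    return np.asarray(sub.coord[order], dtype=float)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (Kabsch).

    Point lists must be equal-length (>= 3) and matched by index.
    Returns the proper rotation and translation minimizing the RMSD,
    together with that RMSD.  Collinear point sets leave the rotation
    about the common axis undetermined and raise
    :class:`NumericalError`.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise InputError(
            f"point counts differ: {moving.shape[0]} vs {fixed.shape[0]}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise InputError("need >= 3 matched 3-D points")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    am = moving - mu_m
    af = fixed - mu_f
    if np.linalg.matrix_rank(am, tol=1e-8) < 2 or np.linalg.matrix_rank(af, tol=1e-8) < 2:
        raise NumericalError("collinear point set: rotation is underdetermined")
    # Kabsch via SVD of the covariance, with the proper-rotation sign fix
    h = am.T @ af
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_f - rot @ mu_m
    fitted = moving @ rot.T + trans
    return RigidTransform(rotation=rot, translation=trans, rmsd=_rmsd(fitted, fixed))


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    """Return a copy of the structure with the transform applied."""
    atoms = structure.atoms.copy()
    atoms.coord = transform(atoms.coord)
    return Structure(atoms=atoms, source=structure.source)


def compose_complex(
    dna_model: Structure,
    placements: list[tuple[Structure, RigidTransform]],
) -> Structure:
    """Assemble DNA plus transformed factor structures into one complex.

    Chain ids are deduplicated deterministically: the DNA keeps its
    chains; each placed structure's chains are renamed to the next
    unused ids in :data:`CHAIN_ID_ALPHABET`.  More than 62 chains is a
    capacity error (the PDB format has single-character chain ids).
    """
    used = set(dna_model.chain_ids)
    pool = (c for c in CHAIN_ID_ALPHABET if c not in used)
    parts = [dna_model]
    for structure, transform in placements:
        placed = apply_transform(structure, transform)
        atoms = placed.atoms.copy()
        mapping = {}
        for old in placed.chain_ids:
            try:
                mapping[old] = next(pool)
            except StopIteration:
                raise CapacityError(
                    "chain-id alphabet exhausted (> 62 chains)"
                ) from None
        atoms.chain_id = np.array(
            [mapping[str(c)] for c in atoms.chain_id], dtype="U4"
        )
        parts.append(Structure(atoms=atoms, source=placed.source))
    return concatenate(parts)


def transverse_extent(
    structure: Structure | np.ndarray, axis_direction=(0.0, 0.0, 1.0)
) -> float:
    """Diameter of the projection perpendicular to ``axis_direction``.

    The maximum pairwise distance between atom positions projected onto
    the plane normal to the axis: a rotation-about-axis and
    translation-invariant proxy for how wide the complex is as a gel
    sees it.  A single atom has extent 0.
    """
    coords = (
        structure.coords if isinstance(structure, Structure) else np.asarray(structure)
    )
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise InputError("need a non-empty (n, 3) coordinate array")
    u = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise InputError("axis direction must be nonzero")
    u = u / norm
    proj = coords - np.outer(coords @ u, u)
    if proj.shape[0] == 1:
        return 0.0
    # exact O(n^2) max pairwise distance; fixture-scale inputs are small
    diff = proj[:, None, :] - proj[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())
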