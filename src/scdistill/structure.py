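"""Backbone structure container, PDB input/output and rigid superposition.

A :class:`BackboneStructure` is an ordered chain of residues represented at
least by their C-alpha coordinates (Angstrom).  It is the operand of the
structure-similarity metrics in :mod:`scdistill.metrics` and of the
neighbor-density classification used for core/surface analysis.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as _struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "BackboneStructure",
    "Superposition",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "kabsch_superpose",
]


class PDBParseError(ValueError):
    """Raised for malformed or unusable PDB input."""


# Three-letter -> one-letter amino-acid codes (standard 20; anything else -> X).
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


@dataclasses.dataclass
class BackboneStructure:
    """Ordered residue chain with C-alpha coordinates in Angstrom.

    ``residue_ids`` are internal, strictly increasing integers (0-based).
    Author numbering (``auth_res_ids``), insertion codes and chain id from a
    source PDB file are kept as metadata so that round-trip writing preserves
    them; residue order always follows the source file.
    ``atom_records`` optionally holds, per residue, a list of
    ``(atom_name, xyz)`` tuples for all-atom distance tests.
    """

    ca_coords: np.ndarray
    sequence: Optional[str] = None
    residue_ids: Optional[np.ndarray] = None
    auth_res_ids: Optional[np.ndarray] = None
    ins_codes: Optional[list] = None
    chain_id: str = "A"
    atom_records: Optional[list] = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if self.ca_coords.ndim != 2 or self.ca_coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (n, 3) array")
        n = len(self.ca_coords)
        if n == 0:
            raise ValueError("structure must contain at least one residue")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError("coordinates must be finite")
        if self.residue_ids is None:
            self.residue_ids = np.arange(n)
        else:
            self.residue_ids = np.asarray(self.residue_ids, dtype=int)
            if len(self.residue_ids) != n:
                raise ValueError("residue_ids length mismatch")
            if np.any(np.diff(self.residue_ids) <= 0):
                raise ValueError("residue_ids must be strictly increasing")
        if self.sequence is not None and len(self.sequence) != n:
            raise ValueError("sequence length must match number of residues")
        if self.atom_records is not None and len(self.atom_records) != n:
            raise ValueError("atom_records length must match number of residues")

    def __len__(self) -> int:
        return len(self.ca_coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a copy with ``x -> R x + t`` applied to all coordinates."""
        rot = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = None
        if self.atom_records is not None:
            new_atoms = [
                [(name, rot @ np.asarray(xyz, float) + t) for name, xyz in res]
                for res in self.atom_records
            ]
        return dataclasses.replace(
            self,
            ca_coords=self.ca_coords @ rot.T + t,
            residue_ids=self.residue_ids.copy(),
            atom_records=new_atoms,
        )


@dataclasses.dataclass(frozen=True)
class Superposition:
    """Proper rigid transform ``x -> rotation @ x + translation`` with its RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if not np.isclose(det, 1.0, atol=1e-6):
            raise ValueError(f"rotation must be proper (det=+1), got det={det:.6f}")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Uses the Kabsch/Umeyama solution (via SVD) restricted to proper
    rotations; reflections are never returned.  For degenerate (e.g.
    collinear) point sets the rotation about the degenerate axis is not
    unique; the deterministic SVD solution is returned as documented
    fallback and still minimizes the RMSD.

    Raises
    ------
    ValueError
        If the point sets differ in size, contain fewer than 3 points or
        non-finite coordinates.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3) arrays of equal n")
    n = len(moving)
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("coordinates must be finite")
    mov_mean = moving.mean(axis=0)
    fix_mean = fixed.mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        # align_vectors warns on rank-deficient (collinear) inputs; the
        # returned rotation is still a valid minimizer (documented fallback).
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(fixed - fix_mean, moving - mov_mean)
    R = rot.as_matrix()
    t = fix_mean - R @ mov_mean
    return Superposition(rotation=R, translation=t, rmsd=float(rssd) / np.sqrt(n))


def read_pdb(path, chain: Optional[str] = None) -> BackboneStructure:
    """Read a PDB file into a :class:`BackboneStructure` (one residue per CA).

    Residues appear in file order; insertion codes are preserved in the
    ordering and metadata.  ``chain`` selects a chain id; by default the
    first chain containing ATOM records is used.

    Raises
    ------
    PDBParseError
        On empty files, files without ATOM records (e.g. HETATM-only), or
        residues that have ATOM records but no CA atom (named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise PDBParseError(f"empty PDB file: {path}")
    pdb = PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # malformed coordinate block
        raise PDBParseError(f"could not parse {path}: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path} contains no ATOM records (HETATM-only or empty)")
    chains = list(dict.fromkeys(atoms.chain_id))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise PDBParseError(f"chain {chain!r} not found in {path}; available: {chains}")
    atoms = atoms[atoms.chain_id == chain]

    ca_coords, seq, auth_ids, icodes, atom_records = [], [], [], [], []
    # group consecutive atoms by (res_id, ins_code, res_name), keeping file order
    starts = _struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        res = atoms[lo:hi]
        names = list(res.atom_name)
        if "CA" not in names:
            rid = int(res.res_id[0])
            rname = str(res.res_name[0])
            raise PDBParseError(
                f"residue {rname} {rid}{str(res.ins_code[0]).strip()} in chain "
                f"{chain} has no CA atom"
            )
        ca = res[np.asarray(names) == "CA"][0]
        ca_coords.append(ca.coord)
        seq.append(_THREE_TO_ONE.get(str(res.res_name[0]), "X"))
        auth_ids.append(int(res.res_id[0]))
        icodes.append(str(res.ins_code[0]))
        atom_records.append([(str(a.atom_name), np.array(a.coord, float)) for a in res])
    return BackboneStructure(
        ca_coords=np.array(ca_coords, float),
        sequence="".join(seq),
        auth_res_ids=np.array(auth_ids),
        ins_codes=icodes,
        chain_id=str(chain),
        atom_records=atom_records,
    )


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write a C-alpha-only PDB file (coordinates at standard 1e-3 A precision)."""
    n = len(structure)
    arr = _struc.AtomArray(n)
    arr.coord = np.asarray(structure.ca_coords, float)
    arr.chain_id[:] = structure.chain_id or "A"
    if structure.auth_res_ids is not None:
        arr.res_id[:] = np.asarray(structure.auth_res_ids, int)
    else:
        arr.res_id[:] = np.asarray(structure.residue_ids, int) + 1  # 1-based in files
    if structure.ins_codes is not None:
        arr.ins_code[:] = [c.strip() for c in structure.ins_codes]
    seq = structure.sequence or "X" * n
    arr.res_name[:] = [_ONE_TO_THREE.get(c, "UNK") for c in seq]
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
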