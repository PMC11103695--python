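"""Annotated electronic systems and their on-disk bundle format.

An :class:`ElectronicSystem` carries the one-electron (Fock) Hamiltonian
``H0`` and the basis overlap matrix ``S0`` of a DNA fragment, in eV, together
with an atom table mapping orbital ranges to atoms, bases, strands, helices
and region tags.  It is the universal input of the pipeline: real matrices
exported from a quantum-chemistry code and synthetic tight-binding matrices
go through exactly the same object.

Bundles are stored in HDF5 (lower triangles only, since both matrices are
real symmetric) or, for small plain-text fixtures, as a TSV directory.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .errors import AnnotationError, FormatError, ValidationError

FORMAT_VERSION = "1"

#: Column order of the atom annotation table.  ``pos`` is the axial
#: base-pair index of the atom within its helix (a backbone site linking
#: bases p and p+1 carries p); it distinguishes the two ends of a helix.
ATOM_COLUMNS = (
    "atom_id",
    "element",
    "orbital_offset",
    "orbital_count",
    "base_id",
    "base_label",
    "strand_id",
    "helix_id",
    "region",
    "pos",
)

_INT_COLUMNS = ("atom_id", "orbital_offset", "orbital_count", "base_id", "helix_id", "pos")
_STR_COLUMNS = ("element", "base_label", "strand_id", "region")

HERMITICITY_TOL = 1e-10


def _as_symmetric(name: str, m: np.ndarray, tol: float = HERMITICITY_TOL) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {m.shape}")
    asym = float(np.max(np.abs(m - m.T))) if m.size else 0.0
    if asym > tol:
        raise ValidationError(
            f"{name} is not symmetric: max asymmetry {asym:.3e} > {tol:.1e}"
        )
    return m


def _normalize_atoms(atoms: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
    if missing:
        raise AnnotationError(f"atom table is missing columns: {missing}")
    atoms = atoms.loc[:, list(ATOM_COLUMNS)].reset_index(drop=True)
    for c in _INT_COLUMNS:
        atoms[c] = atoms[c].astype(np.int64)
    for c in _STR_COLUMNS:
        atoms[c] = atoms[c].astype(str)
    return atoms


def validate_atom_coverage(atoms: pd.DataFrame, n_orb: int) -> None:
    """Check that atom orbital ranges are disjoint, contiguous and cover [0, n_orb)."""
    if atoms["atom_id"].duplicated().any():
        raise AnnotationError("duplicate atom_id in annotation table")
    order = atoms.sort_values("orbital_offset")
    expected = 0
    for aid, off, cnt in zip(order["atom_id"], order["orbital_offset"], order["orbital_count"]):
        if cnt < 1:
            raise AnnotationError(f"atom {aid} has orbital_count {cnt} < 1")
        if off < expected:
            raise AnnotationError(
                f"atom {aid} orbital range [{off}, {off + cnt}) overlaps the previous atom"
            )
        if off > expected:
            raise AnnotationError(
                f"gap in orbital coverage before atom {aid}: [{expected}, {off}) unassigned"
            )
        expected = off + cnt
    if expected != n_orb:
        raise AnnotationError(
            f"atom orbital ranges cover [0, {expected}) but the matrices have {n_orb} orbitals"
        )


@dataclass
class ElectronicSystem:
    """Hamiltonian + overlap + annotation, the pipeline's universal input.

    Parameters
    ----------
    hamiltonian : ndarray
        Real-symmetric one-electron Hamiltonian ``H0`` in eV.
    overlap : ndarray
        Symmetric positive-definite overlap matrix ``S0`` (dimensionless).
        Positive definiteness is checked lazily (see :meth:`min_overlap_eigenvalue`).
    atoms : DataFrame
        Annotation table with the columns in :data:`ATOM_COLUMNS`.
    n_occupied : int
        Number of doubly occupied molecular orbitals.
    metadata : dict
        Free-form provenance map (stored as JSON in bundles).
    """

    hamiltonian: np.ndarray
    overlap: np.ndarray
    atoms: pd.DataFrame
    n_occupied: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hamiltonian = _as_symmetric("hamiltonian", self.hamiltonian)
        self.overlap = _as_symmetric("overlap", self.overlap)
        if self.overlap.shape != self.hamiltonian.shape:
            raise ValidationError(
                f"overlap shape {self.overlap.shape} != hamiltonian shape "
                f"{self.hamiltonian.shape}"
            )
        self.atoms = _normalize_atoms(self.atoms)
        validate_atom_coverage(self.atoms, self.n_orb)
        if not 0 < int(self.n_occupied) < self.n_orb:
            raise ValidationError(
                f"n_occupied must satisfy 0 < n_occupied < n_orb={self.n_orb}, "
                f"got {self.n_occupied}"
            )
        self.n_occupied = int(self.n_occupied)
        self._min_overlap_eig: float | None = None

    @property
    def n_orb(self) -> int:
        return self.hamiltonian.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def orbital_slice(self, atom_id: int) -> slice:
        """Orbital index range of one atom."""
        row = self.atoms.loc[self.atoms["atom_id"] == atom_id]
        if row.empty:
            raise AnnotationError(f"unknown atom_id {atom_id}")
        off = int(row["orbital_offset"].iloc[0])
        cnt = int(row["orbital_count"].iloc[0])
        return slice(off, off + cnt)

    def min_overlap_eigenvalue(self) -> float:
        """Smallest eigenvalue of the overlap matrix (cached)."""
        if self._min_overlap_eig is None:
            self._min_overlap_eig = float(np.linalg.eigvalsh(self.overlap)[0])
        return self._min_overlap_eig

    def equals(self, other: "ElectronicSystem") -> bool:
        """Field-by-field equality (bit-exact matrices, identical annotations)."""
        return (
            np.array_equal(self.hamiltonian, other.hamiltonian)
            and np.array_equal(self.overlap, other.overlap)
            and self.atoms.equals(other.atoms)
            and self.n_occupied == other.n_occupied
            and self.metadata == other.metadata
        )


def _pack_lower(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(m.shape[0])]


def _unpack_lower(vals: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    i, j = np.tril_indices(n)
    m[i, j] = vals
    m[j, i] = vals
    return m


def save_system(system: ElectronicSystem, path: str | os.PathLike) -> Path:
    """Write a system bundle.

    ``.h5``/``.hdf5`` suffixes select the HDF5 layout; anything else is
    written as a plain-text TSV directory (small fixtures only).
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _save_hdf5(system, path)
    else:
        _save_tsv(system, path)
    return path


def load_system(path: str | os.PathLike) -> ElectronicSystem:
    """Read a system bundle written by :func:`save_system`.

    All :class:`ElectronicSystem` invariants are re-validated; symmetric
    matrices are reconstructed from their stored lower triangles.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such bundle: {path}")
    if path.is_dir():
        return _load_tsv(path)
    return _load_hdf5(path)


def _save_hdf5(system: ElectronicSystem, path: Path) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["n_orb"] = np.int64(system.n_orb)
        f.attrs["n_occupied"] = np.int64(system.n_occupied)
        f.attrs["energy_unit"] = "eV"
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["metadata_json"] = json.dumps(system.metadata, sort_keys=True, default=str)
        gh = f.create_group("hamiltonian")
        gh.create_dataset("lower", data=_pack_lower(system.hamiltonian),
                          dtype="f8", track_times=False)
        gs = f.create_group("overlap")
        gs.create_dataset("lower", data=_pack_lower(system.overlap),
                          dtype="f8", track_times=False)
        ga = f.create_group("atoms")
        for col in ATOM_COLUMNS:
            data = system.atoms[col].to_numpy()
            if col in _STR_COLUMNS:
                ga.create_dataset(col, data=data.astype(object), dtype=str_dt,
                                  track_times=False)
            else:
                ga.create_dataset(col, data=data.astype(np.int64), track_times=False)


def _load_hdf5(path: Path) -> ElectronicSystem:
    with h5py.File(path, "r") as f:
        for key in ("n_orb", "n_occupied"):
            if key not in f.attrs:
                raise FormatError(f"bundle {path} is missing attribute '{key}'")
        n = int(f.attrs["n_orb"])
        n_occ = int(f.attrs["n_occupied"])
        try:
            h = _unpack_lower(np.asarray(f["hamiltonian/lower"]), n)
        except KeyError:
            raise FormatError(f"bundle {path} is missing dataset 'hamiltonian/lower'")
        try:
            s = _unpack_lower(np.asarray(f["overlap/lower"]), n)
        except KeyError:
            raise FormatError(f"bundle {path} is missing dataset 'overlap/lower'")
        if "atoms" not in f:
            raise FormatError(f"bundle {path} is missing group 'atoms'")
        cols: dict[str, Any] = {}
        for col in ATOM_COLUMNS:
            if col not in f["atoms"]:
                raise FormatError(f"bundle {path} is missing dataset 'atoms/{col}'")
            data = np.asarray(f["atoms"][col])
            if col in _STR_COLUMNS:
                data = np.array([x.decode() if isinstance(x, bytes) else str(x)
                                 for x in data])
            cols[col] = data
        metadata = json.loads(f.attrs.get("metadata_json", "{}"))
    atoms = pd.DataFrame(cols)
    return ElectronicSystem(hamiltonian=h, overlap=s, atoms=atoms,
                            n_occupied=n_occ, metadata=metadata)


def _save_tsv(system: ElectronicSystem, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    i, j = np.tril_indices(system.n_orb)
    lines = ["matrix\trow\tcol\tvalue"]
    for name, m in (("hamiltonian", system.hamiltonian), ("overlap", system.overlap)):
        for r, c in zip(i, j):
            # repr() round-trips float64 exactly; pandas' writer does not
            lines.append(f"{name}\t{r}\t{c}\t{float(m[r, c])!r}")
    (path / "matrix.tsv").write_text("\n".join(lines) + "\n")
    system.atoms.to_csv(path / "atoms.tsv", sep="\t", index=False)
    meta = {
        "n_orb": system.n_orb,
        "n_occupied": system.n_occupied,
        "energy_unit": "eV",
        "format_version": FORMAT_VERSION,
        "metadata": system.metadata,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True,
                                               default=str) + "\n")


def _load_tsv(path: Path) -> ElectronicSystem:
    for fname in ("matrix.tsv", "atoms.tsv", "meta.json"):
        if not (path / fname).exists():
            raise FormatError(f"TSV bundle {path} is missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    for key in ("n_orb", "n_occupied"):
        if key not in meta:
            raise FormatError(f"TSV bundle {path}: meta.json is missing '{key}'")
    n = int(meta["n_orb"])
    rows = pd.read_csv(path / "matrix.tsv", sep="\t", float_precision="round_trip")
    mats: dict[str, np.ndarray] = {}
    for name in ("hamiltonian", "overlap"):
        sub = rows[rows["matrix"] == name]
        if len(sub) != n * (n + 1) // 2:
            raise FormatError(
                f"TSV bundle {path}: matrix '{name}' has {len(sub)} lower-triangle "
                f"entries, expected {n * (n + 1) // 2}"
            )
        m = np.zeros((n, n))
        r = sub["row"].to_numpy(dtype=int)
        c = sub["col"].to_numpy(dtype=int)
        m[r, c] = sub["value"].to_numpy(dtype=float)
        m[c, r] = m[r, c]
        mats[name] = m
    atoms = pd.read_csv(path / "atoms.tsv", sep="\t")
    return ElectronicSystem(hamiltonian=mats["hamiltonian"], overlap=mats["overlap"],
                            atoms=atoms, n_occupied=int(meta["n_occupied"]),
                            metadata=meta.get("metadata", {}))
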