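"""Basis transformations and spectrum analysis.

Two changes of basis take a non-orthogonal Fock/overlap pair to the
atom-block form used by the transport and DOS stages:

1. **Löwdin symmetric orthogonalization** — ``H_orth = S^{-1/2} H0 S^{-1/2}``,
   which preserves the generalized spectrum of ``(H0, S0)`` while making the
   basis orthonormal.
2. **Per-atom block diagonalization** — the orthogonalized matrix is
   partitioned into atomic blocks; each diagonal block is diagonalized by a
   unitary so that diagonal elements become atomic molecular-orbital
   energies and off-diagonal blocks become inter-atomic hopping matrices.

Both steps are exactly unitary (up to round-off), so the global spectrum is
conserved end to end — the property the test suite leans on hardest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigurationError, NearSingularOverlapError, ValidationError
from .system import ElectronicSystem, HERMITICITY_TOL, validate_atom_coverage

__all__ = [
    "AtomBlockHamiltonian",
    "EnergyLevels",
    "lowdin_orthogonalize",
    "atom_block_transform",
    "spectrum_analysis",
    "align_to_homo",
]


def lowdin_orthogonalize(
    system: ElectronicSystem, min_eig_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric (Löwdin) orthogonalization of a Fock/overlap pair.

    Computes ``S^{-1/2}`` by eigendecomposition of the overlap matrix and
    returns ``(H_orth, X)`` with ``H_orth = X H0 X`` and ``X = S^{-1/2}``.

    Raises
    ------
    NearSingularOverlapError
        If the smallest overlap eigenvalue is at or below ``min_eig_tol``;
        the basis is then (numerically) linearly dependent.
    """
    w, u = np.linalg.eigh(system.overlap)
    if w[0] <= min_eig_tol:
        raise NearSingularOverlapError(w[0], min_eig_tol)
    x = (u * (1.0 / np.sqrt(w))) @ u.T
    h_orth = x @ system.hamiltonian @ x
    h_orth = 0.5 * (h_orth + h_orth.T)  # kill round-off asymmetry
    return h_orth, x


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


@dataclass
class AtomBlockHamiltonian:
    """Orthogonalized Hamiltonian in the per-atom molecular-orbital basis.

    ``matrix`` has atomic MO energies on its within-atom diagonal blocks
    (which are diagonal) and inter-atomic hopping parameters on the
    off-diagonal blocks.  ``block_transforms`` maps atom_id to the unitary
    applied to that atom's orbitals; ``atom_eigenvalues`` maps atom_id to its
    ascending atomic MO energies (eV).
    """

    matrix: np.ndarray
    block_transforms: dict[int, np.ndarray]
    atom_eigenvalues: dict[int, np.ndarray]
    atoms: pd.DataFrame
    n_occupied: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_orb(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def orbital_slice(self, atom_id: int) -> slice:
        row = self.atoms.loc[self.atoms["atom_id"] == atom_id]
        off = int(row["orbital_offset"].iloc[0])
        return slice(off, off + int(row["orbital_count"].iloc[0]))

    def eigenvalues(self) -> np.ndarray:
        """Global spectrum (ascending), identical to the source generalized spectrum."""
        return np.linalg.eigvalsh(self.matrix)


def atom_block_transform(
    orth: np.ndarray,
    atoms: pd.DataFrame,
    n_occupied: int | None = None,
    metadata: dict | None = None,
) -> AtomBlockHamiltonian:
    """Partition an orthogonalized matrix into atoms and diagonalize each block.

    The within-atom unitaries order atomic MOs by ascending eigenvalue with a
    deterministic sign convention (largest-magnitude component positive), so
    the resulting hopping blocks are reproducible.
    """
    orth = np.asarray(orth, dtype=float)
    asym = float(np.max(np.abs(orth - orth.T)))
    if asym > HERMITICITY_TOL:
        raise ValidationError(
            f"input matrix is not symmetric: max asymmetry {asym:.3e}"
        )
    validate_atom_coverage(atoms, orth.shape[0])

    u_full = np.zeros_like(orth)
    transforms: dict[int, np.ndarray] = {}
    eigenvalues: dict[int, np.ndarray] = {}
    for row in atoms.itertuples(index=False):
        sl = slice(int(row.orbital_offset), int(row.orbital_offset) + int(row.orbital_count))
        w, v = np.linalg.eigh(orth[sl, sl])
        v = _fix_eigenvector_signs(v)
        transforms[int(row.atom_id)] = v
        eigenvalues[int(row.atom_id)] = w
        u_full[sl, sl] = v
    h = u_full.T @ orth @ u_full
    h = 0.5 * (h + h.T)
    return AtomBlockHamiltonian(
        matrix=h,
        block_transforms=transforms,
        atom_eigenvalues=eigenvalues,
        atoms=atoms.reset_index(drop=True),
        n_occupied=n_occupied,
        metadata=dict(metadata or {}),
    )


def to_atom_blocks(system: ElectronicSystem, min_eig_tol: float = 1e-8) -> AtomBlockHamiltonian:
    """Convenience driver: Löwdin orthogonalize then atom-block transform."""
    h_orth, _ = lowdin_orthogonalize(system, min_eig_tol=min_eig_tol)
    return atom_block_transform(
        h_orth, system.atoms, n_occupied=system.n_occupied, metadata=dict(system.metadata)
    )


@dataclass
class EnergyLevels:
    """A HOMO/LUMO window of the spectrum.

    ``levels`` holds the requested occupied + unoccupied levels sorted
    ascending; ``homo_index`` is the global index of the HOMO
    (``n_occupied - 1``); ``separations`` lists consecutive occupied-level
    gaps walking down from the HOMO (first entry = HOMO − HOMO-1), in eV.
    """

    levels: np.ndarray
    homo_index: int
    homo: float
    lumo: float
    gap: float
    separations: np.ndarray

    def shifted(self, offset: float) -> "EnergyLevels":
        return EnergyLevels(
            levels=self.levels + offset,
            homo_index=self.homo_index,
            homo=self.homo + offset,
            lumo=self.lumo + offset,
            gap=self.gap,
            separations=self.separations.copy(),
        )


SpectrumSource = Union[ElectronicSystem, AtomBlockHamiltonian, np.ndarray]


def _full_spectrum(obj: SpectrumSource) -> tuple[np.ndarray, int | None]:
    if isinstance(obj, ElectronicSystem):
        return scipy.linalg.eigh(obj.hamiltonian, obj.overlap, eigvals_only=True), obj.n_occupied
    if isinstance(obj, AtomBlockHamiltonian):
        return obj.eigenvalues(), obj.n_occupied
    return np.sort(np.asarray(obj, dtype=float)), None


def spectrum_analysis(
    obj: SpectrumSource,
    n_levels_occ: int = 20,
    n_levels_unocc: int = 10,
    n_occupied: int | None = None,
) -> EnergyLevels:
    """HOMO/LUMO/gap analysis of a system's spectrum.

    For an :class:`ElectronicSystem` the generalized eigenproblem
    ``(H0, S0)`` is solved; for an :class:`AtomBlockHamiltonian` the matrix
    is diagonalized directly (the two agree, by spectrum conservation).
    A raw sorted level array may also be passed with an explicit
    ``n_occupied``.
    """
    levels, n_occ = _full_spectrum(obj)
    if n_occupied is not None:
        n_occ = n_occupied
    if n_occ is None:
        raise ConfigurationError("n_occupied is not set; cannot locate the HOMO")
    n_occ = int(n_occ)
    if not 0 < n_occ < len(levels):
        raise ConfigurationError(
            f"n_occupied={n_occ} incompatible with {len(levels)} levels"
        )
    if n_levels_occ > n_occ:
        raise ConfigurationError(
            f"requested {n_levels_occ} occupied levels but only {n_occ} exist"
        )
    if n_levels_unocc > len(levels) - n_occ:
        raise ConfigurationError(
            f"requested {n_levels_unocc} unoccupied levels but only "
            f"{len(levels) - n_occ} exist"
        )
    homo_index = n_occ - 1
    occ = levels[n_occ - n_levels_occ : n_occ]
    unocc = levels[n_occ : n_occ + n_levels_unocc]
    homo = float(levels[homo_index])
    lumo = float(levels[n_occ])
    # consecutive occupied gaps walking down from the HOMO: HOMO−HOMO-1 first
    seps = -np.diff(occ[::-1]) if n_levels_occ > 1 else np.array([])
    return EnergyLevels(
        levels=np.concatenate([occ, unocc]),
        homo_index=homo_index,
        homo=homo,
        lumo=lumo,
        gap=lumo - homo,
        separations=np.asarray(seps, dtype=float),
    )


def align_to_homo(obj, homo: float):
    """Shift energies so the HOMO maps to zero.

    Accepts an :class:`EnergyLevels` (returns a shifted copy) or any array of
    energies (returns ``array - homo``).
    """
    if not np.isfinite(homo):
        raise ValueError(f"homo must be finite, got {homo}")
    if isinstance(obj, EnergyLevels):
        return obj.shifted(-float(homo))
    return np.asarray(obj, dtype=float) - float(homo)
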