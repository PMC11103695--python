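"""Per-atom density of states and orbital-localization analysis.

The atom-projected DOS is ``D_m(E) = -(1/pi) * sum_{a in m} Im G^r_aa(E)``,
evaluated with the same Green's function the transport stage uses (contact
and probe self-energies included), so the DOS and the transmission describe
one and the same open system.  A bare-broadening mode (constant ``i*eta``)
is retained for purely spectral checks.

Aggregations sum member-atom rows to base / strand / helix / region
resolution — the long-format tables behind strand-resolved 2D DOS maps.
Localization profiles project global eigenvectors onto the same groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .basis import AtomBlockHamiltonian
from .errors import AnnotationError
from .transport import ContactSpec, build_self_energies, retarded_green

GROUP_COLUMNS = {
    "base": "base_id",
    "strand": "strand_id",
    "helix": "helix_id",
    "region": "region",
}


def _group_column(by: str) -> str:
    if by not in GROUP_COLUMNS:
        raise AnnotationError(
            f"unknown grouping '{by}'; choose one of {sorted(GROUP_COLUMNS)}"
        )
    return GROUP_COLUMNS[by]


@dataclass
class DOSField:
    """Density of states resolved on some partition of the system.

    ``dos[k]`` is the DOS row (states/eV) of ``labels[k]`` over ``energies``.
    ``level`` names the resolution ("atom" or an aggregation key); ``atoms``
    keeps the annotation table so aggregations can be re-derived.
    """

    energies: np.ndarray
    dos: np.ndarray
    labels: list
    level: str
    atoms: pd.DataFrame

    @property
    def total(self) -> np.ndarray:
        """Total DOS over the whole system, independent of resolution."""
        return self.dos.sum(axis=0)

    def row(self, label) -> np.ndarray:
        return self.dos[self.labels.index(label)]

    def integrate(self, emin: float | None = None, emax: float | None = None) -> np.ndarray:
        """Trapezoid integral of each row over [emin, emax] (defaults: full grid)."""
        emin = self.energies[0] if emin is None else emin
        emax = self.energies[-1] if emax is None else emax
        mask = (self.energies >= emin) & (self.energies <= emax)
        return np.trapezoid(self.dos[:, mask], self.energies[mask], axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long format (group, energy_eV, dos)."""
        ne = len(self.energies)
        return pd.DataFrame({
            "group": np.repeat(self.labels, ne),
            "energy_eV": np.tile(self.energies, len(self.labels)),
            "dos": self.dos.ravel(),
        })


def per_atom_dos(
    block: AtomBlockHamiltonian,
    spec: ContactSpec | None,
    grid: np.ndarray,
    eta: float = 1e-6,
) -> DOSField:
    """Atom-projected DOS over an energy grid.

    With a :class:`ContactSpec` the transport Green's function is used
    (self-energies from contacts and probes); with ``spec=None`` a bare
    Lorentzian broadening ``eta`` is applied instead.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("energy grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("energy grid must be sorted ascending")
    if spec is not None:
        sigma = build_self_energies(spec, block.atoms).sigma_total
    else:
        sigma = np.zeros(block.n_orb, dtype=complex)
    atoms = block.atoms
    slices = [
        slice(int(off), int(off) + int(cnt))
        for off, cnt in zip(atoms["orbital_offset"], atoms["orbital_count"])
    ]
    dos = np.empty((len(atoms), grid.size))
    for k, energy in enumerate(grid):
        g = retarded_green(energy, block.matrix, sigma, eta=eta)
        im_diag = np.imag(np.diag(g))
        dos[:, k] = [-(1.0 / np.pi) * im_diag[sl].sum() for sl in slices]
    return DOSField(
        energies=grid, dos=dos, labels=[int(a) for a in atoms["atom_id"]],
        level="atom", atoms=atoms,
    )


def aggregate_dos(field: DOSField, by: str) -> DOSField:
    """Sum atom rows to base / strand / helix / region resolution."""
    if field.level != "atom":
        raise AnnotationError("aggregate_dos expects an atom-resolved DOSField")
    col = _group_column(by)
    atoms = field.atoms
    order = {aid: k for k, aid in enumerate(field.labels)}
    groups: list = []
    rows: list = []
    for key, sub in atoms.groupby(col, sort=True):
        idx = [order[int(a)] for a in sub["atom_id"]]
        groups.append(key)
        rows.append(field.dos[idx].sum(axis=0))
    return DOSField(
        energies=field.energies, dos=np.vstack(rows), labels=groups,
        level=by, atoms=atoms,
    )


@dataclass
class LocalizationProfile:
    """Eigenvector weight fractions on annotation groups.

    ``table`` has one row per requested orbital: its global index, energy
    (eV), and one column per group value; fractions sum to 1 per row.
    """

    by: str
    table: pd.DataFrame

    def fraction(self, orbital: int, group) -> float:
        row = self.table.loc[self.table["orbital"] == orbital]
        return float(row[group].iloc[0])


def orbital_localization(
    block: AtomBlockHamiltonian,
    orbitals: Sequence[int] | Iterable[int],
    by: str = "strand",
) -> LocalizationProfile:
    """Project global eigenvectors onto strands / helices / regions / bases.

    For eigenvector ``v`` the weight on group ``g`` is
    ``sum_{a in g} |v_a|^2``; since the basis is orthonormal the fractions
    sum to one.
    """
    col = _group_column(by)
    orbitals = [int(i) for i in orbitals]
    w, v = np.linalg.eigh(block.matrix)
    for i in orbitals:
        if not 0 <= i < block.n_orb:
            raise IndexError(f"orbital index {i} out of range [0, {block.n_orb})")
    atoms = block.atoms
    group_keys = sorted(atoms[col].unique())
    records = []
    for i in orbitals:
        amp2 = np.abs(v[:, i]) ** 2
        rec: dict = {"orbital": i, "energy_eV": float(w[i])}
        for key in group_keys:
            sub = atoms[atoms[col] == key]
            weight = 0.0
            for off, cnt in zip(sub["orbital_offset"], sub["orbital_count"]):
                weight += float(amp2[int(off): int(off) + int(cnt)].sum())
            rec[key] = weight
        records.append(rec)
    return LocalizationProfile(by=by, table=pd.DataFrame.from_records(records))
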