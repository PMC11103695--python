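"""Büttiker-probe decoherent transport.

The molecule is opened to a left and a right contact (broadening
``gamma_contact`` on every orbital of the contacted atoms) and to one
fictitious voltage probe per remaining atom (broadening ``gamma_probe``).
Each self-energy is diagonal with value ``-i*gamma/2`` per orbital, so the
stated gammas are directly the Breit–Wigner level widths.

At each energy the pipeline is

    retarded Green's function  ->  pairwise transmissions T_ij
    ->  probe chemical potentials (zero-net-current condition)
    ->  effective transmission T_eff = T_LR + sum_ij T_Li (W^-1)_ij T_jR

and the zero-bias conductance is ``G = G0 * T_eff`` at the Fermi energy,
with ``G0 = 2e^2/h`` the conductance quantum.  Probe potentials float so
that every probe carries zero net current: probes exchange carriers with
the molecule (dephasing) without acting as sources or sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.constants import physical_constants

from .basis import AtomBlockHamiltonian
from .errors import (
    AnnotationError,
    ConfigurationError,
    IllConditionedError,
    InterpolationRangeError,
    NearSingularityError,
    NotSupportedError,
    SchemeError,
)

#: Quantum of conductance 2e^2/h in siemens.
G0 = physical_constants["conductance quantum"][0]

#: Numerical safety floor for the Green's-function imaginary shift (eV).
#: Physical broadening always comes from the self-energies.
ETA_DEFAULT = 1e-6

#: Condition-number ceiling above which the probe linear system is rejected.
W_COND_MAX = 1e12

#: A probe whose total out-coupling falls below this is treated as decoupled.
DECOUPLED_TOL = 1e-14


@dataclass(frozen=True)
class ContactSpec:
    """Electrode/probe coupling specification.

    ``left_atoms``/``right_atoms`` are disjoint, nonempty sets of atom_ids;
    all orbitals of those atoms couple to the corresponding contact with
    broadening ``gamma_contact`` (eV).  Every remaining atom carries its own
    Büttiker probe with broadening ``gamma_probe`` (eV).  ``temperature`` is
    recorded for provenance but unused in the zero-bias linearization; only
    ``mu_left - mu_right`` matters for the conductance.
    """

    left_atoms: frozenset
    right_atoms: frozenset
    gamma_contact: float = 0.600
    gamma_probe: float = 0.010
    temperature: float = 300.0
    mu_left: float = 0.5
    mu_right: float = -0.5

    def __post_init__(self):
        object.__setattr__(self, "left_atoms", frozenset(int(a) for a in self.left_atoms))
        object.__setattr__(self, "right_atoms", frozenset(int(a) for a in self.right_atoms))
        if not self.left_atoms or not self.right_atoms:
            raise SchemeError("both contacts need at least one atom")
        common = self.left_atoms & self.right_atoms
        if common:
            raise SchemeError(f"atoms {sorted(common)} appear in both contacts")
        if self.gamma_contact <= 0:
            raise SchemeError("gamma_contact must be > 0")
        if self.gamma_probe < 0:
            raise SchemeError("gamma_probe must be >= 0")

    def to_dict(self) -> dict:
        return {
            "left_atoms": sorted(self.left_atoms),
            "right_atoms": sorted(self.right_atoms),
            "gamma_contact": self.gamma_contact,
            "gamma_probe": self.gamma_probe,
            "temperature": self.temperature,
            "mu_left": self.mu_left,
            "mu_right": self.mu_right,
        }


@dataclass
class SelfEnergySet:
    """Diagonal self-energies and broadenings for one contact layout.

    All arrays are length ``n_orb`` diagonals.  ``probe_atom_ids`` orders the
    probes; ``probe_gammas[k]`` is the diagonal broadening of probe ``k``.
    """

    sigma_left: np.ndarray
    sigma_right: np.ndarray
    sigma_probes: np.ndarray
    gamma_left: np.ndarray
    gamma_right: np.ndarray
    probe_atom_ids: list
    probe_gammas: list

    @property
    def sigma_total(self) -> np.ndarray:
        return self.sigma_left + self.sigma_right + self.sigma_probes

    @property
    def n_probes(self) -> int:
        return len(self.probe_atom_ids)

    def terminal_gammas(self) -> list:
        """Broadening diagonals ordered [L, R, probe_1, ..., probe_Nb]."""
        return [self.gamma_left, self.gamma_right, *self.probe_gammas]

    def terminal_labels(self) -> list:
        return ["L", "R", *[f"probe_{a}" for a in self.probe_atom_ids]]


def build_self_energies(spec: ContactSpec, atoms: pd.DataFrame) -> SelfEnergySet:
    """Construct contact and probe self-energies from an atom table.

    Each contact contributes ``-i*gamma_contact/2`` on every orbital of its
    atoms; each non-contact atom gets its own probe with
    ``-i*gamma_probe/2`` on its orbitals.  Off-diagonals are all zero.
    """
    known = set(int(a) for a in atoms["atom_id"])
    for aid in spec.left_atoms | spec.right_atoms:
        if aid not in known:
            raise AnnotationError(f"contact atom_id {aid} not in the atom table")
    n_orb = int((atoms["orbital_offset"] + atoms["orbital_count"]).max())
    sigma_l = np.zeros(n_orb, dtype=complex)
    sigma_r = np.zeros(n_orb, dtype=complex)
    sigma_b = np.zeros(n_orb, dtype=complex)
    gamma_l = np.zeros(n_orb)
    gamma_r = np.zeros(n_orb)
    probe_ids: list = []
    probe_gammas: list = []
    for row in atoms.itertuples(index=False):
        aid = int(row.atom_id)
        sl = slice(int(row.orbital_offset), int(row.orbital_offset) + int(row.orbital_count))
        if aid in spec.left_atoms:
            sigma_l[sl] = -0.5j * spec.gamma_contact
            gamma_l[sl] = spec.gamma_contact
        elif aid in spec.right_atoms:
            sigma_r[sl] = -0.5j * spec.gamma_contact
            gamma_r[sl] = spec.gamma_contact
        else:
            sigma_b[sl] = -0.5j * spec.gamma_probe
            g = np.zeros(n_orb)
            g[sl] = spec.gamma_probe
            probe_ids.append(aid)
            probe_gammas.append(g)
    return SelfEnergySet(
        sigma_left=sigma_l,
        sigma_right=sigma_r,
        sigma_probes=sigma_b,
        gamma_left=gamma_l,
        gamma_right=gamma_r,
        probe_atom_ids=probe_ids,
        probe_gammas=probe_gammas,
    )


def retarded_green(
    energy: float,
    hamiltonian: np.ndarray,
    sigma_total: np.ndarray,
    eta: float = ETA_DEFAULT,
) -> np.ndarray:
    """Retarded Green's function ``G^r = [(E + i*eta) I - H - Sigma]^{-1}``.

    ``sigma_total`` may be a diagonal vector or a full matrix.  The advanced
    function is the conjugate transpose of the result.  ``eta`` is a safety
    floor only; set it to zero when the self-energies already broaden every
    level.
    """
    h = np.asarray(hamiltonian)
    n = h.shape[0]
    if eta < 0:
        raise ValueError("eta must be >= 0")
    a = -h.astype(complex)
    sigma_total = np.asarray(sigma_total)
    if sigma_total.ndim == 1:
        a[np.diag_indices(n)] += (energy + 1j * eta) - sigma_total
    else:
        a -= sigma_total
        a[np.diag_indices(n)] += energy + 1j * eta
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:
        raise NearSingularityError(
            f"(E+i*eta)I - H - Sigma singular at E={energy:.6f} eV; "
            "use a nonzero eta or nonzero broadenings"
        ) from exc


def _diagonals(broadenings: Sequence[np.ndarray]) -> np.ndarray:
    diags = []
    for g in broadenings:
        g = np.asarray(g, dtype=float)
        if g.ndim == 2:
            if np.any(g - np.diag(np.diag(g))):
                raise NotSupportedError(
                    "non-diagonal broadening matrices are not supported "
                    "(couplings are per-orbital)"
                )
            g = np.diag(g).copy()
        if np.any(g < 0):
            raise ValueError("broadenings must be nonnegative")
        diags.append(g)
    return np.vstack(diags)


@dataclass
class TransmissionSet:
    """All pairwise terminal transmissions at a single energy.

    ``labels`` orders the terminals ``["L", "R", probe...]``; ``matrix`` is
    the symmetric ``T_ij = Tr(Gamma_i G^r Gamma_j G^a)``; ``reflections``
    holds ``R_ii = 1 - sum_{j != i} T_ij`` (flux conservation); ``w`` is the
    Büttiker matrix over probes, ``W_ij = (1 - R_ii) d_ij - T_ij (1 - d_ij)``.
    ``mu_probes`` is filled by :func:`probe_potentials`.
    """

    energy: float
    labels: list
    matrix: np.ndarray
    reflections: np.ndarray
    w: np.ndarray
    mu_probes: np.ndarray | None = None

    @property
    def n_probes(self) -> int:
        return len(self.labels) - 2

    @property
    def t_lr(self) -> float:
        return float(self.matrix[0, 1])


def pairwise_transmission(
    green: np.ndarray,
    broadenings: Sequence[np.ndarray],
    energy: float = np.nan,
) -> TransmissionSet:
    """Pairwise transmissions between all terminals from one Green's function.

    ``broadenings`` are diagonal broadening matrices (or their diagonals)
    ordered ``[Gamma_L, Gamma_R, Gamma_probe_1, ...]``.  For diagonal
    couplings the trace formula reduces to
    ``T_ij = sum_{a in i, b in j} gamma_a |G^r_ab|^2 gamma_b``, which is how
    it is evaluated here.
    """
    diags = _diagonals(broadenings)
    absg2 = np.abs(green) ** 2
    t = diags @ absg2 @ diags.T
    t = 0.5 * (t + t.T)  # exact for real-symmetric H; harmless otherwise
    labels = ["L", "R"] + [f"probe_{k}" for k in range(diags.shape[0] - 2)]
    return _assemble_transmission_set(energy, labels, t)


def _assemble_transmission_set(energy, labels, t) -> TransmissionSet:
    nt = t.shape[0]
    offdiag_sums = t.sum(axis=1) - np.diag(t)
    reflections = 1.0 - offdiag_sums
    probes = slice(2, nt)
    tp = t[probes, probes]
    w = -tp.copy()
    np.fill_diagonal(w, offdiag_sums[probes])
    return TransmissionSet(
        energy=float(energy), labels=list(labels), matrix=t,
        reflections=reflections, w=w,
    )


def _split_probes(ts: TransmissionSet):
    """Indices of coupled vs decoupled probes within the probe block."""
    diag = np.diag(ts.w)
    coupled = np.flatnonzero(diag > DECOUPLED_TOL)
    decoupled = np.flatnonzero(diag <= DECOUPLED_TOL)
    return coupled, decoupled


def probe_potentials(
    ts: TransmissionSet, mu_left: float, mu_right: float
) -> np.ndarray:
    """Probe chemical potentials from the zero-net-current condition.

    Solves ``W x = b`` with ``b_i = T_iL mu_L + T_iR mu_R``; after the solve
    the net linear-response current into every probe vanishes.  Probes with
    no coupling at all (e.g. ``gamma_probe = 0``) carry no current at any
    potential and are assigned the mean contact potential.
    """
    nb = ts.n_probes
    mu = np.full(nb, 0.5 * (mu_left + mu_right))
    if nb == 0:
        ts.mu_probes = mu
        return mu
    coupled, _ = _split_probes(ts)
    if coupled.size:
        w = ts.w[np.ix_(coupled, coupled)]
        cond = np.linalg.cond(w)
        if not np.isfinite(cond) or cond > W_COND_MAX:
            raise IllConditionedError(ts.energy, cond)
        b = ts.matrix[2 + coupled, 0] * mu_left + ts.matrix[2 + coupled, 1] * mu_right
        mu[coupled] = np.linalg.solve(w, b)
    ts.mu_probes = mu
    return mu


def terminal_currents(
    ts: TransmissionSet, mu_left: float, mu_right: float,
    mu_probes: np.ndarray | None = None,
) -> np.ndarray:
    """Net linear-response current out of each terminal, in units of
    ``(2e/h) * energy`` — i.e. ``I_i = sum_j T_ij (mu_i - mu_j)``.

    After :func:`probe_potentials`, probe entries are ~0 and the total sums
    to zero (current conservation).
    """
    if mu_probes is None:
        mu_probes = ts.mu_probes
    if mu_probes is None:
        raise ConfigurationError("probe potentials not computed yet")
    mu = np.concatenate([[mu_left, mu_right], mu_probes])
    t = ts.matrix.copy()
    np.fill_diagonal(t, 0.0)
    return t.sum(axis=1) * mu - t @ mu


def effective_transmission(ts: TransmissionSet) -> float:
    """Effective transmission ``T_eff = T_LR + sum_ij T_Li (W^-1)_ij T_jR``.

    The probe correction is nonnegative (W is an M-matrix with nonnegative
    inverse), so decoherence never pushes the conductance below the coherent
    two-terminal value.
    """
    if ts.n_probes == 0:
        return ts.t_lr
    coupled, _ = _split_probes(ts)
    if coupled.size == 0:
        return ts.t_lr
    w = ts.w[np.ix_(coupled, coupled)]
    cond = np.linalg.cond(w)
    if not np.isfinite(cond) or cond > W_COND_MAX:
        raise IllConditionedError(ts.energy, cond)
    t_l = ts.matrix[0, 2 + coupled]
    t_r = ts.matrix[2 + coupled, 1]
    correction = float(t_l @ np.linalg.solve(w, t_r))
    return ts.t_lr + correction


def effective_transmission_via_current(
    ts: TransmissionSet, mu_left: float, mu_right: float
) -> float:
    """Cross-check route: current at the left contact over the bias window.

    ``I_L / (mu_L - mu_R)`` with probe potentials from the zero-current
    condition equals :func:`effective_transmission` for reciprocal systems.
    """
    mu = probe_potentials(ts, mu_left, mu_right)
    i_left = terminal_currents(ts, mu_left, mu_right, mu)[0]
    return float(i_left / (mu_left - mu_right))


@dataclass
class TransportResult:
    """Energy-resolved transport output.

    ``t_direct`` is the coherent left-right transmission ``T_LR``;
    ``t_eff`` the probe-corrected effective transmission; ``conductance``
    is ``G0 * T_eff`` interpolated at ``fermi_energy`` (siemens).  Energies
    where the probe system was too ill-conditioned to solve are recorded in
    ``flagged_energies`` and carry NaN.
    """

    energies: np.ndarray
    t_direct: np.ndarray
    t_eff: np.ndarray
    mu_probes: np.ndarray
    probe_atom_ids: list
    fermi_energy: float
    conductance: float
    contact: ContactSpec
    flagged_energies: list = field(default_factory=list)

    def t_eff_at(self, energy: float) -> float:
        lo, hi = self.energies[0], self.energies[-1]
        if not (lo <= energy <= hi):
            raise InterpolationRangeError(
                f"energy {energy:.6f} eV outside computed grid [{lo:.6f}, {hi:.6f}]"
            )
        return float(np.interp(energy, self.energies, self.t_eff))

    def conductance_at(self, energy: float) -> float:
        return G0 * self.t_eff_at(energy)

    def aligned_energies(self, homo: float) -> np.ndarray:
        return self.energies - homo

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "energy_eV": self.energies,
            "t_direct": self.t_direct,
            "t_eff": self.t_eff,
        })
        df["conductance_S"] = np.nan
        if len(self.energies):
            idx = int(np.argmin(np.abs(self.energies - self.fermi_energy)))
            df.loc[idx, "conductance_S"] = self.conductance
        return df


def default_energy_grid(
    block: AtomBlockHamiltonian, npoints: int = 400,
    below_homo: float = 3.0, above_lumo: float = 1.0,
) -> np.ndarray:
    """Default grid: HOMO - 3 eV to LUMO + 1 eV, 400 points."""
    if block.n_occupied is None:
        raise ConfigurationError("n_occupied required to build the default grid")
    levels = block.eigenvalues()
    homo = levels[block.n_occupied - 1]
    lumo = levels[block.n_occupied]
    return np.linspace(homo - below_homo, lumo + above_lumo, npoints)


def transmission_spectrum(
    block: AtomBlockHamiltonian,
    spec: ContactSpec,
    grid: np.ndarray | None = None,
    fermi: float | None = None,
    fermi_offset: float = 0.0,
    eta: float = ETA_DEFAULT,
    npoints: int = 400,
) -> TransportResult:
    """Run the full per-energy transport pipeline over an energy grid.

    ``fermi`` defaults to the HOMO energy plus ``fermi_offset`` (the paper's
    zero-bias working point); the conductance is ``G0 * T_eff(fermi)``.
    """
    se = build_self_energies(spec, block.atoms)
    if grid is None:
        grid = default_energy_grid(block, npoints=npoints)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("energy grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("energy grid must be sorted ascending")
    if fermi is None:
        if block.n_occupied is None:
            raise ConfigurationError("n_occupied required for the default Fermi energy")
        fermi = float(block.eigenvalues()[block.n_occupied - 1]) + fermi_offset

    gammas = se.terminal_gammas()
    sigma = se.sigma_total
    t_direct = np.empty_like(grid)
    t_eff = np.empty_like(grid)
    mu_probes = np.empty((grid.size, se.n_probes))
    flagged: list = []
    for k, energy in enumerate(grid):
        g = retarded_green(energy, block.matrix, sigma, eta=eta)
        ts = pairwise_transmission(g, gammas, energy=energy)
        t_direct[k] = ts.t_lr
        try:
            mu_probes[k] = probe_potentials(ts, spec.mu_left, spec.mu_right)
            t_eff[k] = effective_transmission(ts)
        except IllConditionedError:
            flagged.append(float(energy))
            mu_probes[k] = np.nan
            t_eff[k] = np.nan

    lo, hi = grid[0], grid[-1]
    if not (lo <= fermi <= hi):
        raise InterpolationRangeError(
            f"fermi energy {fermi:.6f} eV outside grid [{lo:.6f}, {hi:.6f}]"
        )
    conductance = G0 * float(np.interp(fermi, grid, t_eff))
    return TransportResult(
        energies=grid, t_direct=t_direct, t_eff=t_eff, mu_probes=mu_probes,
        probe_atom_ids=list(se.probe_atom_ids), fermi_energy=float(fermi),
        conductance=conductance, contact=spec, flagged_energies=flagged,
    )
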