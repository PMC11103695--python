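"""Electrode contact schemes and conductance comparisons.

Electrodes are assumed to touch only terminal base pairs.  For a two-helix
origami there are five placements — ``helix_1_to_1``, ``helix_2_to_2``,
``helix_1_to_2``, ``helix_2_to_1`` and ``both`` (both helices' terminals
share one electrode per side) — and a duplex has the single
``ds_end_to_end`` placement.  Conductances are evaluated at the HOMO plus a
few configurable offsets, HOMO-aligned so different systems compare at the
same relative energy, and reported as ratios against a reference scheme
(the companion duplex when one is supplied).

The crossover-barrier report quantifies why cross-helix schemes conduct
poorly: the crossover backbone carries almost no density of states near the
HOMO, so carriers crossing helices must tunnel through an energy barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .basis import AtomBlockHamiltonian, to_atom_blocks
from .dos import aggregate_dos, per_atom_dos
from .errors import CatalogError, ConfigurationError
from .system import ElectronicSystem
from .transport import G0, ContactSpec, transmission_spectrum

ORIGAMI_SCHEMES = ("helix_1_to_1", "helix_2_to_2", "helix_1_to_2", "helix_2_to_1", "both")


@dataclass
class SchemeCatalog:
    """Named (left, right) contact atom sets for one system."""

    schemes: dict
    helices: list

    def names(self) -> list:
        return list(self.schemes)

    def __contains__(self, name: str) -> bool:
        return name in self.schemes

    def sides(self, name: str) -> tuple:
        if name not in self.schemes:
            raise CatalogError(f"unknown scheme {name!r}; have {self.names()}")
        return self.schemes[name]

    def contact_spec(self, name: str, **kwargs) -> ContactSpec:
        left, right = self.sides(name)
        return ContactSpec(left_atoms=left, right_atoms=right, **kwargs)


def _helix_ends(atoms: pd.DataFrame, helix: int, base_pair: bool) -> tuple:
    term = atoms[(atoms["helix_id"] == helix) & (atoms["region"] == "terminal")]
    if term.empty:
        return None
    lo, hi = int(term["pos"].min()), int(term["pos"].max())
    if lo == hi:
        return None
    left = term[term["pos"] == lo]["atom_id"]
    right = term[term["pos"] == hi]["atom_id"]
    if not base_pair:  # contact a single base per side: deterministic pick
        left, right = left.iloc[:1], right.iloc[:1]
    return frozenset(int(a) for a in left), frozenset(int(a) for a in right)


def enumerate_schemes(system: ElectronicSystem, base_pair: bool = True) -> SchemeCatalog:
    """Derive the contact-scheme catalog from terminal-base annotations.

    ``base_pair=True`` contacts every atom of the terminal base pair on each
    side (the default); ``False`` restricts each side to a single terminal
    base.
    """
    atoms = system.atoms
    helices = sorted(int(h) for h in atoms["helix_id"].unique())
    ends = {}
    missing = []
    for h in helices:
        e = _helix_ends(atoms, h, base_pair)
        if e is None:
            missing.append(h)
        else:
            ends[h] = e
    if missing:
        raise CatalogError(
            f"helices {missing} lack terminal-base annotations on both ends"
        )
    if len(helices) == 1:
        h = helices[0]
        return SchemeCatalog(schemes={"ds_end_to_end": ends[h]}, helices=helices)
    if len(helices) != 2:
        raise CatalogError(
            f"contact schemes are defined for 1 or 2 helices, found {len(helices)}"
        )
    h1, h2 = helices
    schemes = {
        "helix_1_to_1": (ends[h1][0], ends[h1][1]),
        "helix_2_to_2": (ends[h2][0], ends[h2][1]),
        "helix_1_to_2": (ends[h1][0], ends[h2][1]),
        "helix_2_to_1": (ends[h2][0], ends[h1][1]),
        "both": (ends[h1][0] | ends[h2][0], ends[h1][1] | ends[h2][1]),
    }
    return SchemeCatalog(schemes=schemes, helices=helices)


@dataclass
class TransportConfig:
    """Shared sweep settings: couplings (eV) and the energy grid around the HOMO."""

    gamma_contact: float = 0.600
    gamma_probe: float = 0.010
    grid_below: float = 1.0
    grid_above: float = 1.0
    npoints: int = 200
    eta: float = 1e-6

    def grid(self, homo: float, max_offset: float) -> np.ndarray:
        return np.linspace(homo - self.grid_below, homo + max_offset + self.grid_above,
                           self.npoints)


@dataclass
class ComparisonTable:
    """Scheme-by-offset conductances with ratios against a reference scheme."""

    frame: pd.DataFrame
    reference: str
    metadata: dict = field(default_factory=dict)


def _homo_of(block: AtomBlockHamiltonian) -> float:
    if block.n_occupied is None:
        raise ConfigurationError("n_occupied required to locate the HOMO")
    return float(block.eigenvalues()[block.n_occupied - 1])


def conductance_sweep(
    system: ElectronicSystem,
    catalog: SchemeCatalog | None = None,
    fermi_offsets: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    config: TransportConfig | None = None,
    reference: ElectronicSystem | None = None,
    reference_scheme: str | None = None,
) -> ComparisonTable:
    """Conductance of every scheme at E_F = HOMO + offset, HOMO-aligned.

    When a companion ``reference`` system (typically the dsDNA counterpart)
    is supplied, its ``ds_end_to_end`` conductance at each offset is the
    ratio denominator and its rows are included in the table; otherwise the
    reference defaults to ``ds_end_to_end`` if present, else ``helix_1_to_1``.
    """
    config = config or TransportConfig()
    fermi_offsets = [float(o) for o in fermi_offsets]
    if not all(np.isfinite(fermi_offsets)):
        raise ConfigurationError("fermi offsets must be finite")
    catalog = catalog or enumerate_schemes(system)

    def run_system(sys_: ElectronicSystem, cat: SchemeCatalog) -> dict:
        block = to_atom_blocks(sys_)
        homo = _homo_of(block)
        grid = config.grid(homo, max(fermi_offsets))
        out = {}
        for name in cat.names():
            spec = cat.contact_spec(name, gamma_contact=config.gamma_contact,
                                    gamma_probe=config.gamma_probe)
            res = transmission_spectrum(block, spec, grid=grid, fermi=homo,
                                        eta=config.eta)
            out[name] = (homo, res)
        return out

    results = run_system(system, catalog)
    rows = []
    for name, (homo, res) in results.items():
        for off in fermi_offsets:
            t_eff = res.t_eff_at(homo + off)
            rows.append({"scheme": name, "fermi_offset_eV": off,
                         "t_eff": t_eff, "conductance_S": G0 * t_eff})

    if reference is not None:
        ref_catalog = enumerate_schemes(reference)
        if "ds_end_to_end" not in ref_catalog:
            raise ConfigurationError(
                "reference system has no ds_end_to_end scheme (is it a duplex?)"
            )
        ref_results = run_system(reference, SchemeCatalog(
            schemes={"ds_end_to_end": ref_catalog.sides("ds_end_to_end")},
            helices=ref_catalog.helices))
        homo_r, res_r = ref_results["ds_end_to_end"]
        for off in fermi_offsets:
            t_eff = res_r.t_eff_at(homo_r + off)
            rows.append({"scheme": "ds_end_to_end", "fermi_offset_eV": off,
                         "t_eff": t_eff, "conductance_S": G0 * t_eff})
        ref_name = "ds_end_to_end"
    else:
        if reference_scheme is None:
            ref_name = "ds_end_to_end" if "ds_end_to_end" in catalog else "helix_1_to_1"
        else:
            ref_name = reference_scheme
        if not any(r["scheme"] == ref_name for r in rows):
            raise ConfigurationError(f"reference scheme {ref_name!r} not in the catalog")

    frame = pd.DataFrame(rows)
    ref_vals = {
        off: frame.loc[(frame["scheme"] == ref_name)
                       & (frame["fermi_offset_eV"] == off), "conductance_S"].iloc[0]
        for off in fermi_offsets
    }
    frame["ratio_to_reference"] = [
        row["conductance_S"] / ref_vals[row["fermi_offset_eV"]]
        for _, row in frame.iterrows()
    ]
    return ComparisonTable(
        frame=frame.reset_index(drop=True), reference=ref_name,
        metadata={
            "gamma_contact": config.gamma_contact,
            "gamma_probe": config.gamma_probe,
            "fermi_offsets": fermi_offsets,
            "reference": ref_name,
        },
    )


@dataclass
class CrossoverReport:
    """Crossover-as-barrier summary.

    ``dos_fraction``: share of the total DOS integrated over
    [HOMO − window, HOMO] that sits on crossover-region atoms.
    ``conductance_ratio``: cross-helix over same-helix conductance at the
    HOMO.  ``barrier_like`` is True when the crossover carries < 5% of the
    near-HOMO DOS and suppresses cross-helix conductance.
    """

    empty: bool
    dos_fraction: float | None = None
    conductance_ratio: float | None = None
    barrier_like: bool | None = None
    window: float = 0.3

    def to_frame(self) -> pd.DataFrame:
        if self.empty:
            return pd.DataFrame(columns=["quantity", "value"])
        return pd.DataFrame({
            "quantity": ["crossover_dos_fraction", "cross_to_same_conductance_ratio",
                         "barrier_like"],
            "value": [self.dos_fraction, self.conductance_ratio,
                      float(self.barrier_like)],
        })


def crossover_barrier_report(
    system: ElectronicSystem,
    config: TransportConfig | None = None,
    window: float = 0.3,
    dos_points: int = 61,
) -> CrossoverReport:
    """Quantify the crossover backbone as a transport barrier.

    Reports (a) the fraction of DOS on crossover atoms within
    [HOMO − window, HOMO], and (b) the helix_1_to_2 / helix_1_to_1
    conductance ratio at E_F = HOMO.  Systems without crossover atoms (plain
    duplexes) produce an empty report with a warning.
    """
    config = config or TransportConfig()
    if not (system.atoms["region"] == "crossover").any():
        warnings.warn("system has no crossover-region atoms; report is empty")
        return CrossoverReport(empty=True, window=window)
    catalog = enumerate_schemes(system)
    block = to_atom_blocks(system)
    homo = _homo_of(block)

    spec = catalog.contact_spec("helix_1_to_1", gamma_contact=config.gamma_contact,
                                gamma_probe=config.gamma_probe)
    grid = np.linspace(homo - window, homo, dos_points)
    field_ = per_atom_dos(block, spec, grid, eta=config.eta)
    by_region = aggregate_dos(field_, "region")
    totals = by_region.integrate()
    fraction = float(totals[by_region.labels.index("crossover")] / totals.sum())

    small = np.linspace(homo - 0.05, homo + 0.05, 5)
    cond = {}
    for name in ("helix_1_to_1", "helix_1_to_2"):
        sp = catalog.contact_spec(name, gamma_contact=config.gamma_contact,
                                  gamma_probe=config.gamma_probe)
        res = transmission_spectrum(block, sp, grid=small, fermi=homo, eta=config.eta)
        cond[name] = res.conductance
    ratio = cond["helix_1_to_2"] / cond["helix_1_to_1"]
    return CrossoverReport(
        empty=False, dos_fraction=fraction, conductance_ratio=float(ratio),
        barrier_like=bool(fraction < 0.05 and ratio < 1.0), window=window,
    )
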