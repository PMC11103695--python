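"""Synthetic tight-binding DNA systems.

Real inputs to this pipeline are Fock/overlap matrices from quantum
chemistry.  This module generates annotated stand-ins with the same
*structure*: ladder lattices with one π site per base (sequence-dependent
energy, guanine ~0.5 eV above cytosine), one phosphate-backbone site per
internal phosphodiester linkage (14 for an 8-bp duplex, 28 for the
four-strand origami), intrastrand stacking, interstrand pairing,
base–backbone and backbone–backbone couplings, a uniform off-diagonal
overlap on coupled pairs, and — for origami — a single crossover where the
two crossing strands' backbones reroute between the helices.

Two origami conformations are modeled: C1 keeps the helices electronically
connected only through the crossover backbone, while C2 adds a direct
base–base coupling ``t_x`` between the designated terminal bases of the two
helices (terminal bases coming into proximity).

Each base site carries two orbitals by default — an occupied π level at the
site energy and a virtual π* level ``virtual_offset`` above it — so that
every site contributes exactly one doubly occupied level while the system
still has a HOMO–LUMO gap.  Backbone sites carry one (occupied) orbital.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SequenceError, TopologyError
from .system import ElectronicSystem

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

STRAND_NAMES = ("I", "II", "III", "IV")


def complement(sequence: str) -> str:
    """Position-wise complement (pairing partner at each ladder position)."""
    try:
        return "".join(COMPLEMENT[b] for b in sequence)
    except KeyError as exc:
        raise SequenceError(f"invalid base {exc.args[0]!r}; expected A/C/G/T") from exc


@dataclass(frozen=True)
class ModelParams:
    """Tight-binding model parameters (energies in eV).

    Site energies satisfy ``eps_G > eps_A > eps_C > eps_T`` with
    ``eps_G - eps_C = 0.5``; absolute values are arbitrary.  The backbone
    sits 2 eV below guanine, far from the HOMO region.  Couplings are kept
    well below the site-energy spacings so base-character labels stay
    meaningful.  ``t_x`` is the inter-helix base coupling used only by the
    C2 origami conformation.  ``s`` is the uniform off-diagonal overlap on
    every coupled orbital pair; ``noise_sd`` adds a Gaussian rigid shift per
    site, drawn from ``seed``.
    """

    eps_G: float = -7.8
    eps_A: float = -8.1
    eps_C: float = -8.3
    eps_T: float = -8.4
    eps_backbone: float = -9.8
    virtual_offset: float = 4.0
    virtual_spacing: float = 2.0
    base_orbital_count: int = 2
    backbone_orbital_count: int = 1
    t_stack: float = -0.10
    t_pair: float = -0.05
    t_bb: float = -0.08
    t_chain: float = -0.12
    t_x: float = -0.06
    s: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= abs(self.s) < 0.5):
            raise ParameterError(f"|s|={abs(self.s)} must be < 0.5 to keep the overlap SPD")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.base_orbital_count < 1 or self.backbone_orbital_count < 1:
            raise ParameterError("orbital counts must be >= 1")
        energies = sorted({self.eps_G, self.eps_A, self.eps_C, self.eps_T, self.eps_backbone})
        spacings = np.diff(energies)
        min_spacing = float(spacings.min()) if len(spacings) else np.inf
        tmax = max(abs(t) for t in (self.t_stack, self.t_pair, self.t_bb,
                                    self.t_chain, self.t_x))
        if tmax >= 10.0 * min_spacing:
            raise ParameterError(
                f"coupling magnitude {tmax} exceeds 10x the minimum site-energy "
                f"spacing {min_spacing}; the perturbative site picture breaks down"
            )

    def site_energy(self, label: str) -> float:
        table = {"G": self.eps_G, "A": self.eps_A, "C": self.eps_C,
                 "T": self.eps_T, "backbone": self.eps_backbone}
        if label not in table:
            raise SequenceError(f"invalid base {label!r}; expected A/C/G/T")
        return table[label]

    def orbital_energies(self, label: str) -> np.ndarray:
        """Orbital ladder of one site: occupied level, then virtual levels."""
        eps = self.site_energy(label)
        count = self.backbone_orbital_count if label == "backbone" else self.base_orbital_count
        out = [eps]
        for k in range(1, count):
            out.append(eps + self.virtual_offset + (k - 1) * self.virtual_spacing)
        return np.array(out)


#: Preset exercising the block machinery with 3 orbitals per base site.
RICH_PARAMS = ModelParams(base_orbital_count=3)


@dataclass(frozen=True)
class TopologySpec:
    """Strand/topology layout of a synthetic system.

    ``duplex`` mode takes one strand (partner derived by complementarity).
    ``origami`` mode takes the two helix sequences (the two crossing
    staple-like strands are derived), or an explicit four-strand layout
    ``(I, II, III, IV)`` with the crossing strands written in
    helix-position order; ``crossover`` is the base index where the
    crossing strands' backbones reroute between helices.
    """

    mode: str
    sequences: tuple
    crossover: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequences",
                           tuple(str(s).upper() for s in self.sequences))
        for s in self.sequences:
            if any(b not in COMPLEMENT for b in s):
                raise SequenceError(f"invalid characters in sequence {s!r}")
        if self.mode == "duplex":
            if len(self.sequences) != 1:
                raise TopologyError("duplex mode takes exactly one strand sequence")
            if len(self.sequences[0]) < 2:
                raise SequenceError("duplex sequence must have length >= 2")
        elif self.mode == "origami":
            if len(self.sequences) not in (2, 4):
                raise TopologyError(
                    "origami mode takes two helix sequences or an explicit "
                    "four-strand layout"
                )
            lengths = {len(s) for s in self.sequences}
            if len(lengths) != 1:
                raise TopologyError("all origami strands must have equal length")
            length = lengths.pop()
            if length < 4:
                raise TopologyError("origami helices need at least 4 base pairs")
            c = self.crossover if self.crossover is not None else length // 2
            if not 2 <= c <= length - 2:
                raise TopologyError(
                    f"crossover at base index {c} touches a terminal base pair; "
                    f"it must lie in [2, {length - 2}]"
                )
            object.__setattr__(self, "crossover", int(c))
            if len(self.sequences) == 4:
                h1, s2, h2, s4 = self.sequences
                want2 = complement(h1[:c]) + complement(h2[c:])
                want4 = complement(h2[:c]) + complement(h1[c:])
                if (s2, s4) != (want2, want4):
                    raise TopologyError(
                        "explicit crossing strands are not complementary to the "
                        f"helix sequences: expected II={want2!r}, IV={want4!r}"
                    )
        else:
            raise TopologyError(f"unknown mode {self.mode!r}")

    @classmethod
    def duplex(cls, sequence: str) -> "TopologySpec":
        return cls(mode="duplex", sequences=(sequence,))

    @classmethod
    def origami(cls, helix1: str, helix2: str, crossover: int | None = None) -> "TopologySpec":
        return cls(mode="origami", sequences=(helix1, helix2), crossover=crossover)

    @property
    def helix_sequences(self) -> tuple:
        if self.mode == "duplex":
            return (self.sequences[0],)
        return (self.sequences[0], self.sequences[2 if len(self.sequences) == 4 else 1])


@dataclass
class _Site:
    key: tuple  # unique hashable site key
    label: str  # A/C/G/T/backbone
    element: str
    strand_id: str
    helix_id: int
    region: str
    pos: int


def _assemble(
    sites: Sequence[_Site],
    edges: Sequence[tuple],
    params: ModelParams,
    metadata: dict,
) -> ElectronicSystem:
    """Expand a site graph into an annotated Hamiltonian/overlap pair.

    ``edges`` are ``(key_a, key_b, t)``; orbital channel k of one site
    couples to channel k of the other (shared channels only), with overlap
    ``params.s`` wherever the Hamiltonian couples.
    """
    index = {s.key: i for i, s in enumerate(sites)}
    counts = [len(params.orbital_energies(s.label)) for s in sites]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n_orb = int(offsets[-1])

    rng = np.random.default_rng(params.seed)
    shifts = (rng.normal(0.0, params.noise_sd, size=len(sites))
              if params.noise_sd > 0 else np.zeros(len(sites)))

    h = np.zeros((n_orb, n_orb))
    s_mat = np.eye(n_orb)
    for i, site in enumerate(sites):
        levels = params.orbital_energies(site.label) + shifts[i]
        sl = slice(int(offsets[i]), int(offsets[i + 1]))
        h[sl, sl] = np.diag(levels)
    for key_a, key_b, t in edges:
        if t == 0.0:
            continue
        a, b = index[key_a], index[key_b]
        for k in range(min(counts[a], counts[b])):
            ia, ib = int(offsets[a]) + k, int(offsets[b]) + k
            h[ia, ib] = h[ib, ia] = t
            s_mat[ia, ib] = s_mat[ib, ia] = params.s

    min_eig = float(np.linalg.eigvalsh(s_mat)[0])
    if min_eig <= 0:
        raise ParameterError(
            f"overlap not positive definite (min eigenvalue {min_eig:.3e}); "
            f"reduce |s|={abs(params.s)}"
        )

    atoms = pd.DataFrame({
        "atom_id": np.arange(len(sites), dtype=np.int64),
        "element": [s.element for s in sites],
        "orbital_offset": offsets[:-1].astype(np.int64),
        "orbital_count": np.asarray(counts, dtype=np.int64),
        "base_id": np.arange(len(sites), dtype=np.int64),
        "base_label": [s.label for s in sites],
        "strand_id": [s.strand_id for s in sites],
        "helix_id": [s.helix_id for s in sites],
        "region": [s.region for s in sites],
        "pos": [s.pos for s in sites],
    })
    meta = dict(metadata)
    meta["params"] = asdict(params)
    return ElectronicSystem(
        hamiltonian=h, overlap=s_mat, atoms=atoms,
        n_occupied=len(sites), metadata=meta,
    )


def _base_region(pos: int, length: int) -> str:
    return "terminal" if pos in (0, length - 1) else "base"


def build_chain(sequence: str, params: ModelParams | None = None) -> ElectronicSystem:
    """Single-strand stacked chain (no pairing, no backbone).

    A minimal system whose π band is the textbook nearest-neighbor cosine
    band ``eps + 2 t_stack cos(k pi / (L+1))`` — used for parameter-recovery
    checks.
    """
    params = params or ModelParams()
    seq = sequence.upper()
    if len(seq) < 2:
        raise SequenceError("chain needs at least 2 bases")
    sites = [
        _Site(("b", "I", p), seq[p], "pi", "I", 1, _base_region(p, len(seq)), p)
        for p in range(len(seq))
    ]
    edges = [(("b", "I", p), ("b", "I", p + 1), params.t_stack)
             for p in range(len(seq) - 1)]
    return _assemble(sites, edges, params,
                     {"model": "chain", "sequence": seq})


def build_duplex(sequence: str, params: ModelParams | None = None) -> ElectronicSystem:
    """Double-stranded ladder with phosphate backbone sites.

    One π site per base on both strands (2L sites), one backbone site per
    internal phosphodiester linkage (2(L−1) sites; 14 for L=8).  Strand I
    carries ``sequence`` 5'→3'; strand II is its pairing partner.
    """
    params = params or ModelParams()
    spec = TopologySpec.duplex(sequence)
    seq = spec.sequences[0]
    length = len(seq)
    comp = complement(seq)

    sites: list[_Site] = []
    for strand, bases in (("I", seq), ("II", comp)):
        for p in range(length):
            sites.append(_Site(("b", strand, p), bases[p], "pi", strand, 1,
                               _base_region(p, length), p))
    for strand in ("I", "II"):
        for p in range(length - 1):
            sites.append(_Site(("p", strand, p), "backbone", "P", strand, 1,
                               "backbone", p))

    edges: list[tuple] = []
    for strand in ("I", "II"):
        for p in range(length - 1):
            edges.append((("b", strand, p), ("b", strand, p + 1), params.t_stack))
            edges.append((("p", strand, p), ("b", strand, p), params.t_bb))
            edges.append((("p", strand, p), ("b", strand, p + 1), params.t_bb))
        for p in range(length - 2):
            edges.append((("p", strand, p), ("p", strand, p + 1), params.t_chain))
    for p in range(length):
        edges.append((("b", "I", p), ("b", "II", p), params.t_pair))

    return _assemble(sites, edges, params,
                     {"model": "duplex", "sequence": seq})


def build_origami(
    spec: TopologySpec,
    params: ModelParams | None = None,
    conformation: str = "C1",
) -> ElectronicSystem:
    """Four-strand, two-helix, one-crossover origami ladder.

    Strand I runs the full length of helix 1 and strand III of helix 2; the
    crossing strands II and IV complete the complementary sides, each
    rerouting its backbone to the other helix at the crossover.  For the
    8-bp geometry this yields 32 base sites and 28 backbone sites.

    ``conformation="C1"`` keeps the helices coupled only through the
    crossover backbone (``t_x`` forced to 0); ``"C2"`` adds ``t_x`` between
    the terminal bases of the two helices at the far end (position L−1).
    """
    params = params or ModelParams()
    if spec.mode != "origami":
        raise TopologyError(f"expected an origami TopologySpec, got mode {spec.mode!r}")
    if conformation not in ("C1", "C2"):
        raise TopologyError(f"conformation must be 'C1' or 'C2', got {conformation!r}")
    h1, h2 = spec.helix_sequences
    length = len(h1)
    c = spec.crossover
    comp1, comp2 = complement(h1), complement(h2)

    def comp_strand(helix: int, p: int) -> str:
        # which crossing strand supplies the complementary base at (helix, p)
        if helix == 1:
            return "II" if p < c else "IV"
        return "IV" if p < c else "II"

    sites: list[_Site] = []
    for helix, primary, primary_seq, comp_seq in (
        (1, "I", h1, comp1), (2, "III", h2, comp2)
    ):
        for p in range(length):
            sites.append(_Site(("b", helix, "prim", p), primary_seq[p], "pi",
                               primary, helix, _base_region(p, length), p))
        for p in range(length):
            sites.append(_Site(("b", helix, "comp", p), comp_seq[p], "pi",
                               comp_strand(helix, p), helix,
                               _base_region(p, length), p))

    # Backbone chains, one per strand, in strand order.  ``chain`` lists the
    # base-site keys the strand threads through; site j links chain[j], chain[j+1].
    chains = {
        "I": [("b", 1, "prim", p) for p in range(length)],
        "III": [("b", 2, "prim", p) for p in range(length)],
        "II": [("b", 1, "comp", p) for p in range(c)]
              + [("b", 2, "comp", p) for p in range(c, length)],
        "IV": [("b", 2, "comp", p) for p in range(c)]
              + [("b", 1, "comp", p) for p in range(c, length)],
    }
    strand_helix_start = {"I": 1, "II": 1, "III": 2, "IV": 2}
    for strand in ("I", "II", "III", "IV"):
        for j in range(length - 1):
            if strand in ("I", "III"):
                helix = strand_helix_start[strand]
            else:
                helix = strand_helix_start[strand] if j < c else (
                    2 if strand_helix_start[strand] == 1 else 1)
            region = "crossover" if j == c - 1 else "backbone"
            sites.append(_Site(("p", strand, j), "backbone", "P", strand,
                               helix, region, j))

    edges: list[tuple] = []
    for helix in (1, 2):
        for side in ("prim", "comp"):
            for p in range(length - 1):
                edges.append((("b", helix, side, p), ("b", helix, side, p + 1),
                              params.t_stack))
        for p in range(length):
            edges.append((("b", helix, "prim", p), ("b", helix, "comp", p),
                          params.t_pair))
    for strand, chain in chains.items():
        for j in range(length - 1):
            edges.append((("p", strand, j), chain[j], params.t_bb))
            edges.append((("p", strand, j), chain[j + 1], params.t_bb))
        for j in range(length - 2):
            edges.append((("p", strand, j), ("p", strand, j + 1), params.t_chain))
    if conformation == "C2":
        edges.append((("b", 1, "prim", length - 1), ("b", 2, "prim", length - 1),
                      params.t_x))
        edges.append((("b", 1, "comp", length - 1), ("b", 2, "comp", length - 1),
                      params.t_x))

    return _assemble(sites, edges, params, {
        "model": "origami", "conformation": conformation,
        "helix1": h1, "helix2": h2, "crossover": c,
    })


def perturb(system: ElectronicSystem, noise_sd: float, seed: int) -> ElectronicSystem:
    """Rigid per-site Gaussian jitter of the site energies.

    All diagonal entries of an atom's orbitals shift together; topology,
    couplings, overlap and annotations are untouched.  A stand-in for
    conformational variability across structures.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    h = system.hamiltonian.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        shifts = rng.normal(0.0, noise_sd, size=system.n_atoms)
        for shift, (off, cnt) in zip(
            shifts, zip(system.atoms["orbital_offset"], system.atoms["orbital_count"])
        ):
            idx = np.arange(int(off), int(off) + int(cnt))
            h[idx, idx] += shift
    meta = dict(system.metadata)
    meta["perturb"] = {"noise_sd": noise_sd, "seed": int(seed)}
    return ElectronicSystem(
        hamiltonian=h, overlap=system.overlap.copy(),
        atoms=system.atoms.copy(), n_occupied=system.n_occupied, metadata=meta,
    )


PRESETS = {
    "paper-gc-dsdna": ("duplex", "GGGGCCCC"),
    "paper-at-dsdna": ("duplex", "AAAATTTT"),
    "paper-gc-origami": ("origami", "GGGGCCCC"),
    "paper-at-origami": ("origami", "AAAATTTT"),
}


def build_preset(
    name: str,
    conformation: str = "C1",
    seed: int = 0,
    noise_sd: float = 0.0,
    params: ModelParams | None = None,
) -> ElectronicSystem:
    """Build one of the four sequence/topology combinations as a synthetic analogue.

    ``paper-gc-*`` use the G4C4 sequence, ``paper-at-*`` the A4T4 sequence;
    origami presets bundle two identical helices with one central crossover.
    """
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    mode, seq = PRESETS[name]
    params = replace(params or ModelParams(), seed=int(seed), noise_sd=float(noise_sd))
    if mode == "duplex":
        return build_duplex(seq, params)
    return build_origami(TopologySpec.origami(seq, seq), params, conformation=conformation)
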