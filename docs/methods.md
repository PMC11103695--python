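# Methods

## The model

`dqt` analyzes hole transport through DNA duplexes and two-helix DNA
origami at the level of an effective one-electron Hamiltonian. The input is
a Fock matrix `H0` and overlap matrix `S0` (eV, real symmetric) in a
non-orthogonal basis, annotated so that every orbital belongs to an atom,
every atom to a base (or a backbone phosphate), a strand, a helix and a
region tag (`base`, `backbone`, `crossover`, `terminal`). Three stages sit
on top of this input.

**Basis transformations.** The Löwdin symmetric orthogonalization
`H_orth = S0^(-1/2) H0 S0^(-1/2)` removes the overlap while preserving the
generalized spectrum of `(H0, S0)`. `S0^(-1/2)` is computed by
eigendecomposition of `S0` with a positive-definiteness check (smallest
eigenvalue must exceed `1e-8`); this route is numerically transparent and
directly testable against an independent generalized eigensolver.
`H_orth` is then partitioned into atomic blocks and each within-atom block
is diagonalized, so that diagonal elements become atomic molecular-orbital
energies and off-diagonal blocks become inter-atomic hopping matrices.
Within an atom, eigenvectors are ordered by ascending eigenvalue, signs are
fixed by making the largest-magnitude component positive, and exact
degeneracies keep the eigensolver's (deterministic) order — so block
transforms, and therefore hopping parameters, are bit-reproducible.

**Büttiker-probe transport.** The molecule is opened with diagonal
self-energies: `-i·Γ_L/2` (`-i·Γ_R/2`) on every orbital of the atoms
touching the left (right) electrode, and `-i·Γ_B/2` on every orbital of
each remaining atom, one fictitious voltage probe per atom. With this
convention the broadening matrix `Γ_i = i(Σ_i − Σ_i†)` equals the stated
coupling, so `Γ` values are directly Breit–Wigner level widths. Defaults
follow the molecular-junction regime: `Γ_L = Γ_R = 600 meV`,
`Γ_B = 10 meV`, temperature 300 K recorded but unused in the zero-bias
linearization. At each energy:

1. `G^r(E) = [(E + iη) I − H − Σ]^(-1)` with safety floor `η = 1e-6 eV`
   (physical broadening comes from `Σ`; `η` only guards the all-`Γ`-zero
   corner).
2. `T_ij = Tr(Γ_i G^r Γ_j G^a)`, which for diagonal couplings reduces to
   `Σ_{α∈i,β∈j} γ_α |G^r_αβ|² γ_β` — the form evaluated here.
3. Reflections close the flux balance: `R_ii = 1 − Σ_{j≠i} T_ij`, making
   `W_ij = (1 − R_ii)δ_ij − T_ij(1 − δ_ij)` the standard Büttiker matrix —
   weakly diagonally dominant with nonpositive off-diagonals (an M-matrix,
   hence `W^(-1) ≥ 0`).
4. Probe potentials solve `W μ = b`, `b_i = T_iL μ_L + T_iR μ_R`, which is
   exactly the zero-net-current condition at every probe. Probes with no
   coupling at all are excluded from the solve and pinned to the mean
   contact potential; if the reduced `W` has condition number above `1e12`
   (a probe effectively severed from both contacts) the energy point is
   flagged and reported as NaN rather than silently regularized.
5. `T_eff = T_LR + Σ_ij T_Li (W^(-1))_ij T_jR`. Because `W^(-1) ≥ 0` the
   probe correction is nonnegative: decoherence never pushes the
   two-terminal transmission below its coherent value. The identical number
   obtained from the current at the left contact divided by the bias window
   is kept as a cross-check routine.

The zero-bias conductance is `G = G0 · T_eff(E_F)` with `G0 = 2e²/h`; the
Fermi energy defaults to the HOMO plus a configurable offset, and systems
are compared on HOMO-aligned energy axes. The default spectrum grid runs
from HOMO − 3 eV to LUMO + 1 eV with 400 points.

**DOS and localization.** The atom-projected density of states is
`D_m(E) = −(1/π) Σ_{α∈m} Im G^r_αα(E)` using the *same* Green's function as
transport (contact + probe self-energies), so DOS and transmission describe
one open system; a bare-`η` Lorentzian mode is retained for spectral
checks. Aggregations sum atom rows to base/strand/helix/region resolution.
Localization fractions are squared eigenvector amplitudes summed over a
group; in the orthogonal basis they sum to one exactly.

## The synthetic generator

The DFT matrices behind the original origami study are not distributable,
so the generator emulates their structure as annotated tight-binding
ladders that exercise every pipeline stage:

- One π site per base, with site energies `ε_G = −7.8`, `ε_A = −8.1`,
  `ε_C = −8.3`, `ε_T = −8.4` eV. Only the ordering and the 0.5 eV G–C
  offset are meaningful (guanine's highest-lying occupied levels sit about
  half an eV above cytosine's); absolute values are arbitrary.
- One backbone site per internal phosphodiester linkage at
  `ε_backbone = ε_G − 2 eV`, far below the HOMO region. An 8-bp duplex has
  2·7 = 14 of them and the four-strand origami 4·7 = 28, mirroring the
  phosphate counts (and hence the net charges) of the reference structures.
- Couplings `t_stack = −0.10`, `t_pair = −0.05`, `t_bb = −0.08`,
  `t_chain = −0.12` eV, all well inside the perturbative regime where
  base-character labels stay crisp (enforced: no coupling may reach 10×
  the minimum site-energy spacing).
- Uniform overlap `s = 0.05` on every coupled orbital pair (must stay
  < 0.5 for positive definiteness, checked at build time).
- Optional Gaussian site-energy jitter (`noise_sd`, rigid per-site shift),
  seeded; identical parameters and seed give bit-identical systems.

**Orbital granularity.** Each base site carries two orbitals by default: an
occupied π level at the site energy and a virtual π* level
`virtual_offset = 4 eV` above it; backbone sites carry one occupied
orbital. This makes "one doubly occupied level per site" hold exactly
(`n_occupied = n_atoms`) while the system retains a genuine HOMO–LUMO gap,
and it exercises the per-atom block machinery in every default run. A
3-orbitals-per-base preset (`RICH_PARAMS`) adds a second virtual level.

**Origami topology.** Strand I runs the full length of helix 1 and strand
III of helix 2; crossing strands II and IV complete the complementary
sides, each rerouting its backbone to the other helix at the crossover
index (default mid-sequence; terminal crossovers are rejected). The four
backbone sites at the crossover axial position — one per strand — are
tagged `region="crossover"`. Conformation C1 couples the helices only
through that backbone bridge; C2 adds `t_x = −0.06 eV` between the
terminal bases of the two helices at the far end, emulating terminal bases
brought into proximity.

**What the emulation does and does not show.** Passing tests demonstrate
that the pipeline's mathematics is correct (spectrum conservation, flux
conservation, coherent limits, closed forms) and that the generator
reproduces the *qualitative* electronic structure of the reference
systems: a G band above a C band with an intra-HOMO-band gap, an A/T
region that is more continuous, negligible crossover DOS near the HOMO,
cross-helix conductance suppressed by the backbone barrier in C1 and
partially restored in C2, and mirror symmetry where construction implies
it. They say nothing quantitative about real DNA origami: the published
HOMO−HOMO-1 separations, band gaps and 3–10× conductance ratios derive
from DFT on MD-derived geometries and are not reproduced at this scale.

## Numerical choices and caveats

- **Non-orthogonality is not a small effect.** With `s = 0.05` and site
  energies near −8 eV, Löwdin orthogonalization induces effective
  couplings of order `s·|ε| ≈ 0.4 eV`. Level spacings stretch (the G–C
  peak separation grows from 0.50 to ≈ 0.63 eV) and interstrand mixing
  strengthens (the poly(G)·poly(C) HOMO keeps ≈ 0.8 of its weight on the
  G strand instead of ≈ 0.98 at `s = 0`). Tests assert the sharp values in
  the orthogonal-basis limit and the qualitative ordering at defaults.
- **Parameter recovery** fits the poly(G) chain band
  `ε + 2t·cos(kπ/(L+1))` by linear regression on `cos`; it is performed at
  `s = 0`, where that model is exact — with overlap the generalized band is
  `(ε + 2tc)/(1 + 2sc)` and a cosine fit estimates `t − sε` instead.
- **Degenerate-lattice resonances.** A perfectly mirror-symmetric origami
  has an (almost) degenerate HOMO pair delocalized over both helices; at
  `E_F` exactly on that resonance, cross-helix transmission is large and
  not monotone in `t_x`. C1-vs-C2 comparisons and the `t_x` ramp are
  therefore evaluated at `E_F = HOMO + 0.1 eV`, inside the
  few-hundred-meV window used for scheme comparisons, where the
  inter-helix coupling helps strictly. The same-helix vs cross-helix
  inequality is robust at the HOMO itself. HOMO-spreading comparisons
  between C1 and C2 use a jittered lattice (`noise_sd = 0.05 eV`, fixed
  seed) because with exact degeneracy the eigensolver returns arbitrary
  50/50 helix mixtures.
- **DOS normalization** integrates Lorentzians of width down to `Γ_B/2`;
  tests use grids refined around the eigenvalues plus a ±50Γ tail window,
  which captures each state to well within the 2% check.
- **Problem sizes.** The shipped systems are 8-bp duplexes (30 atoms, 46
  orbitals) and 8-bp two-helix origami (60 atoms, 92 orbitals); spectra
  use a few hundred energy points. These sizes keep every check dense-
  algebra exact while remaining interactive.
- `ContactSpec` permits `gamma_probe = 0` (the fully coherent limit);
  `gamma_contact` must be positive.

## Known limitations

- Real-symmetric Hamiltonians only (no spin–orbit or magnetic field);
  bundles store lower triangles.
- No finite-bias I–V, no inelastic (phonon) self-energies, no
  hopping/polaron regime; the zero-bias linearized Büttiker network is the
  only transport model.
- Electrodes are broadening matrices; there is no atomistic gold/linker
  model, so absolute conductances carry the usual contact-model
  arbitrariness (ratios between schemes are the meaningful output).
- The generator does not attempt quantitative correspondence with any DFT
  parameterization; `t_x` in particular is a free emulation parameter.
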