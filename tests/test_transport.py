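"""Büttiker-probe transport: self-energies, Green's functions, transmissions,
probe potentials, effective transmission and the spectrum driver."""

import numpy as np
import pytest

from dqt import (
    ContactSpec,
    G0,
    build_self_energies,
    effective_transmission,
    effective_transmission_via_current,
    enumerate_schemes,
    pairwise_transmission,
    probe_potentials,
    retarded_green,
    terminal_currents,
    transmission_spectrum,
)
from dqt.errors import (
    AnnotationError,
    IllConditionedError,
    InterpolationRangeError,
    NotSupportedError,
    SchemeError,
)
from dqt.transport import _assemble_transmission_set

from conftest import make_atom_table


def breit_wigner(e, eps, gl, gr):
    return gl * gr / ((e - eps) ** 2 + ((gl + gr) / 2) ** 2)


def chain_hamiltonian(n, t=-0.2, eps=0.0):
    h = np.full((n, n), 0.0)
    np.fill_diagonal(h, eps)
    idx = np.arange(n - 1)
    h[idx, idx + 1] = h[idx + 1, idx] = t
    return h


def gamma_vec(n, value, orbitals):
    g = np.zeros(n)
    g[list(orbitals)] = value
    return g


class TestSelfEnergies:
    def test_three_atom_chain_has_one_probe(self):
        atoms = make_atom_table([1, 1, 1])
        spec = ContactSpec({0}, {2})
        se = build_self_energies(spec, atoms)
        assert se.n_probes == 1
        assert se.probe_atom_ids == [1]
        assert np.allclose(se.probe_gammas[0], [0.0, spec.gamma_probe, 0.0])
        assert np.allclose(se.sigma_left, [-0.3j, 0, 0])
        assert np.allclose(se.sigma_right, [0, 0, -0.3j])

    def test_zero_probe_coupling_gives_zero_sigma_b(self):
        atoms = make_atom_table([1, 1, 1])
        se = build_self_energies(ContactSpec({0}, {2}, gamma_probe=0.0), atoms)
        assert np.all(se.sigma_probes == 0)

    def test_duplex_probe_count_matches_independent_recount(self, gc_duplex):
        catalog = enumerate_schemes(gc_duplex)
        spec = catalog.contact_spec("ds_end_to_end")
        se = build_self_energies(spec, gc_duplex.atoms)
        expected = gc_duplex.n_atoms - len(spec.left_atoms) - len(spec.right_atoms)
        assert se.n_probes == expected

    def test_unknown_contact_atom_rejected(self):
        with pytest.raises(AnnotationError):
            build_self_energies(ContactSpec({0}, {99}), make_atom_table([1, 1]))

    def test_atom_in_both_contacts_rejected(self):
        with pytest.raises(SchemeError):
            ContactSpec({0, 1}, {1, 2})


class TestRetardedGreen:
    def test_scalar_closed_form(self):
        eps, gamma = -1.0, 0.4
        for e in (-2.0, -1.0, 0.5):
            g = retarded_green(e, np.array([[eps]]), np.array([-0.5j * gamma]), eta=0.0)
            assert g[0, 0] == pytest.approx(1.0 / (e - eps + 0.5j * gamma), abs=1e-14)

    def test_advanced_is_conjugate_transpose(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(4, 4))
        h = 0.5 * (h + h.T)
        sigma = -0.3j * gamma_vec(4, 2.0, [0, 3])
        e = 0.2
        g = retarded_green(e, h, sigma, eta=1e-6)
        a = (e + 1e-6j) * np.eye(4) - h - np.diag(sigma)
        assert np.max(np.abs(a @ g - np.eye(4))) < 1e-8
        assert np.max(np.abs(g.conj().T @ a.conj().T - np.eye(4))) < 1e-8

    def test_matches_independent_dense_solve(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(4, 4))
        h = 0.5 * (h + h.T)
        sigma = -0.3j * gamma_vec(4, 0.6, [0, 3])
        g = retarded_green(0.1, h, sigma, eta=0.0)
        oracle = np.linalg.solve(0.1 * np.eye(4) - h - np.diag(sigma), np.eye(4))
        assert np.max(np.abs(g - oracle)) < 1e-10


class TestPairwiseTransmission:
    def test_symmetric_resonance_transmits_fully(self):
        gamma = 0.6
        g = retarded_green(0.0, np.zeros((1, 1)), np.array([-1j * gamma]), eta=0.0)
        ts = pairwise_transmission(g, [np.array([gamma]), np.array([gamma])])
        assert ts.t_lr == pytest.approx(1.0, abs=1e-12)

    def test_asymmetric_resonance_closed_form(self):
        gl, gr = 0.6, 0.2
        g = retarded_green(0.0, np.zeros((1, 1)),
                           np.array([-0.5j * (gl + gr)]), eta=0.0)
        ts = pairwise_transmission(g, [np.array([gl]), np.array([gr])])
        assert ts.t_lr == pytest.approx(4 * 0.6 * 0.2 / 0.8 ** 2, abs=1e-12)

    def test_matches_explicit_trace_formula(self):
        rng = np.random.default_rng(5)
        h = chain_hamiltonian(3, t=float(rng.normal(-0.2, 0.05)))
        gammas = [gamma_vec(3, 0.6, [0]), gamma_vec(3, 0.6, [2]),
                  gamma_vec(3, 0.01, [1])]
        sigma = -0.5j * sum(gammas)
        g = retarded_green(0.05, h, sigma, eta=0.0)
        ts = pairwise_transmission(g, gammas)
        ga = g.conj().T
        for i, gi in enumerate(gammas):
            for j, gj in enumerate(gammas):
                oracle = np.trace(np.diag(gi) @ g @ np.diag(gj) @ ga).real
                assert ts.matrix[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_reciprocity_and_nonnegativity(self, gc_duplex_block):
        se_spec = ContactSpec({0}, {7})
        se = build_self_energies(se_spec, gc_duplex_block.atoms)
        g = retarded_green(-7.1, gc_duplex_block.matrix, se.sigma_total)
        ts = pairwise_transmission(g, se.terminal_gammas())
        assert np.max(np.abs(ts.matrix - ts.matrix.T)) < 1e-9
        assert np.min(ts.matrix) >= -1e-12

    def test_non_diagonal_broadening_rejected(self):
        g = retarded_green(0.0, np.zeros((2, 2)), -0.1j * np.ones(2))
        bad = np.array([[0.1, 0.05], [0.05, 0.1]])
        with pytest.raises(NotSupportedError):
            pairwise_transmission(g, [bad, np.diag([0.1, 0.0])])


class TestProbePotentials:
    @staticmethod
    def _chain_ts(e=0.0, gp=0.01, n=3, probes=(1,), gl=0.6, gr=0.6, t=-0.2):
        h = chain_hamiltonian(n, t=t)
        gammas = [gamma_vec(n, gl, [0]), gamma_vec(n, gr, [n - 1])]
        gammas += [gamma_vec(n, gp, [p]) for p in probes]
        sigma = -0.5j * sum(gammas)
        g = retarded_green(e, h, sigma, eta=0.0)
        return pairwise_transmission(g, gammas, energy=e)

    def test_mirror_symmetric_probe_sits_at_midpoint(self):
        ts = self._chain_ts()
        mu = probe_potentials(ts, 0.5, -0.5)
        assert mu[0] == pytest.approx(0.0, abs=1e-12)
        ts2 = self._chain_ts()
        mu2 = probe_potentials(ts2, 1.0, 0.2)
        assert mu2[0] == pytest.approx(0.6, abs=1e-12)

    def test_zero_probe_coupling_floats_to_midpoint_without_current(self):
        ts = self._chain_ts(gp=0.0)
        mu = probe_potentials(ts, 0.5, -0.5)
        assert mu[0] == pytest.approx(0.0, abs=1e-15)
        cur = terminal_currents(ts, 0.5, -0.5)
        assert abs(cur[2]) < 1e-15

    def test_matches_least_squares_zero_current_oracle(self):
        rng = np.random.default_rng(11)
        n = 4
        h = chain_hamiltonian(n, t=-0.25)
        h[np.diag_indices(n)] = rng.normal(0, 0.1, n)  # asymmetric chain
        gammas = [gamma_vec(n, 0.6, [0]), gamma_vec(n, 0.4, [3]),
                  gamma_vec(n, 0.02, [1]), gamma_vec(n, 0.05, [2])]
        sigma = -0.5j * sum(gammas)
        g = retarded_green(0.03, h, sigma, eta=0.0)
        ts = pairwise_transmission(g, gammas, energy=0.03)
        mu = probe_potentials(ts, 0.5, -0.5)
        # oracle: least-squares solve of sum_j T_ij (mu_i - mu_j) = 0 per probe
        t = ts.matrix.copy()
        np.fill_diagonal(t, 0.0)
        a = np.zeros((2, 2))
        b = np.zeros(2)
        for ii, i in enumerate((2, 3)):
            a[ii, ii] = t[i].sum()
            for jj, j in enumerate((2, 3)):
                if i != j:
                    a[ii, jj] -= t[i, j]
            b[ii] = t[i, 0] * 0.5 + t[i, 1] * (-0.5)
        oracle = np.linalg.lstsq(a, b, rcond=None)[0]
        assert np.allclose(mu, oracle, atol=1e-10)

    def test_zero_current_condition_holds(self):
        ts = self._chain_ts(n=5, probes=(1, 2, 3), t=-0.3)
        probe_potentials(ts, 0.5, -0.5)
        cur = terminal_currents(ts, 0.5, -0.5)
        assert np.max(np.abs(cur[2:])) < 1e-9
        assert abs(cur.sum()) < 1e-9

    def test_ill_conditioned_w_raises_with_energy(self):
        t = np.zeros((4, 4))
        t[0, 1] = t[1, 0] = 0.5
        t[2, 0] = t[0, 2] = 1e-13  # nearly decoupled probe (above decoupled tol)
        t[3, 0] = t[0, 3] = 0.4
        t[3, 1] = t[1, 3] = 0.4
        ts = _assemble_transmission_set(-1.5, ["L", "R", "p0", "p1"], t)
        with pytest.raises(IllConditionedError) as exc:
            probe_potentials(ts, 0.5, -0.5)
        assert exc.value.energy == pytest.approx(-1.5)


class TestEffectiveTransmission:
    def test_no_probes_reduces_to_direct_transmission(self):
        h = chain_hamiltonian(2, t=-0.3)
        gammas = [gamma_vec(2, 0.6, [0]), gamma_vec(2, 0.6, [1])]
        g = retarded_green(0.1, h, -0.5j * sum(gammas), eta=0.0)
        ts = pairwise_transmission(g, gammas)
        assert effective_transmission(ts) == ts.t_lr

    @pytest.mark.parametrize("e", [-0.3, 0.0, 0.2])
    def test_coherent_limit_monotone_on_chain(self, e):
        devs = []
        for gp in (1e-2, 1e-4, 1e-6):
            ts = TestProbePotentials._chain_ts(e=e, gp=gp)
            devs.append(abs(effective_transmission(ts) - ts.t_lr))
        assert devs[0] > devs[1] > devs[2]

    def test_single_site_single_probe_matches_three_terminal_elimination(self):
        # one site, L/R/probe all with equal coupling: solve the 3-terminal
        # current balance by hand-coded elimination
        gamma = 0.3
        g = retarded_green(0.0, np.zeros((1, 1)), np.array([-1.5j * gamma]), eta=0.0)
        gammas = [np.array([gamma])] * 3
        ts = pairwise_transmission(g, gammas, energy=0.0)
        t = ts.matrix
        # zero probe current: T_pL(muL - mup) + T_pR(muR - mup) = 0
        mu_l, mu_r = 0.5, -0.5
        mu_p = (t[2, 0] * mu_l + t[2, 1] * mu_r) / (t[2, 0] + t[2, 1])
        i_l = t[0, 1] * (mu_l - mu_r) + t[0, 2] * (mu_l - mu_p)
        oracle = i_l / (mu_l - mu_r)
        assert effective_transmission(ts) == pytest.approx(oracle, abs=1e-12)

    def test_current_route_agrees_with_w_inverse_route(self):
        ts = TestProbePotentials._chain_ts(n=5, probes=(1, 2, 3))
        via_w = effective_transmission(ts)
        via_i = effective_transmission_via_current(ts, 0.5, -0.5)
        assert via_w == pytest.approx(via_i, abs=1e-10)
        assert via_w >= ts.t_lr - 1e-10


class TestTransmissionSpectrum:
    def test_full_transmission_gives_conductance_quantum(self):
        # symmetric two-site junction with gamma = 2|t| transmits fully at
        # midband (E = 0), so the conductance there is exactly G0
        from dqt.basis import atom_block_transform
        atoms = make_atom_table([1, 1])
        h = np.array([[0.0, -0.2], [-0.2, 0.0]])
        block = atom_block_transform(h, atoms, n_occupied=1)
        spec = ContactSpec({0}, {1}, gamma_contact=0.4)
        grid = np.linspace(-0.4, 0.4, 81)
        res = transmission_spectrum(block, spec, grid=grid, fermi=0.0, eta=0.0)
        assert res.t_eff_at(0.0) == pytest.approx(1.0, abs=1e-12)
        assert res.conductance == pytest.approx(7.748091729e-5, rel=1e-9)

    def test_swapping_contacts_leaves_t_eff_unchanged(self, gc_duplex,
                                                      gc_duplex_block):
        catalog = enumerate_schemes(gc_duplex)
        left, right = catalog.sides("ds_end_to_end")
        grid = np.linspace(-7.6, -6.8, 21)
        fwd = transmission_spectrum(gc_duplex_block, ContactSpec(left, right),
                                    grid=grid, fermi=-7.1)
        rev = transmission_spectrum(gc_duplex_block, ContactSpec(right, left),
                                    grid=grid, fermi=-7.1)
        assert np.max(np.abs(fwd.t_eff - rev.t_eff)) < 1e-9

    def test_driver_matches_single_energy_ops_in_random_order(self, gc_duplex,
                                                              gc_duplex_block):
        catalog = enumerate_schemes(gc_duplex)
        spec = catalog.contact_spec("ds_end_to_end")
        grid = np.linspace(-7.5, -7.0, 11)
        res = transmission_spectrum(gc_duplex_block, spec, grid=grid, fermi=-7.2)
        se = build_self_energies(spec, gc_duplex_block.atoms)
        order = np.random.default_rng(0).permutation(len(grid))
        for k in order:
            g = retarded_green(grid[k], gc_duplex_block.matrix, se.sigma_total)
            ts = pairwise_transmission(g, se.terminal_gammas(), energy=grid[k])
            assert res.t_direct[k] == pytest.approx(ts.t_lr, abs=1e-12)
            assert res.t_eff[k] == pytest.approx(effective_transmission(ts), abs=1e-12)

    def test_fermi_outside_grid_rejected(self, gc_duplex_block):
        spec = ContactSpec({0}, {7})
        grid = np.linspace(-7.5, -7.0, 5)
        with pytest.raises(InterpolationRangeError):
            transmission_spectrum(gc_duplex_block, spec, grid=grid, fermi=-2.0)
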