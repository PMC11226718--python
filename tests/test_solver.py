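"""Discrete-ordinates BFP solver: quadrature, cell sweeps, energy
propagation, scattering sources, angular FP operator and full solves."""

import numpy as np
import pytest

import bfpdose as bd
from bfpdose.quadrature import legendre_all
from bfpdose.solver import (angular_fp_matrix, energy_propagation,
                            gauss_legendre, scattering_source, sweep_cell)
from conftest import absorber_library


class TestGaussLegendre:
    def test_normalisation(self):
        for n in (2, 8, 16):
            mu, w = gauss_legendre(n)
            assert w.sum() == pytest.approx(2.0, abs=1e-14)
            assert np.allclose(mu, -mu[::-1])

    def test_two_point_closed_form(self):
        mu, w = gauss_legendre(2)
        assert np.allclose(np.abs(mu), 1 / np.sqrt(3))
        assert np.allclose(w, 1.0)

    def test_galerkin_discrete_orthogonality(self):
        """With N = L+1 the quadrature integrates P_l P_l' exactly for
        all retained orders: sum_n w_n P_l P_l' = 2 delta / (2l+1)."""
        L, N = 15, 16
        mu, w = gauss_legendre(N)
        pl = legendre_all(L, mu)
        gram = np.einsum("n,ln,kn->lk", w, pl, pl)
        expect = np.diag(2.0 / (2.0 * np.arange(L + 1) + 1.0))
        assert np.max(np.abs(gram - expect)) < 1e-13

    def test_too_few_ordinates(self):
        with pytest.raises(ValueError):
            gauss_legendre(1)


class TestSweepCell:
    def test_hand_evaluated_m0(self):
        """dx=1, mu=1, Sigma=1, L0=1, psi_in=1 -> cell and exit flux 1."""
        mom, out = sweep_cell(0, 1.0, 1.0, 1.0, [[1.0]], 1.0)
        assert mom[0, 0] == pytest.approx(1.0)
        assert out[0] == pytest.approx(1.0)

    def test_free_streaming_all_orders(self):
        for M in (0, 1, 2):
            lt = np.zeros((M + 1, 2))
            mom, out = sweep_cell(M, 0.7, np.array([0.5, -0.5]), 0.0, lt,
                                  np.array([2.0, 3.0]))
            assert np.allclose(mom[0], [2.0, 3.0])
            assert np.allclose(out, [2.0, 3.0])

    def test_m1_reduces_to_m0(self):
        """With a flat source the linear moment vanishes and M=1
        reproduces the M=0 cell flux."""
        mom1, out1 = sweep_cell(1, 1.0, 1.0, 1.0, [[1.0], [0.0]], 1.0)
        mom0, out0 = sweep_cell(0, 1.0, 1.0, 1.0, [[1.0]], 1.0)
        assert mom1[0, 0] == pytest.approx(mom0[0, 0], rel=1e-13)
        assert mom1[1, 0] == pytest.approx(0.0, abs=1e-13)

    @pytest.mark.parametrize("M", [1, 2])
    def test_closed_forms_match_direct_solve(self, M):
        """Closed-form cell solutions equal a dense solve of the printed
        diamond-difference systems, both sweep directions."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            dx = rng.uniform(0.1, 2.0)
            mu = rng.uniform(0.05, 1.0) * rng.choice([-1.0, 1.0])
            sig = rng.uniform(0.0, 3.0)
            lt = rng.normal(size=(M + 1, 1))
            psi_in = rng.normal()
            mom, out = sweep_cell(M, dx, mu, sig, lt, psi_in)
            A = dx * sig
            am, s3, s5, s15 = abs(mu), np.sqrt(3), np.sqrt(5), np.sqrt(15)
            if M == 1:
                mat = np.array([[A, 2 * s3 * mu],
                                [2 * s3 * mu, -A - 6 * am]])
                rhs = np.array([dx * lt[0, 0],
                                -dx * lt[1, 0] + 2 * s3 * mu * psi_in])
            else:
                mat = np.array([
                    [A + 2 * am, 0.0, 2 * s5 * am],
                    [0.0, -A, -2 * s15 * mu],
                    [2 * s5 * am, -2 * s15 * mu, A + 10 * am]])
                rhs = np.array([dx * lt[0, 0] + 2 * am * psi_in,
                                -dx * lt[1, 0],
                                dx * lt[2, 0] + 2 * s5 * am * psi_in])
            ref = np.linalg.solve(mat, rhs)
            assert np.allclose(mom[:, 0], ref, rtol=1e-10, atol=1e-12)


class TestEnergyPropagation:
    def test_classic_diamond(self):
        assert energy_propagation(2.0, 2.0, 1.5, 1.0) == pytest.approx(2.0)

    def test_flat_spectrum_fixed_point(self):
        assert energy_propagation(3.0, 1.0, 2.5, 2.5) == pytest.approx(2.5)

    def test_pure_absorption_guard(self):
        with pytest.raises(ZeroDivisionError):
            energy_propagation(1.0, 0.0, 1.0, 1.0)

    def test_current_conserved_down_a_cascade(self):
        """In an infinite medium the balance relation transmits the CSD
        current beta psi exactly through every group."""
        rng = np.random.default_rng(3)
        beta = rng.uniform(0.5, 5.0, size=51)
        psi_in = 1.0
        current_in = beta[0] * psi_in
        for g in range(50):
            bu, bl = beta[g], beta[g + 1]
            psi = 2.0 * bu * psi_in / (bu + bl)   # zero-D group balance
            psi_out = energy_propagation(bu, bl, psi, psi_in)
            assert bl * psi_out == pytest.approx(bu * psi_in, rel=1e-12)
            psi_in = psi_out
        assert beta[50] * psi_in == pytest.approx(current_in, rel=1e-8)


class TestScatteringSource:
    def test_isotropic_flat(self):
        mu, w = gauss_legendre(4)
        phi = np.array([2.0])          # P0 moment only
        src = scattering_source(phi, np.array([3.0]), mu)
        assert np.allclose(src, 3.0 * 2.0 / 2.0)

    def test_zero_moments(self):
        mu, _ = gauss_legendre(8)
        src = scattering_source(np.zeros(4), np.ones(4), mu)
        assert np.all(src == 0.0)

    def test_galerkin_delta_identity(self):
        """A forward-delta kernel (sigma_l = sigma_0 for l <= L)
        represented on N = L+1 Galerkin ordinates acts as the identity:
        scattering without deflection."""
        L, N = 15, 16
        mu, w = gauss_legendre(N)
        rng = np.random.default_rng(5)
        psi = rng.uniform(0.5, 2.0, size=N)
        pl = legendre_all(L, mu)
        phi_l = np.einsum("n,ln->l", w, pl * psi)
        src = scattering_source(phi_l, np.ones(L + 1), mu)
        assert np.max(np.abs(src - psi)) < 1e-10


class TestAngularFP:
    def test_isotropic_null_space(self):
        mu, w = gauss_legendre(8)
        out = bd.angular_fp(2.0, np.ones(8), mu, w)
        assert np.max(np.abs(out)) < 1e-13

    def test_zeroth_moment_conserved(self):
        mu, w = gauss_legendre(16)
        rng = np.random.default_rng(9)
        psi = rng.normal(size=16)
        out = bd.angular_fp(1.7, psi, mu, w)
        assert abs(np.dot(w, out)) < 1e-13

    def test_relaxes_toward_isotropy(self):
        """All non-trivial eigenvalues of the discrete operator are
        negative: anisotropy decays monotonically in L2."""
        mu, w = gauss_legendre(8)
        B = angular_fp_matrix(mu, w)
        sym = np.diag(w) @ B
        vals = np.linalg.eigvalsh(0.5 * (sym + sym.T))
        assert np.sum(vals > 1e-10) == 0
        assert np.sum(np.abs(vals) < 1e-10) == 1   # the isotropic mode

    def test_disabled_by_default(self):
        mu, w = gauss_legendre(4)
        assert np.all(bd.angular_fp(0.0, np.ones(4), mu, w) == 0.0)


class TestSolve:
    def _absorber_problem(self, gs, sigma, thickness, nvox, M):
        lib = absorber_library(gs, sigma_t=sigma, L=1)
        return bd.SlabProblem(
            regions=[(lib, thickness, nvox)],
            source=bd.BoundarySource(group=gs.G - 1), N=2, M=M, tol=1e-10)

    def test_pure_absorber_exponential(self, gs30):
        """Scalar flux of a purely absorbing slab is exp(-Sigma x / mu)
        within discretisation error."""
        sigma = 1.0
        prob = self._absorber_problem(gs30, sigma, 3.0, 60, M=1)
        sol = bd.solve(prob)
        mu = 1 / np.sqrt(3)
        w_mu = 1.0
        x = sol.depth
        phi = sol.phi[-1]
        analytic = (1.0 / (w_mu * mu)) * w_mu * np.exp(-sigma * x / mu)
        assert np.max(np.abs(phi - analytic) / analytic.max()) < 5e-3

    @pytest.mark.parametrize("M,min_order", [(0, 1.8), (1, 2.7)])
    def test_spatial_convergence_order(self, gs30, M, min_order):
        """Observed order under mesh halving: ~2 for M=0, >=3 for M=1."""
        sigma, mu = 1.0, 1 / np.sqrt(3)
        errs = []
        for nvox in (20, 40, 80):
            prob = self._absorber_problem(gs30, sigma, 2.0, nvox, M)
            sol = bd.solve(prob)
            x = sol.depth
            dx = sol.dx
            a, b = x - dx / 2, x + dx / 2
            cell_avg = (np.exp(-sigma * a / mu) - np.exp(-sigma * b / mu)) \
                / (sigma * dx / mu)
            analytic = cell_avg / mu
            errs.append(np.max(np.abs(sol.phi[-1] - analytic)))
        orders = [np.log2(e1 / e2) for e1, e2 in zip(errs, errs[1:])]
        assert min(orders) > min_order

    def test_vacuum_no_source_zero_flux(self, gs30):
        lib = absorber_library(gs30, sigma_t=0.5, L=1)
        prob = bd.SlabProblem(
            regions=[(lib, 2.0, 10)],
            source=bd.BoundarySource(group=gs30.G - 1, current=0.0),
            N=2, M=0, tol=1e-8)
        sol = bd.solve(prob)
        assert np.all(sol.phi == 0.0)

    def test_galerkin_delta_transport(self, gs30):
        """A pure forward-delta scattering kernel transports without
        deflection: the flux equals free streaming to 1e-10."""
        L, N = 15, 16
        G = gs30.G
        sigma0 = 1.0
        lib = absorber_library(gs30, sigma_t=sigma0, L=L)
        lib.transfer = np.zeros((L + 1, G, G))
        for l in range(L + 1):
            lib.transfer[l, G - 1, G - 1] = sigma0
        free = absorber_library(gs30, sigma_t=0.0, L=L)
        kw = dict(N=N, M=0, tol=1e-13, max_inners=5000)
        src = bd.BoundarySource(group=G - 1)
        sol_d = bd.solve(bd.SlabProblem(regions=[(lib, 3.0, 30)],
                                        source=src, **kw))
        sol_f = bd.solve(bd.SlabProblem(regions=[(free, 3.0, 30)],
                                        source=src, **kw))
        ref = np.max(sol_f.phi[G - 1])
        assert np.max(np.abs(sol_d.phi[G - 1] - sol_f.phi[G - 1])) \
            < 1e-10 * ref

    def test_particle_balance_full_physics(self, water_lib30):
        """Injected + created electrons = killed at cutoff + leaked."""
        lib = water_lib30
        r = bd.csda_range(10.0, "water")
        prob = bd.SlabProblem(regions=[(lib, 1.2 * r, 60)],
                              source=bd.BoundarySource(group=lib.gs.G - 1),
                              N=8, M=1, tol=1e-7)
        sol = bd.solve(prob)
        killed = float(np.sum(sol.subcut_kill * sol.dx))
        leaked = float(sol.leakage.sum())
        prod = lib.channels["ed"] + lib.channels["auger"]
        created = float(np.einsum("gh,gi,i->", prod, sol.phi, sol.dx))
        balance = (killed + leaked - created)
        assert balance == pytest.approx(1.0, rel=1e-3)

    def test_both_sided_irradiation_symmetry(self, water_lib30):
        """Two-sided beams on a symmetric slab give a symmetric dose."""
        lib = water_lib30
        prob = bd.SlabProblem(regions=[(lib, 8.0, 40)],
                              source=bd.BoundarySource(group=lib.gs.G - 1,
                                                       side="both"),
                              N=8, M=1, tol=1e-7)
        sol = bd.solve(prob)
        _, dose = bd.dose_profile(sol)
        assert np.allclose(dose, dose[::-1], rtol=1e-6)

    def test_galerkin_order_mismatch_rejected(self, water_lib30):
        with pytest.raises(ValueError, match="Galerkin"):
            bd.SlabProblem(regions=[(water_lib30, 1.0, 5)],
                           source=bd.BoundarySource(group=29), N=4, M=0)
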