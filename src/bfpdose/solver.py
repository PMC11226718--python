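"""1D discrete-ordinates Boltzmann-Fokker-Planck slab solver.

The multigroup BFP equation couples a Boltzmann catastrophic-collision
kernel (Legendre-expanded, within-group and strictly down-scattering), a
continuous-slowing-down (CSD) operator handled by a weighted-diamond
energy propagation between group boundaries, and an optional angular
Fokker-Planck operator for soft deflections.

Discretisation:

* angles: N-point Gauss-Legendre; with N = L + 1 this is a Galerkin
  quadrature -- the discrete Legendre transform is exactly invertible, so
  a forward-delta scattering kernel transports without deflection;
* space: high-order diamond difference with orthonormal spatial Legendre
  moments of order M in {0, 1, 2}; cell systems are solved in closed
  form during directional sweeps;
* energy: groups are swept top-down (no upscatter exists); inside a group,
  source iteration converges the within-group (elastic) scattering with a
  relative flux criterion (1e-5 by default).

Electrons slowing below the cutoff group are killed, their residual
kinetic energy tallied as a local deposit.  Photon production (soft
radiative, catastrophic bremsstrahlung, fluorescence) is tallied, never
transported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MEC2
from .groups import GroupStructure
from .library import MultigroupLibrary
from .quadrature import legendre_all

SQRT3 = np.sqrt(3.0)
SQRT5 = np.sqrt(5.0)
SQRT15 = np.sqrt(15.0)


def gauss_legendre(N: int):
    """Gauss-Legendre ordinates (mu_n, w_n) on [-1, 1]; sum w = 2."""
    if N < 2:
        raise ValueError("need at least 2 ordinates")
    return np.polynomial.legendre.leggauss(N)


def energy_propagation(beta_plus, beta_minus, psi, psi_plus):
    """Weighted-diamond slowing-down closure.

    ``beta+ psi+ + beta- psi- = (beta+ + beta-) psi`` solved for the
    lower-boundary flux psi-; beta+/psi+ belong to the higher-energy
    (inflow) edge.  With beta- = 0 the CSD current is purely absorbed and
    no outflow flux exists.
    """
    if beta_minus == 0.0:
        raise ZeroDivisionError("beta- = 0: no lower-edge flux is defined")
    return ((beta_plus + beta_minus) * psi - beta_plus * psi_plus) \
        / beta_minus


def scattering_source(phi_l, sigma_l, mu_n):
    """Within-group scattering source (2l+1)/2 P_l(mu_n) sigma_l phi_l.

    ``phi_l`` has leading Legendre axis (L+1, ...); returns shape
    (N, ...) over the ordinates ``mu_n``.
    """
    phi_l = np.asarray(phi_l, dtype=float)
    sigma_l = np.asarray(sigma_l, dtype=float)
    L = sigma_l.shape[0] - 1
    pl = legendre_all(L, np.asarray(mu_n, dtype=float))  # (L+1, N)
    cl = (2.0 * np.arange(L + 1) + 1.0) / 2.0
    weighted = phi_l * sigma_l.reshape((L + 1,) + (1,) * (phi_l.ndim - 1))
    return np.einsum("ln,l...->n...", cl[:, None] * pl, weighted)


def angular_fp_matrix(mu, w):
    """Conservative discretisation of d/dmu (1 - mu^2) d/dmu on the
    quadrature nodes (Morel's weighted-difference form).

    The zeroth angular moment of the output vanishes identically and an
    isotropic distribution is in the null space.
    """
    N = mu.size
    gamma = np.zeros(N + 1)
    for n in range(N):
        gamma[n + 1] = gamma[n] - 2.0 * mu[n] * w[n]
    gamma[-1] = 0.0
    B = np.zeros((N, N))
    for n in range(N):
        if n + 1 < N:
            c = gamma[n + 1] / (mu[n + 1] - mu[n]) / w[n]
            B[n, n + 1] += c
            B[n, n] -= c
        if n - 1 >= 0:
            c = gamma[n] / (mu[n] - mu[n - 1]) / w[n]
            B[n, n - 1] += c
            B[n, n] -= c
    return B


def angular_fp(alpha_g, psi, mu, w):
    """Apply (alpha_g / 2) times the discrete angular FP operator."""
    if alpha_g == 0.0:
        return np.zeros_like(psi)
    B = angular_fp_matrix(np.asarray(mu), np.asarray(w))
    return 0.5 * alpha_g * np.einsum("nm,m...->n...", B, psi)


def sweep_cell(M, dx, mu, sigma_tilde, Lt, psi_in):
    """Solve one spatial cell for a batch of directions.

    ``Lt`` has shape (M+1, N) (spatial source moments per direction),
    ``psi_in`` (N,) the incoming edge flux.  Returns the cell flux
    moments (M+1, N) and the outgoing edge flux (N,).  Closed forms of
    the order-M diamond-difference systems.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    psi_in = np.atleast_1d(np.asarray(psi_in, dtype=float))
    Lt = np.atleast_2d(np.asarray(Lt, dtype=float))
    if np.any(mu == 0.0):
        raise ValueError("mu = 0 ordinate is not sweepable")
    am = np.abs(mu)
    sgn = np.sign(mu)
    A = dx * sigma_tilde
    if M == 0:
        psi0 = (dx * Lt[0] + 2.0 * am * psi_in) / (A + 2.0 * am)
        out = 2.0 * psi0 - psi_in
        return psi0[None, :], out
    if M == 1:
        b = 2.0 * SQRT3 * mu
        r1 = dx * Lt[0]
        r2 = -dx * Lt[1] + b * psi_in
        det = -A * (A + 6.0 * am) - b * b
        if np.any(np.abs(det) < 1e-300):
            raise np.linalg.LinAlgError("singular M=1 cell system")
        psi0 = (-(A + 6.0 * am) * r1 - b * r2) / det
        psi1 = (A * r2 - b * r1) / det
        out = psi_in + 2.0 * SQRT3 * sgn * psi1
        return np.stack([psi0, psi1]), out
    if M == 2:
        N = mu.size
        mat = np.zeros((N, 3, 3))
        mat[:, 0, 0] = A + 2.0 * am
        mat[:, 0, 2] = 2.0 * SQRT5 * am
        mat[:, 1, 1] = -A
        mat[:, 1, 2] = -2.0 * SQRT15 * mu
        mat[:, 2, 0] = 2.0 * SQRT5 * am
        mat[:, 2, 1] = -2.0 * SQRT15 * mu
        mat[:, 2, 2] = A + 10.0 * am
        rhs = np.stack([dx * Lt[0] + 2.0 * am * psi_in,
                        -dx * Lt[1],
                        dx * Lt[2] + 2.0 * SQRT5 * am * psi_in], axis=-1)
        sol = np.linalg.solve(mat, rhs[..., None])[..., 0]
        psi = sol.T
        out = 2.0 * psi[0] + 2.0 * SQRT5 * psi[2] - psi_in
        return psi, out
    raise ValueError("spatial order M must be 0, 1 or 2")


@dataclass
class BoundarySource:
    group: int                   # incident energy group
    side: str = "left"           # 'left' | 'right' | 'both'
    current: float = 1.0         # electrons per cm^2 per source electron


@dataclass
class SlabProblem:
    """Ordered material regions with mesh and discretisation settings."""

    regions: list                 # [(MultigroupLibrary, thickness_cm, nvox)]
    source: BoundarySource
    N: int = 16
    M: int = 1
    tol: float = 1e-5
    max_inners: int = 200
    galerkin: bool = True

    def __post_init__(self):
        if not self.regions:
            raise ValueError("need at least one region")
        libs = [r[0] for r in self.regions]
        gs0 = libs[0].gs
        for lib in libs[1:]:
            if not lib.gs.same_as(gs0, tol=1e-12):
                raise ValueError("regions use different group structures")
        if any(r[1] <= 0 for r in self.regions):
            raise ValueError("region thicknesses must be positive")
        L = libs[0].L
        if self.galerkin and self.N != L + 1:
            raise ValueError(
                f"Galerkin quadrature requires N = L + 1 = {L + 1}")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")

    def mesh(self):
        """Cell widths, cell->library map and unique libraries."""
        libs, dx, lib_idx = [], [], []
        for lib, thick, nvox in self.regions:
            if lib not in libs:
                libs.append(lib)
            k = libs.index(lib)
            dx.extend([thick / nvox] * nvox)
            lib_idx.extend([k] * nvox)
        return np.asarray(dx), np.asarray(lib_idx, dtype=int), libs


@dataclass
class FluxSolution:
    gs: GroupStructure
    dx: np.ndarray               # (I,)
    lib_idx: np.ndarray          # (I,)
    libs: list
    phi_l: np.ndarray            # (G, L+1, I): scalar-flux Legendre moments
    leakage: np.ndarray          # (G, 2): left/right outflow currents
    subcut_kill: np.ndarray      # (I,): electrons/cm^3 killed below cutoff
    iterations: np.ndarray       # (G,)
    negative_fraction: float
    source: BoundarySource

    @property
    def phi(self) -> np.ndarray:
        return self.phi_l[:, 0, :]

    @property
    def depth(self) -> np.ndarray:
        return np.cumsum(self.dx) - 0.5 * self.dx


def solve(problem: SlabProblem) -> FluxSolution:
    """Source-iteration solve, sweeping groups from high to low energy."""
    dx, lib_idx, libs = problem.mesh()
    I = dx.size
    gs = libs[0].gs
    G, L = gs.G, libs[0].L
    M, N = problem.M, problem.N
    mu, w = gauss_legendre(N)
    pl_mu = legendre_all(L, mu)                       # (L+1, N)
    cl = (2.0 * np.arange(L + 1) + 1.0) / 2.0
    proj = (cl[:, None] * pl_mu).T                    # (N, L+1)
    pos = mu > 0
    neg = ~pos

    # per-cell material tables
    sig_t = np.stack([lib.sigma_t for lib in libs])       # (K, G)
    beta_bnd = np.stack([lib.beta_bnd for lib in libs])   # (K, G+1)
    alpha = np.stack([lib.alpha for lib in libs])         # (K, G)
    dE = gs.widths * MEC2                                 # (G,)

    phi_l = np.zeros((G, L + 1, I))
    phi_la = np.zeros((G, L + 1, I, M + 1))
    leak = np.zeros((G, 2))
    subcut = np.zeros(I)
    iters = np.zeros(G, dtype=int)
    n_neg = 0
    n_val = 0

    src = problem.source
    g_src = src.group if src.group is not None else G - 1
    # boundary angular flux: beam along the most forward ordinate,
    # normalised to unit incident current
    n_fwd = int(np.argmax(mu))
    n_bwd = int(np.argmin(mu))
    psi_edge_csd = np.zeros((N, I, M + 1))   # inflow from the group above

    fp_B = angular_fp_matrix(mu, w) if np.any(alpha != 0.0) else None

    for g in range(G - 1, -1, -1):
        st = sig_t[lib_idx, g]                       # (I,)
        b_up = beta_bnd[lib_idx, g + 1]
        b_lo = beta_bnd[lib_idx, g]
        sig_eff = st + (b_up + b_lo) / dE[g]
        alf = alpha[lib_idx, g]

        # down-scatter source moments (fixed during inners)
        q_dn = np.zeros((L + 1, I, M + 1))
        if g + 1 < G:
            if len(libs) == 1:
                T = libs[0].transfer[:, g + 1:, g]   # (L+1, Gup)
                q_dn = np.einsum("lk,klia->lia", T, phi_la[g + 1:])
            else:
                for k, lib in enumerate(libs):
                    cells = lib_idx == k
                    T = lib.transfer[:, g + 1:, g]
                    q_dn[:, cells, :] += np.einsum(
                        "lk,klia->lia", T, phi_la[g + 1:, :, cells, :])
        csd_src = (2.0 / dE[g]) * b_up[None, :, None] * psi_edge_csd

        # in-group (diagonal) transfer per cell
        t_diag = np.zeros((L + 1, I))
        for k, lib in enumerate(libs):
            t_diag[:, lib_idx == k] = lib.transfer[:, g, g][:, None]

        psi = np.zeros((N, I, M + 1))
        phi_a = np.zeros((L + 1, I, M + 1))
        bl_in = np.zeros(N)
        br_in = np.zeros(N)
        if g == g_src:
            if src.side in ("left", "both"):
                bl_in[n_fwd] = src.current / (w[n_fwd] * mu[n_fwd])
            if src.side in ("right", "both"):
                br_in[n_bwd] = src.current / (w[n_bwd] * abs(mu[n_bwd]))

        phi_prev = np.zeros(I)
        for it in range(problem.max_inners):
            q_mom = q_dn + t_diag[:, :, None] * phi_a
            lt = np.einsum("nl,li a->ni a", proj, q_mom) + csd_src
            if fp_B is not None and np.any(alf != 0.0):
                lt = lt + 0.5 * alf[None, :, None] * np.einsum(
                    "nm,mia->nia", fp_B, psi)

            # forward sweep
            edge = bl_in[pos].copy()
            for i in range(I):
                mom, edge = sweep_cell(M, dx[i], mu[pos], sig_eff[i],
                                       lt[pos, i, :].T, edge)
                psi[pos, i, :] = mom.T
            leak_r = float(np.sum(w[pos] * mu[pos] * edge))
            # backward sweep
            edge = br_in[neg].copy()
            for i in range(I - 1, -1, -1):
                mom, edge = sweep_cell(M, dx[i], mu[neg], sig_eff[i],
                                       lt[neg, i, :].T, edge)
                psi[neg, i, :] = mom.T
            leak_l = float(np.sum(w[neg] * np.abs(mu[neg]) * edge))

            phi_a = np.einsum("n,ln,nia->lia", w, pl_mu, psi)
            phi_new = phi_a[0, :, 0]
            ref = np.max(np.abs(phi_new)) or 1.0
            err = np.max(np.abs(phi_new - phi_prev)) / ref
            phi_prev = phi_new.copy()
            if err < problem.tol:
                break
        else:
            raise RuntimeError(
                f"group {g}: source iteration did not converge "
                f"({problem.max_inners} inners, residual {err:.3e})")
        iters[g] = it + 1
        n_neg += int(np.count_nonzero(phi_new < 0))
        n_val += I

        phi_l[g] = phi_a[:, :, 0]
        phi_la[g] = phi_a
        leak[g, 0], leak[g, 1] = leak_l, leak_r

        # CSD outflow edge flux (weighted diamond), inflow for group g-1
        with np.errstate(divide="ignore", invalid="ignore"):
            out_edge = ((b_up + b_lo)[None, :, None] * psi
                        - b_up[None, :, None] * psi_edge_csd) \
                / b_lo[None, :, None]
        out_edge = np.where(b_lo[None, :, None] > 0.0, out_edge, 0.0)
        if g == 0:
            # electrons crossing the cutoff: local kill, count them
            subcut = np.einsum("n,ni->i", w, out_edge[:, :, 0]) \
                * b_lo / dE[g]
            psi_edge_csd = out_edge
        else:
            # the edge flux is an energy density scaled by the group
            # width: rescale when handing it to the narrower group below
            psi_edge_csd = out_edge * (dE[g - 1] / dE[g])

    return FluxSolution(gs=gs, dx=dx, lib_idx=lib_idx, libs=libs,
                        phi_l=phi_l, leakage=leak, subcut_kill=subcut,
                        iterations=iters,
                        negative_fraction=n_neg / max(n_val, 1),
                        source=src)
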