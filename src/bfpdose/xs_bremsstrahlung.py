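"""Catastrophic bremsstrahlung: Berger-Seltzer assembled cross sections.

The single differential cross section in photon energy is assembled from
four Born-type kernels:

* ``sigma1`` -- exact unscreened Born (Sauter-Gluckstern-Hull / Koch-Motz
  form), valid at intermediate energies;
* ``sigma2`` -- screened Born with Thomas-Fermi screening functions;
* ``sigma3`` -- the unscreened high-energy logarithmic limit;
* ``sigma4`` -- ``sigma2`` with the Davies-Bethe-Maximon Coulomb
  correction f(Z).

The working combination ``sigma1 + sigma2 - sigma3 + omega (sigma4 -
sigma2)`` interpolates smoothly: where screening is weak sigma2 ~ sigma3
and the exact Born kernel survives; at high energy sigma1 ~ sigma3 and the
screened (Coulomb-corrected) kernel survives.  The whole assembly is
multiplied by the Elwert factor and an optional atomic correction xi_r.

The surviving electron is emitted strictly forward (P_l(1) = 1 for all l),
so one matrix serves every Legendre order.  Photons are not transported:
their emitted energy is integrated per emitting group for bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ALPHA, R0
from .constants import MEC2
from .elements import ElementRecord, get_element
from .groups import GroupStructure
from .quadrature import panel_points, split_panels

#: count of negative assembled DDCS values clamped to zero
CLAMP_COUNT = 0

#: omega ramp bounds on the *total* electron energy, MeV
OMEGA_LO_MEV = 15.0
OMEGA_HI_MEV = 50.0

#: fraction of the spectrum tip replaced by a linear ramp to zero
TIP_FRACTION = 0.01


def reset_clamp_count():
    global CLAMP_COUNT
    CLAMP_COUNT = 0


def coulomb_f(Z):
    """Davies-Bethe-Maximon Coulomb correction f(Z).

    Series in a = Z alpha; zero at Z = 0 and monotone increasing.
    """
    a2 = (np.asarray(Z, dtype=float) * ALPHA) ** 2
    out = a2 * (1.0 / (1.0 + a2) + 0.20206 - 0.0369 * a2
                + 0.0083 * a2 ** 2 - 0.002 * a2 ** 3)
    return out if out.ndim else float(out)


def screening_zeta(e_gamma, e_t, e_s, Z):
    """Screening argument zeta = 100 e_gamma / (e_t e_s Z^(1/3))."""
    return 100.0 * e_gamma / (e_t * e_s * float(Z) ** (1.0 / 3.0))


def screening_phis(zeta):
    """Thomas-Fermi screening functions (Phi1, Phi2).

    Single smooth expressions (Tsai's fit), so no fit-piece boundary
    exists; complete screening gives Phi1(0) = 20.863, Phi2(0) = 20.196
    and Phi1 - Phi2 -> 0 in the weak-screening (large zeta) limit.
    """
    z = np.asarray(zeta, dtype=float)
    phi1 = (20.863 - 2.0 * np.log1p((0.55846 * z) ** 2)
            - 4.0 * (1.0 - 0.6 * np.exp(-0.9 * z) - 0.4 * np.exp(-1.5 * z)))
    phi2 = phi1 - 2.0 / 3.0 / (1.0 + 6.5 * z + 6.0 * z ** 2)
    if phi1.ndim:
        return phi1, phi2
    return float(phi1), float(phi2)


def elwert_factor(e_prime, e_gamma, Z):
    """Elwert Coulomb ratio correction.

    ``(beta'/beta) (1 - exp(-2 pi Z alpha / beta')) /
    (1 - exp(-2 pi Z alpha / beta))`` with beta evaluated after emission;
    tends to 1 for soft photons and exactly 1 for Z = 0.
    """
    e_prime = np.asarray(e_prime, dtype=float)
    e_gamma = np.asarray(e_gamma, dtype=float)
    e_t = e_prime + 1.0
    e_s = e_t - e_gamma
    b0 = np.sqrt(e_prime * (e_prime + 2.0)) / e_t
    bs = np.sqrt(np.maximum(e_s ** 2 - 1.0, 0.0)) / e_s
    if Z == 0:
        out = np.ones_like(b0)
        return out if out.ndim else 1.0
    x0 = 2.0 * np.pi * Z * ALPHA / b0
    xs = 2.0 * np.pi * Z * ALPHA / np.maximum(bs, 1e-300)
    out = (b0 / np.maximum(bs, 1e-300)) * (-np.expm1(-x0)) / (-np.expm1(-xs))
    return out if out.ndim else float(out)


def omega_weight(e_prime, lo_mev=None, hi_mev=None):
    """Smooth 0 -> 1 ramp in total energy switching the Coulomb correction on."""
    lo = OMEGA_LO_MEV if lo_mev is None else lo_mev
    hi = OMEGA_HI_MEV if hi_mev is None else hi_mev
    et_mev = (np.asarray(e_prime, dtype=float) + 1.0) * MEC2
    t = np.clip((et_mev - lo) / (hi - lo), 0.0, 1.0)
    out = t * t * (3.0 - 2.0 * t)
    return out if out.ndim else float(out)


def _zz(Z, include_electron_field):
    return Z * (Z + 1.0) if include_electron_field else float(Z) ** 2


def sigma1(e_prime, e_gamma, Z, include_electron_field=True):
    """Unscreened Born kernel (Koch-Motz form), cm^2 per reduced energy."""
    et = e_prime + 1.0
    es = et - e_gamma
    p0 = np.sqrt(et ** 2 - 1.0)
    p = np.sqrt(np.maximum(es ** 2 - 1.0, 1e-300))
    eps0 = 2.0 * np.log(et + p0)
    eps = 2.0 * np.log(es + p)
    big_l = 2.0 * np.log(np.maximum((et * es + p0 * p - 1.0) / e_gamma, 1e-300))
    k = e_gamma
    bracket = (
        4.0 / 3.0
        - 2.0 * et * es * (p0 ** 2 + p ** 2) / (p0 ** 2 * p ** 2)
        + eps0 * es / p0 ** 3 + eps * et / p ** 3
        - eps * eps0 / (p0 * p)
        + big_l * (
            8.0 / 3.0 * et * es / (p0 * p)
            + k ** 2 * (et ** 2 * es ** 2 + p0 ** 2 * p ** 2) / (p0 ** 3 * p ** 3)
            + k / (2.0 * p0 * p) * (
                (et * es + p0 ** 2) / p0 ** 3 * eps0
                - (et * es + p ** 2) / p ** 3 * eps
                + 2.0 * k * et * es / (p0 ** 2 * p ** 2)
            )
        )
    )
    return _zz(Z, include_electron_field) * R0 ** 2 * ALPHA / k * (p / p0) * bracket


def sigma2(e_prime, e_gamma, Z, include_electron_field=True, f_coul=0.0):
    """Screened Born kernel; with ``f_coul`` > 0 it becomes sigma4."""
    et = e_prime + 1.0
    es = et - e_gamma
    ratio = es / et
    zeta = screening_zeta(e_gamma, et, es, Z)
    phi1, phi2 = screening_phis(zeta)
    ln_z3 = np.log(float(Z)) / 3.0 if Z > 0 else 0.0
    val = ((1.0 + ratio ** 2) * (0.25 * phi1 - ln_z3 - f_coul)
           - 2.0 / 3.0 * ratio * (0.25 * phi2 - ln_z3 - f_coul))
    return 4.0 * _zz(Z, include_electron_field) * R0 ** 2 * ALPHA / e_gamma * val


def sigma3(e_prime, e_gamma, Z, include_electron_field=True):
    """Unscreened high-energy logarithmic limit."""
    et = e_prime + 1.0
    es = et - e_gamma
    ratio = es / et
    val = ((1.0 - 2.0 / 3.0 * ratio + ratio ** 2)
           * (np.log(2.0 * et * es / e_gamma) - 0.5))
    return 4.0 * _zz(Z, include_electron_field) * R0 ** 2 * ALPHA / e_gamma * val


def sigma4(e_prime, e_gamma, Z, include_electron_field=True):
    """Olsen-Maximon Coulomb-corrected screened kernel."""
    return sigma2(e_prime, e_gamma, Z, include_electron_field,
                  f_coul=coulomb_f(Z))


def high_frequency_limit(e_prime, e_cut):
    """Maximum photon energy: the electron may fall to ``e_cut`` at most."""
    return e_prime - e_cut


def berger_seltzer_ddcs(e_prime, e_gamma, elem, e_gamma_max=None,
                        xi_r=1.0, omega=None, include_electron_field=True,
                        tip_fraction=None, clamp=True):
    """Assembled bremsstrahlung DDCS, cm^2 per unit reduced photon energy.

    ``e_gamma_max`` caps the spectrum (default: the photon takes all but
    1e-3 of the kinetic energy); the last ``tip_fraction`` of the spectrum
    is a linear ramp to zero replacing the divergent Elwert tip.  Negative
    assembled values (possible deep in corners of the fit domain) are
    clamped to zero and counted in ``CLAMP_COUNT``.
    """
    global CLAMP_COUNT
    Z = elem.Z if isinstance(elem, ElementRecord) else int(elem)
    e_prime = np.asarray(e_prime, dtype=float)
    e_gamma = np.asarray(e_gamma, dtype=float)
    tip = TIP_FRACTION if tip_fraction is None else tip_fraction
    kmax = (e_prime * (1.0 - 1e-3) if e_gamma_max is None
            else np.asarray(e_gamma_max, dtype=float))
    k_knee = (1.0 - tip) * kmax
    ramp = np.clip((kmax - e_gamma) / np.maximum(kmax - k_knee, 1e-300),
                   0.0, 1.0)
    k_eval = np.minimum(e_gamma, k_knee)

    w = omega_weight(e_prime) if omega is None else omega
    s1 = sigma1(e_prime, k_eval, Z, include_electron_field)
    s2 = sigma2(e_prime, k_eval, Z, include_electron_field)
    s3 = sigma3(e_prime, k_eval, Z, include_electron_field)
    s4 = sigma4(e_prime, k_eval, Z, include_electron_field)
    fe = elwert_factor(e_prime, k_eval, Z)
    val = xi_r * fe * (s1 + s2 - s3 + w * (s4 - s2)) * ramp
    neg = val < 0.0
    if clamp and np.any(neg):
        CLAMP_COUNT += int(np.count_nonzero(neg))
        val = np.where(neg, 0.0, val)
    return val if val.ndim else float(val)


@dataclass
class BremsTransfer:
    """Surviving-electron bremsstrahlung transfer for one element.

    ``sigma0[gp, g]`` is the zeroth-Legendre group-to-group microscopic
    cross section (cm^2); forward emission makes every Legendre order equal
    to it.  ``sigma1_out`` carries the outgoing-energy first moment,
    ``total_e1`` the incident-energy-weighted total, and ``photon_energy``
    the emitted catastrophic photon energy per incident group (reduced
    energy x cm^2).
    """

    gs: GroupStructure
    L: int
    Z: int
    sigma0: np.ndarray        # (G, G)
    sigma1_out: np.ndarray    # (G, G), reduced-energy weighted
    total: np.ndarray         # (G,)
    total_e1: np.ndarray      # (G,)
    photon_energy: np.ndarray  # (G,)

    def legendre(self, l: int) -> np.ndarray:
        if not 0 <= l <= self.L:
            raise ValueError("Legendre order out of range")
        return self.sigma0


def _inner_brems(ep, wp, lo, hi, kink, Z, e_cut_top, include_electron_field,
                 xi_r):
    """Integrate the DDCS over electron exit energies [lo, hi] per e' node.

    Returns (zeroth, e_out-weighted, photon-energy-weighted) integrals
    accumulated over the outer nodes with weights ``wp``.  The integration
    interval is split at the tip-ramp knee (expressed as an exit energy,
    ``kink``) whenever the knee lies inside it.
    """
    kmax = ep - e_cut_top
    tot = np.zeros(3)
    if np.max(kink) <= lo or np.min(kink) >= hi:
        panels = ((np.full_like(ep, lo), np.full_like(ep, hi)),)
    else:
        mid = np.clip(kink, lo, hi)
        panels = ((np.full_like(ep, lo), mid), (mid, np.full_like(ep, hi)))
    for a, b in panels:
        ee, we = panel_points(a, b, 16)
        epp = ep[..., None]
        k = epp - ee
        val = berger_seltzer_ddcs(epp, k, Z, e_gamma_max=kmax[..., None],
                                  xi_r=xi_r,
                                  include_electron_field=include_electron_field)
        base = we * val
        tot[0] += np.sum(wp[..., None] * base)
        tot[1] += np.sum(wp[..., None] * base * ee)
        tot[2] += np.sum(wp[..., None] * base * k)
    return tot


def build_brems_transfer(gs: GroupStructure, L: int, elem,
                         include_electron_field=True, xi_r=1.0,
                         n_outer=16) -> BremsTransfer:
    """Group-to-group surviving-electron transfer matrices for the
    catastrophic radiative channel.

    The catastrophic domain for incident group g' restricts the surviving
    electron to ``e_e <= b[g'-2]`` (the two-boundary skip rule) and
    ``e_e >= b[1]`` (the photon may at most take the electron down to the
    top of the cutoff group).
    """
    elem = get_element(elem) if not isinstance(elem, ElementRecord) else elem
    if L < 0:
        raise ValueError("Legendre order must be >= 0")
    b = gs.bounds
    G = gs.G
    sig0 = np.zeros((G, G))
    sig1 = np.zeros((G, G))
    photon = np.zeros(G)
    total_e1 = np.zeros(G)
    e_cut_top = b[1]
    for gp in range(3, G):
        e_lo, e_hi = b[gp], b[gp + 1]
        width = e_hi - e_lo
        emax_dest = b[gp - 2]
        for g in range(1, gp - 2):
            lo = b[g]
            hi = min(b[g + 1], emax_dest)
            if hi <= lo:
                continue
            # outer split where the tip-ramp knee crosses the inner bounds:
            # knee(e') = e' - 0.99 (e' - b1) = 0.01 e' + 0.99 b1
            breaks = [(lo - 0.99 * e_cut_top) / 0.01,
                      (hi - 0.99 * e_cut_top) / 0.01]
            for a_p, b_p in split_panels(e_lo, e_hi, breaks):
                ep, wp = panel_points(a_p, b_p, n_outer)
                kink = 0.01 * ep + 0.99 * e_cut_top
                z0, z1, zk = _inner_brems(ep, wp, lo, hi, kink, elem.Z,
                                          e_cut_top,
                                          include_electron_field, xi_r)
                sig0[gp, g] += z0 / width
                sig1[gp, g] += z1 / width
                photon[gp] += zk / width
    total = sig0.sum(axis=1)
    # total_e1: total weighted by incident energy; recompute by one sweep
    # over the full catastrophic domain per incident group.
    for gp in range(3, G):
        e_lo, e_hi = b[gp], b[gp + 1]
        width = e_hi - e_lo
        emax_dest = b[gp - 2]
        lo, hi = e_cut_top, emax_dest
        if hi <= lo:
            continue
        breaks = [(lo - 0.99 * e_cut_top) / 0.01,
                  (hi - 0.99 * e_cut_top) / 0.01]
        acc = 0.0
        for a_p, b_p in split_panels(e_lo, e_hi, breaks):
            ep, wp = panel_points(a_p, b_p, n_outer)
            kink = 0.01 * ep + 0.99 * e_cut_top
            # split the inner integral at every group boundary so panel
            # quadrature matches the per-destination assembly exactly
            inner_breaks = b[(b > lo) & (b < hi)]
            edges = np.concatenate(([lo], inner_breaks, [hi]))
            for ia, ib in zip(edges[:-1], edges[1:]):
                z0, _, _ = _inner_brems(ep, wp * ep, ia, ib, kink, elem.Z,
                                        e_cut_top,
                                        include_electron_field, xi_r)
                acc += z0
        total_e1[gp] = acc / width
    return BremsTransfer(gs=gs, L=L, Z=elem.Z, sigma0=sig0, sigma1_out=sig1,
                         total=total, total_e1=total_e1,
                         photon_energy=photon)
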