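"""Catastrophic Moller ionization: DDCS, kinematics and transfer matrices.

Ionization is treated as a free-electron two-body collision.  Of the two
outgoing electrons the less energetic one is the delta ray, so
``e_delta <= e'/2``.  A collision is *catastrophic* when the scattered
primary skips past two group boundaries below its incident group
(equivalently the delta ray receives at least ``e_c = e' - b[g'-2]``);
smaller losses are soft and belong to the continuous-slowing-down
operator.  Group indices are 0-based with energy increasing with index.

The transfer matrices are built with fixed-order Gauss-Legendre panel
quadrature, with panels split wherever a kinematic bound crosses a group
boundary so every panel integrand is smooth.  Closed-form antiderivatives
of the Moller kernel provide an independent path for totals and
catastrophic energy-loss moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R0, velocity_beta
from .elements import ElementRecord, get_element
from .groups import GroupStructure
from .quadrature import legendre_all, panel_points, split_panels


def moller_ddcs(e_prime, e_delta):
    """Moller DDCS, cm^2 per unit reduced delta energy, per target electron.

    Valid for ``0 < e_delta <= e_prime / 2`` (delta = less energetic
    electron); symmetric in the exchange e_delta <-> e' - e_delta.
    """
    ep = np.asarray(e_prime, dtype=float)
    ed = np.asarray(e_delta, dtype=float)
    if np.any(ed <= 0) or np.any(ed > ep / 2.0 * (1 + 1e-12)):
        raise ValueError("delta energy must lie in (0, e'/2]")
    out = _moller_kernel(ep, ed)
    return out if out.ndim else float(out)


def _moller_kernel(ep, ed):
    """Moller single-differential cross section, no domain checks.

    2 pi (r0/beta')^2 times the bracketed form; the azimuthal 2 pi makes
    the kernel consistent with the collisional stopping-power prefactor
    2 pi r0^2 m_e c^2 / beta^2 (so the soft/catastrophic split of the
    restricted stopping power carves up the same physical loss rate).
    """
    ee = ep - ed
    beta = velocity_beta(ep)
    bracket = (1.0 / ed ** 2 + 1.0 / ee ** 2 + 1.0 / (ep + 1.0) ** 2
               - (2.0 * ep + 1.0) / ((ep + 1.0) ** 2 * ee * ed))
    return 2.0 * np.pi * (R0 / beta) ** 2 * bracket


def _moller_int0(ep, a, b):
    """Closed-form integral of the kernel over delta energy in [a, b]."""
    def F(ed):
        ee = ep - ed
        return (-1.0 / ed + 1.0 / ee + ed / (ep + 1.0) ** 2
                - (2.0 * ep + 1.0) / ((ep + 1.0) ** 2 * ep)
                * (np.log(ed) - np.log(ee)))
    beta = velocity_beta(ep)
    return 2.0 * np.pi * (R0 / beta) ** 2 * (F(b) - F(a))


def _moller_int1(ep, a, b):
    """Closed-form integral of e_delta x kernel over [a, b]."""
    def G(ed):
        ee = ep - ed
        return (np.log(ed) + np.log(ee) + ep / ee
                + ed ** 2 / (2.0 * (ep + 1.0) ** 2)
                + (2.0 * ep + 1.0) / (ep + 1.0) ** 2 * np.log(ee))
    beta = velocity_beta(ep)
    return 2.0 * np.pi * (R0 / beta) ** 2 * (G(b) - G(a))


def kinematic_cosine(e_prime, e_out):
    """Laboratory cosine of an outgoing electron of energy ``e_out``.

    mu = sqrt(e_out (e' + 2) / (e' (e_out + 2))): 1 for no loss, -> 0 as
    the outgoing energy vanishes; both outgoing electrons are forward.
    """
    ep = np.asarray(e_prime, dtype=float)
    eo = np.asarray(e_out, dtype=float)
    if np.any(eo > ep * (1 + 1e-12)):
        raise ValueError("outgoing energy exceeds incident energy")
    out = np.sqrt(eo * (ep + 2.0) / (ep * (eo + 2.0)))
    return out if out.ndim else float(out)


def catastrophic_cutoff(gp: int, gs: GroupStructure, e_prime=None):
    """Minimum delta energy for a catastrophic collision in group ``gp``.

    ``e_c = e' - b[gp - 2]`` (0-based boundaries).  For ``gp < 2`` there is
    no boundary two steps below: the channel is empty and every loss is
    soft, expressed by returning ``e'/2`` (an empty delta interval).
    """
    ep = gs.midpoints[gp] if e_prime is None else e_prime
    if gp < 2:
        return ep / 2.0
    return ep - gs.bounds[gp - 2]


@dataclass
class IonizationTransfer:
    """Moller transfer matrices for one element (cm^2 per atom).

    ``sigma_ee[l, gp, g]`` moves the surviving primary, ``sigma_ed`` books
    the delta ray; ``*_1`` are the outgoing-energy-weighted (m = 1)
    zeroth-Legendre variants; ``total``/``total_e1`` are the plain and
    incident-energy-weighted catastrophic totals; ``loss_cat`` is the mean
    catastrophic energy-loss rate (reduced energy x cm^2) used by the
    restricted stopping power.
    """

    gs: GroupStructure
    L: int
    Z: int
    sigma_ee: np.ndarray
    sigma_ed: np.ndarray
    sigma_ee1: np.ndarray
    sigma_ed1: np.ndarray
    total: np.ndarray
    total_e1: np.ndarray
    loss_cat: np.ndarray


def _ee_panel(ep, wp, lo, hi, L, out_l, out_1, width):
    """Accumulate the primary-electron (ee) panel integrals."""
    ee, we = panel_points(lo, hi, 16)
    epp = ep[..., None]
    kern = _moller_kernel(epp, epp - ee)   # delta energy = e' - e_e
    mu = np.sqrt(ee * (epp + 2.0) / (epp * (ee + 2.0)))
    pl = legendre_all(L, mu)
    base = we * kern
    out_l += np.einsum("p,lpq->l", wp, pl * base) / width
    out_1[0] += np.sum(wp[..., None] * base * ee) / width
    return out_l


def _ed_panel(ep, wp, lo, hi, L, out_l, out_1, width):
    """Accumulate the delta-ray (ed) panel integrals."""
    ed, we = panel_points(lo, hi, 16)
    epp = ep[..., None]
    kern = _moller_kernel(epp, ed)
    mu = np.sqrt(ed * (epp + 2.0) / (epp * (ed + 2.0)))
    pl = legendre_all(L, mu)
    base = we * kern
    out_l += np.einsum("p,lpq->l", wp, pl * base) / width
    out_1[0] += np.sum(wp[..., None] * base * ed) / width
    return out_l


def build_ionization_transfer(gs: GroupStructure, L: int, elem,
                              n_outer=16) -> IonizationTransfer:
    """Assemble both ionization channels for every incident group.

    The Legendre weight P_l is evaluated at the energy-dependent kinematic
    cosine of the *outgoing* particle inside the integral.  Values are per
    atom: the per-electron Moller kernel is scaled by Z.
    """
    elem = get_element(elem) if not isinstance(elem, ElementRecord) else elem
    if L < 0:
        raise ValueError("Legendre order must be >= 0")
    b = gs.bounds
    G = gs.G
    Z = elem.Z
    s_ee = np.zeros((L + 1, G, G))
    s_ed = np.zeros((L + 1, G, G))
    s_ee1 = np.zeros((G, G))
    s_ed1 = np.zeros((G, G))
    total = np.zeros(G)
    total_e1 = np.zeros(G)
    loss = np.zeros(G)

    cut = b[0]
    for gp in range(2, G):
        e_lo, e_hi = b[gp], b[gp + 1]
        width = e_hi - e_lo
        emax = b[gp - 2]          # highest surviving-primary energy

        # The catastrophic domain in delta energy is
        #   [max(e_c, cut), min(e'/2, e' - cut)]:
        # the delta must be producible (>= cutoff) and the surviving
        # primary must stay above the cutoff; events outside are soft.

        # --- ee channel: e_e in [max(b_g, e'/2), min(b_g+1, emax, e'-cut)]
        for g in range(0, gp - 2):
            hi_c = min(b[g + 1], emax)
            if hi_c <= b[g]:
                continue
            breaks = [2.0 * b[g], 2.0 * hi_c, b[g] + cut, hi_c + cut]
            for a_p, b_p in split_panels(e_lo, e_hi, breaks):
                ep, wp = panel_points(a_p, b_p, n_outer)
                lo = np.maximum(b[g], 0.5 * ep)
                hi = np.minimum(hi_c, ep - cut)
                hi = np.maximum(hi, lo)
                if np.all(hi <= lo):
                    continue
                acc1 = np.zeros(1)
                _ee_panel(ep, wp, lo, hi, L, s_ee[:, gp, g], acc1, width)
                s_ee1[gp, g] += acc1[0]

        # --- ed channel: e_d in [max(b_g, e_c), min(b_g+1, emax, e'/2,
        #     e' - cut)] ------------------------------------------------
        for g in range(0, gp):
            cap = min(b[g + 1], emax)
            if cap <= b[g]:
                continue
            breaks = [b[g] + emax, cap + emax, 2.0 * b[g], 2.0 * cap,
                      b[g] + cut, cap + cut, 2.0 * emax]
            for a_p, b_p in split_panels(e_lo, e_hi, breaks):
                ep, wp = panel_points(a_p, b_p, n_outer)
                lo = np.maximum(b[g], ep - emax)
                hi = np.minimum(np.minimum(cap, 0.5 * ep), ep - cut)
                hi = np.maximum(hi, lo)
                if np.all(hi <= lo):
                    continue
                acc1 = np.zeros(1)
                _ed_panel(ep, wp, lo, hi, L, s_ed[:, gp, g], acc1, width)
                s_ed1[gp, g] += acc1[0]

        # --- totals and catastrophic loss via closed-form inner integrals
        breaks = [2.0 * emax, emax + cut, 2.0 * cut]
        for a_p, b_p in split_panels(e_lo, e_hi, breaks):
            ep, wp = panel_points(a_p, b_p, 64)
            a = np.maximum(ep - emax, cut)
            bb = np.minimum(0.5 * ep, ep - cut)
            bb = np.maximum(bb, a)
            t0 = _moller_int0(ep, a, bb)
            t1 = _moller_int1(ep, a, bb)
            total[gp] += np.sum(wp * t0) / width
            total_e1[gp] += np.sum(wp * ep * t0) / width
            loss[gp] += np.sum(wp * t1) / width

    z = float(Z)
    return IonizationTransfer(gs=gs, L=L, Z=Z,
                              sigma_ee=s_ee * z, sigma_ed=s_ed * z,
                              sigma_ee1=s_ee1 * z, sigma_ed1=s_ed1 * z,
                              total=total * z, total_e1=total_e1 * z,
                              loss_cat=loss * z)
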