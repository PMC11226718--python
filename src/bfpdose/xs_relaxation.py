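"""Impact ionization of inner subshells and the relaxation cascade.

An inner-shell vacancy created by electron impact (Gryzinski cross
section) relaxes by a chain of Auger and fluorescence transitions; the
vacancy migrates outward one eligible subshell per step until it reaches
the outermost one.  Each step emits either an Auger electron (isotropic,
transported, energy e_b^j - 2 e_b^j') or a fluorescence photon (energy
e_b^j - e_b^j', bookkept only).  Emissions below the transport cutoff are
excluded, their energy remaining a local deposit.

Subshell eligibility follows the Z thresholds (K: Z>10, L1: Z>27, L2/L3:
Z>29, M: Z>51, N: Z>84, with e_b^N = 0).  At most 5 cascade subshells and
28 transition lines are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R0, velocity_beta
from .elements import ElementRecord, get_element
from .groups import GroupStructure
from .quadrature import panel_points

MAX_SUBSHELLS = 5
MAX_LINES = 28


def gryzinski_sigma(e_prime, e_b, cutoff=0.0):
    """Gryzinski impact-ionization cross section per subshell electron, cm^2.

    Vanishes for ``e' <= e_b`` through the cube-root threshold factor.
    A zero binding energy (N shell) is floored at the transport cutoff,
    the minimum energy transfer the chain can represent.
    """
    ep = np.asarray(e_prime, dtype=float)
    eb = max(float(e_b), float(cutoff), 1e-12)
    below = ep <= eb
    eps = np.where(below, 2.0 * eb, ep)      # safe dummy below threshold
    beta_e2 = (eps * (eps + 2.0)) / (eps + 1.0) ** 2
    beta_j2 = (eb * (eb + 2.0)) / (eb + 1.0) ** 2
    mix = np.cbrt(beta_e2 / (beta_e2 + beta_j2 - beta_e2 * beta_j2))
    log_term = 1.0 + (2.0 / 3.0) * (1.0 - eb / (2.0 * eps)) \
        * np.log(2.7 + np.sqrt(eps / eb - 1.0))
    thresh = np.cbrt(1.0 - eb / eps)
    val = np.pi * (R0 / eb) ** 2 * (beta_j2 / beta_e2) * mix \
        * log_term * thresh
    val = np.where(below, 0.0, val)
    return val if val.ndim else float(val)


def gryzinski_sigma_group(gs: GroupStructure, gp: int, e_b, cutoff=None,
                          n=16):
    """Flat-weighted group average of :func:`gryzinski_sigma` over group gp."""
    cut = gs.cutoff if cutoff is None else cutoff
    a, b = gs.bounds[gp], gs.bounds[gp + 1]
    ep, w = panel_points(a, b, n)
    return float(np.sum(w * gryzinski_sigma(ep, e_b, cut)) / (b - a))


@dataclass(frozen=True)
class CascadeLine:
    shell: str          # ionized subshell starting the chain step
    kind: str           # 'auger' | 'fluor'
    energy: float       # emitted particle energy, reduced units
    efficiency: float   # probability of this emission per initial vacancy


@dataclass
class CascadeModel:
    """Enumerated relaxation cascade for one element.

    ``lines[j]`` lists the emissions that can follow a vacancy in cascade
    subshell ``j``; ``paths[j]`` the terminal path probabilities (they sum
    to 1 whenever a cascade exists).
    """

    Z: int
    shells: tuple = ()                  # cascade-initiating subshell labels
    lines: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.shells

    @property
    def n_lines(self) -> int:
        return sum(len(v) for v in self.lines.values())


def _shell_yield(elem: ElementRecord, label: str) -> float:
    if label == "K":
        return elem.fluor_yield_K
    if label.startswith("L"):
        return elem.fluor_yield_L
    return 0.0


def cascade_lines(elem) -> CascadeModel:
    """Enumerate the relaxation cascade by replicating de-excitations.

    The vacancy chain is deterministic in position (it moves to the next
    eligible subshell at every step); each step branches between an Auger
    and a fluorescence emission, so every complete path's probability is
    the product of its branch probabilities and the terminal-state
    probabilities close to 1 exactly.
    """
    elem = get_element(elem) if not isinstance(elem, ElementRecord) else elem
    if not elem.has_relaxation_data or len(elem.subshells) < 2:
        return CascadeModel(Z=elem.Z)
    labels = [s.label for s in elem.subshells]
    binding = {s.label: s.binding for s in elem.subshells}
    starters = labels[:-1]               # outermost shell cannot cascade
    if len(starters) > MAX_SUBSHELLS:
        raise ValueError(f"more than {MAX_SUBSHELLS} cascade subshells")
    model = CascadeModel(Z=elem.Z, shells=tuple(starters))
    for j0, start in enumerate(starters):
        lines = []
        # walk the chain from `start` to the outermost subshell
        reach_prob = 1.0
        for step in range(j0, len(labels) - 1):
            j, jn = labels[step], labels[step + 1]
            w_f = _shell_yield(elem, j)
            e_f = binding[j] - binding[jn]
            e_a = max(binding[j] - 2.0 * binding[jn], 0.0)
            if w_f > 0:
                lines.append(CascadeLine(j, "fluor", e_f, reach_prob * w_f))
            lines.append(CascadeLine(j, "auger", e_a,
                                     reach_prob * (1.0 - w_f)))
            # both branches move the vacancy to jn: reach prob unchanged
        model.lines[start] = lines
        model.paths[start] = _terminal_paths(elem, labels, j0)
    if model.n_lines > MAX_LINES:
        raise ValueError(f"more than {MAX_LINES} transition lines")
    return model


def _terminal_paths(elem, labels, j0):
    """Probabilities of the complete branch-choice paths from shell j0."""
    probs = [1.0]
    for step in range(j0, len(labels) - 1):
        w_f = _shell_yield(elem, labels[step])
        new = []
        for p in probs:
            if w_f > 0:
                new.append(p * w_f)
            new.append(p * (1.0 - w_f))
        probs = new
    return np.asarray(probs)


@dataclass
class RelaxationTransfer:
    """Auger production matrix and energy bookkeeping (cm^2 per atom).

    Only the zeroth Legendre block exists: Auger emission is isotropic.
    ``sigma_a[gp, g]`` produces an Auger electron in group g per unit flux
    in group gp; ``auger_e1`` is its energy first moment; ``fluor_energy``
    and ``subcut_energy`` book fluorescence photons and below-cutoff
    emissions (reduced energy x cm^2).
    """

    gs: GroupStructure
    Z: int
    sigma_a: np.ndarray
    auger_e1: np.ndarray
    fluor_energy: np.ndarray
    subcut_energy: np.ndarray


def build_relaxation_transfer(gs: GroupStructure, elem,
                              cascade: CascadeModel | None = None
                              ) -> RelaxationTransfer:
    """Bin cascade emissions into energy groups.

    A line on an exact group boundary goes to the lower group; lines below
    the lowest boundary are excluded from transport and their energy kept
    as a local deposit.
    """
    elem = get_element(elem) if not isinstance(elem, ElementRecord) else elem
    model = cascade_lines(elem) if cascade is None else cascade
    G = gs.G
    sigma_a = np.zeros((G, G))
    auger_e1 = np.zeros(G)
    fluor_e = np.zeros(G)
    subcut = np.zeros(G)
    if model.empty:
        return RelaxationTransfer(gs, elem.Z, sigma_a, auger_e1,
                                  fluor_e, subcut)
    occ = {s.label: s.occupancy for s in elem.subshells}
    binding = {s.label: s.binding for s in elem.subshells}
    for start in model.shells:
        lines = model.lines[start]
        for gp in range(G):
            sig_j = occ[start] * gryzinski_sigma_group(
                gs, gp, binding[start])
            if sig_j == 0.0:
                continue
            for ln in lines:
                contrib = ln.efficiency * sig_j
                if ln.kind == "fluor":
                    fluor_e[gp] += contrib * ln.energy
                    continue
                if ln.energy < gs.cutoff:
                    subcut[gp] += contrib * ln.energy
                    continue
                gk = gs.group_of(ln.energy)
                sigma_a[gp, gk] += contrib
                auger_e1[gp] += contrib * ln.energy
    return RelaxationTransfer(gs, elem.Z, sigma_a, auger_e1, fluor_e, subcut)
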