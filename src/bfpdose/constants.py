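"""Physical constants and reduced-unit conversions.

Throughout the package electron kinetic energies are carried in *reduced
units*, i.e. in multiples of the electron rest energy m_e c^2.  All cross
sections are microscopic (cm^2 per atom) unless a function name says
"macroscopic"; lengths are cm, mass stopping powers MeV cm^2/g.
"""

from __future__ import annotations

import numpy as np

#: electron rest energy, MeV (CODATA 2018)
MEC2 = 0.51099895000
#: classical electron radius, cm
R0 = 2.8179403262e-13
#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23
#: fine-structure constant
ALPHA = 1.0 / 137.035999084
#: barns per cm^2
CM2_PER_BARN = 1.0e-24
#: default transport cutoff (lowest group boundary), MeV
DEFAULT_CUTOFF_MEV = 1.0e-3

# 2 pi r0^2 N_A m_e c^2  -- the Berger-Seltzer collisional prefactor,
# MeV cm^2 mol/g when multiplied by Z/A (g/mol)^-1.
COL_PREFACTOR = 2.0 * np.pi * R0 ** 2 * N_AVOGADRO * MEC2


def reduced_energy(energy_mev):
    """Convert kinetic energy in MeV to reduced units e = E / m_e c^2.

    Raises ``ValueError`` for negative input.  Vectorised.
    """
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e < 0):
        raise ValueError("kinetic energy must be non-negative")
    out = e / MEC2
    return out if out.ndim else float(out)


def energy_mev(e_reduced):
    """Inverse of :func:`reduced_energy`."""
    e = np.asarray(e_reduced, dtype=float)
    if np.any(e < 0):
        raise ValueError("reduced energy must be non-negative")
    out = e * MEC2
    return out if out.ndim else float(out)


def velocity_beta(e):
    """Electron speed in units of c for reduced kinetic energy ``e``.

    beta = sqrt(e (e + 2)) / (e + 1); zero at rest, monotone, < 1.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("reduced energy must be non-negative")
    out = np.sqrt(e * (e + 2.0)) / (e + 1.0)
    return out if out.ndim else float(out)


def momentum(e):
    """Electron momentum in m_e c units: p = sqrt(e (e + 2))."""
    e = np.asarray(e, dtype=float)
    out = np.sqrt(e * (e + 2.0))
    return out if out.ndim else float(out)
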