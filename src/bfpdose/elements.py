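"""Element data: atomic masses, mean excitation energies, subshell structure.

The embedded tables cover the elements appearing in the bundled benchmark
phantoms (plus a few common extras).  Mean excitation energies I follow the
ICRU-37 recommendations; atomic masses are standard atomic weights; the
default densities are those of the element in its common condensed (or,
for gases, NTP) state and are used when an element is irradiated as a pure
slab.

Subshell binding energies and fluorescence yields are a compact set of
approximate reference values (keV-resolution X-ray data tables); they drive
the impact-ionisation/relaxation channel, which is a small correction to
the dose at very high energy.  Everything here can be overridden at run
time (:func:`register_element`, :meth:`ElementRecord.replace`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .constants import MEC2

# Z: (symbol, A [g/mol], I [eV], default density [g/cm^3])
_ELEMENT_TABLE = {
    1:  ("H",  1.008,    19.2, 8.375e-5),
    2:  ("He", 4.0026,   41.8, 1.663e-4),
    3:  ("Li", 6.941,    40.0, 0.534),
    5:  ("B",  10.811,   76.0, 2.370),
    6:  ("C",  12.011,   78.0, 2.000),
    7:  ("N",  14.007,   82.0, 1.165e-3),
    8:  ("O",  15.999,   95.0, 1.332e-3),
    11: ("Na", 22.990,  149.0, 0.971),
    12: ("Mg", 24.305,  156.0, 1.740),
    13: ("Al", 26.982,  166.0, 2.699),
    14: ("Si", 28.086,  173.0, 2.330),
    15: ("P",  30.974,  173.0, 2.200),
    16: ("S",  32.065,  180.0, 2.070),
    17: ("Cl", 35.453,  174.0, 2.995e-3),
    18: ("Ar", 39.948,  188.0, 1.662e-3),
    19: ("K",  39.098,  190.0, 0.862),
    20: ("Ca", 40.078,  191.0, 1.550),
    22: ("Ti", 47.867,  233.0, 4.540),
    23: ("V",  50.942,  245.0, 6.110),
    24: ("Cr", 51.996,  257.0, 7.180),
    25: ("Mn", 54.938,  272.0, 7.440),
    26: ("Fe", 55.845,  286.0, 7.874),
    28: ("Ni", 58.693,  311.0, 8.902),
    29: ("Cu", 63.546,  322.0, 8.960),
    30: ("Zn", 65.380,  330.0, 7.133),
    33: ("As", 74.922,  347.0, 5.730),
    34: ("Se", 78.960,  348.0, 4.500),
    39: ("Y",  88.906,  379.0, 4.469),
    40: ("Zr", 91.224,  393.0, 6.506),
    41: ("Nb", 92.906,  417.0, 8.570),
    42: ("Mo", 95.960,  424.0, 10.220),
    46: ("Pd", 106.42,  470.0, 12.020),
    49: ("In", 114.818, 488.0, 7.310),
    50: ("Sn", 118.710, 488.0, 7.310),
    62: ("Sm", 150.36,  574.0, 7.520),
    70: ("Yb", 173.04,  684.0, 6.900),
    74: ("W",  183.84,  727.0, 19.300),
    79: ("Au", 196.967, 790.0, 19.320),
    82: ("Pb", 207.20,  823.0, 11.350),
    87: ("Fr", 223.00,  827.0, 1.870),
}

_SYMBOL_TO_Z = {sym: z for z, (sym, _, _, _) in _ELEMENT_TABLE.items()}

# Approximate subshell binding energies, keV: Z -> (K, L1, L2, L3, M1).
# Only needed for elements eligible for relaxation cascades (Z > 10).
_BINDING_KEV = {
    11: (1.072, 0.063, 0.031, 0.031, 0.0),
    12: (1.305, 0.089, 0.051, 0.051, 0.0),
    13: (1.560, 0.118, 0.073, 0.072, 0.0),
    14: (1.839, 0.149, 0.100, 0.099, 0.0),
    15: (2.146, 0.189, 0.136, 0.135, 0.0),
    16: (2.472, 0.231, 0.163, 0.162, 0.0),
    17: (2.822, 0.270, 0.202, 0.200, 0.0),
    19: (3.608, 0.377, 0.297, 0.295, 0.0),
    20: (4.038, 0.438, 0.350, 0.346, 0.0),
    22: (4.966, 0.561, 0.460, 0.454, 0.0),
    23: (5.465, 0.627, 0.520, 0.513, 0.0),
    24: (5.989, 0.696, 0.584, 0.575, 0.0),
    25: (6.539, 0.769, 0.650, 0.639, 0.0),
    26: (7.112, 0.845, 0.720, 0.707, 0.0),
    28: (8.333, 1.008, 0.870, 0.853, 0.0),
    29: (8.979, 1.096, 0.953, 0.933, 0.074),
    30: (9.659, 1.196, 1.045, 1.022, 0.101),
    33: (11.867, 1.527, 1.359, 1.323, 0.188),
    34: (12.658, 1.652, 1.476, 1.436, 0.232),
    39: (17.038, 2.373, 2.156, 2.080, 0.392),
    40: (17.998, 2.532, 2.307, 2.223, 0.430),
    41: (18.986, 2.698, 2.465, 2.371, 0.466),
    42: (20.000, 2.866, 2.625, 2.520, 0.506),
    46: (24.350, 3.604, 3.330, 3.173, 0.670),
    49: (27.940, 4.238, 3.938, 3.730, 0.827),
    50: (29.200, 4.465, 4.156, 3.929, 0.884),
    62: (46.834, 7.737, 7.312, 6.716, 1.723),
    70: (61.332, 10.486, 9.978, 8.944, 2.398),
    74: (69.525, 12.100, 11.544, 10.207, 2.820),
    79: (80.725, 14.353, 13.734, 11.919, 3.425),
    82: (88.005, 15.861, 15.200, 13.035, 3.851),
    87: (101.137, 18.639, 17.907, 14.975, 4.652),
}

# Approximate K- and mean L-shell fluorescence yields.
_FLUOR_YIELD = {
    11: (0.023, 0.0), 12: (0.030, 0.0), 13: (0.039, 0.0), 14: (0.050, 0.0),
    15: (0.063, 0.0), 16: (0.078, 0.0), 17: (0.097, 0.0), 19: (0.140, 0.0),
    20: (0.163, 0.0), 22: (0.214, 0.0), 23: (0.243, 0.0), 24: (0.275, 0.0),
    25: (0.308, 0.0), 26: (0.340, 0.001), 28: (0.406, 0.001),
    29: (0.440, 0.002), 30: (0.474, 0.003), 33: (0.562, 0.005),
    34: (0.589, 0.006), 39: (0.710, 0.015), 40: (0.730, 0.017),
    41: (0.747, 0.020), 42: (0.764, 0.023), 46: (0.820, 0.035),
    49: (0.853, 0.050), 50: (0.860, 0.055), 62: (0.917, 0.135),
    70: (0.939, 0.200), 74: (0.945, 0.255), 79: (0.960, 0.320),
    82: (0.965, 0.360), 87: (0.970, 0.420),
}

#: subshell label -> minimum Z for cascade eligibility
SUBSHELL_Z_THRESHOLD = {"K": 10, "L1": 27, "L2": 29, "L3": 29, "M": 51, "N": 84}
_SUBSHELL_ORDER = ("K", "L1", "L2", "L3", "M", "N")


@dataclass(frozen=True)
class Subshell:
    label: str
    binding: float      # binding energy, reduced units
    occupancy: float    # number of electrons


@dataclass(frozen=True)
class ElementRecord:
    """One element: identity, dosimetric constants and subshell structure.

    ``subshells`` is ordered K -> N with strictly decreasing binding
    energies; an N shell, when eligible, carries a binding energy of
    exactly zero.  ``fluor_yield_K``/``fluor_yield_L`` are the per-vacancy
    fluorescence efficiencies (the Auger efficiency is the complement).
    """

    Z: int
    symbol: str
    A: float            # g/mol
    I_eV: float         # mean excitation energy
    density: float      # default density, g/cm^3
    subshells: tuple = ()
    fluor_yield_K: float = 0.0
    fluor_yield_L: float = 0.0

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError("Z must be >= 1")
        eb = [s.binding for s in self.subshells]
        if any(b < 0 for b in eb):
            raise ValueError("binding energies must be non-negative")
        if any(b1 <= b2 for b1, b2 in zip(eb, eb[1:]) if b2 > 0):
            raise ValueError("binding energies must decrease K -> N")

    @property
    def has_relaxation_data(self) -> bool:
        return len(self.subshells) > 0

    def subshell(self, label: str) -> Optional[Subshell]:
        for s in self.subshells:
            if s.label == label:
                return s
        return None

    def replace(self, **kwargs) -> "ElementRecord":
        return replace(self, **kwargs)


def _occupancy(z: int, label: str) -> float:
    if label == "K":
        return min(2, z)
    if label == "L1":
        return min(2, max(0, z - 2))
    if label == "L2":
        return min(2, max(0, z - 4))
    if label == "L3":
        return min(4, max(0, z - 6))
    if label == "M":
        return min(18, max(0, z - 10))
    if label == "N":
        return max(0, z - 28)
    raise KeyError(label)


def _build_subshells(z: int):
    if z not in _BINDING_KEV:
        return ()
    kev = dict(zip(("K", "L1", "L2", "L3", "M"), _BINDING_KEV[z]))
    kev["N"] = 0.0
    shells = []
    for label in _SUBSHELL_ORDER:
        if z > SUBSHELL_Z_THRESHOLD[label]:
            shells.append(
                Subshell(label, kev[label] * 1e-3 / MEC2, _occupancy(z, label))
            )
    return tuple(shells)


_REGISTRY: dict = {}


def get_element(key) -> ElementRecord:
    """Look an element up by atomic number or symbol."""
    z = _SYMBOL_TO_Z.get(key, key) if isinstance(key, str) else key
    if not isinstance(z, int) or z not in _ELEMENT_TABLE:
        raise KeyError(f"no embedded data for element {key!r}")
    if z not in _REGISTRY:
        sym, a, i_ev, rho = _ELEMENT_TABLE[z]
        wk, wl = _FLUOR_YIELD.get(z, (0.0, 0.0))
        _REGISTRY[z] = ElementRecord(
            Z=z, symbol=sym, A=a, I_eV=i_ev, density=rho,
            subshells=_build_subshells(z),
            fluor_yield_K=wk, fluor_yield_L=wl,
        )
    return _REGISTRY[z]


def register_element(record: ElementRecord) -> None:
    """Install or override an element record (takes precedence thereafter)."""
    _ELEMENT_TABLE.setdefault(record.Z, (record.symbol, record.A,
                                         record.I_eV, record.density))
    _SYMBOL_TO_Z[record.symbol] = record.Z
    _REGISTRY[record.Z] = record


def known_elements():
    return sorted(_ELEMENT_TABLE)
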