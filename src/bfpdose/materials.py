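"""Materials: composition, density, effective dosimetric constants.

A :class:`MaterialSpec` is a mass-fraction mixture of elements with a bulk
density.  The mean excitation energy of a compound follows the Bragg
additivity rule on ln I weighted by electron fraction, unless overridden.
Standard ICRU-44 body tissues, water and the metals used by the bundled
phantoms are predefined; arbitrary materials can be loaded from a YAML
mapping (``load_materials``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .constants import N_AVOGADRO
from .elements import ElementRecord, get_element

_FRACTION_TOL = 1e-12


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    constituents: tuple          # ((ElementRecord, mass fraction), ...)
    density: float               # g/cm^3
    I_override_eV: float | None = None

    def __post_init__(self):
        total = sum(w for _, w in self.constituents)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, not 1"
            )
        if self.density <= 0:
            raise ValueError("density must be positive")
        # renormalise tiny rounding residue so invariants hold exactly
        if abs(total - 1.0) > _FRACTION_TOL:
            object.__setattr__(
                self, "constituents",
                tuple((el, w / total) for el, w in self.constituents),
            )

    @property
    def z_over_a(self) -> float:
        """Mean Z/A, mol/g (electron density per gram / N_A)."""
        return sum(w * el.Z / el.A for el, w in self.constituents)

    @property
    def I_eV(self) -> float:
        if self.I_override_eV is not None:
            return self.I_override_eV
        num = sum(w * el.Z / el.A * math.log(el.I_eV)
                  for el, w in self.constituents)
        return math.exp(num / self.z_over_a)

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3."""
        return self.density * self.z_over_a * N_AVOGADRO

    def number_densities(self):
        """Atoms per cm^3 for each constituent element."""
        return [(el, self.density * w * N_AVOGADRO / el.A)
                for el, w in self.constituents]

    def scaled_density(self, factor: float) -> "MaterialSpec":
        return MaterialSpec(self.name, self.constituents,
                            self.density * factor, self.I_override_eV)


def material(name, composition, density, I_eV=None) -> MaterialSpec:
    """Build a material from ``{symbol_or_Z: mass fraction}``."""
    cons = tuple((get_element(k), float(w)) for k, w in composition.items())
    return MaterialSpec(name, cons, float(density), I_eV)


def element_material(key, density=None) -> MaterialSpec:
    """A pure single-element material (density defaults to the element's)."""
    el = get_element(key)
    rho = el.density if density is None else density
    return MaterialSpec(el.symbol, ((el, 1.0),), rho)


# --- predefined materials ------------------------------------------------
# Body tissues: ICRU-44 compositions. "tumor" is modelled as soft tissue at
# a slightly elevated density, "steel" as AISI-304 stainless.

_PREDEFINED = {
    "water": ({"H": 0.111894, "O": 0.888106}, 1.000, 75.0),
    "tissue": ({"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                "K": 0.003}, 1.060, None),
    "muscle": ({"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710,
                "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001,
                "K": 0.004}, 1.050, None),
    "bone": ({"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
              "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
              "Ca": 0.225}, 1.920, None),
    "lung": ({"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
              "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003,
              "K": 0.002}, 0.260, None),
    "adipose": ({"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
                 "Na": 0.001, "S": 0.001, "Cl": 0.001}, 0.950, None),
    "tumor": ({"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
               "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
               "K": 0.003}, 1.040, None),
    "aluminum": ({"Al": 1.0}, 2.699, None),
    "steel": ({"Fe": 0.695, "Cr": 0.190, "Ni": 0.095, "Mn": 0.020},
              8.000, None),
}

_CACHE: dict = {}


def get_material(name) -> MaterialSpec:
    """Fetch a predefined material (or pass a MaterialSpec through)."""
    if isinstance(name, MaterialSpec):
        return name
    key = name.lower()
    if key == "aluminium":
        key = "aluminum"
    if key not in _PREDEFINED:
        try:
            return element_material(name)
        except KeyError:
            raise KeyError(f"unknown material {name!r}") from None
    if key not in _CACHE:
        comp, rho, i_ev = _PREDEFINED[key]
        _CACHE[key] = material(key, comp, rho, i_ev)
    return _CACHE[key]


def load_materials(path) -> dict:
    """Read a YAML materials file.

    Expected layout::

        materials:
          mymat: {composition: {H: 0.112, O: 0.888}, density: 1.0, I_eV: 75}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for name, spec in (doc.get("materials") or {}).items():
        out[name] = material(name, spec["composition"], spec["density"],
                             spec.get("I_eV"))
    return out
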