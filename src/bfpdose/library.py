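"""Assembly of per-material macroscopic multigroup libraries.

For each constituent element the microscopic channel builders produce
transfer matrices per atom; number-density weighting (N_i = rho w_i N_A /
A_i) turns them into macroscopic quantities (cm^-1).  The library then
carries everything the slab solver needs:

* ``sigma_t`` -- total catastrophic cross section: outflow of the
  ionization (primary) and bremsstrahlung channels plus the
  transport-corrected within-group elastic P0 moment.  Delta-ray and
  Auger production redistribute without removing the primary and are
  excluded from the total.
* ``transfer`` -- combined Legendre-resolved scattering/production
  matrices (ionization both channels, bremsstrahlung, isotropic Auger,
  within-group elastic).
* ``beta_c``/``beta_r`` -- soft (restricted) stopping powers: analytic
  totals at group midpoints minus the catastrophic first-moment loss of
  the same DDCS assemblies, guaranteeing soft + catastrophic = total.
* ``edep`` -- electron energy-deposition cross section (MeV/cm per unit
  group flux): soft collisional deposit plus catastrophic bookkeeping
  residuals minus energy exported by Auger electrons and photons.  The
  as-printed variant including radiative terms as local deposit is kept
  in ``edep_total``.
* ``photon_prod`` -- radiative + fluorescence energy emission rate,
  tallied (not transported): photons are eliminated at birth.

The on-disk container is a single HDF5 file with a versioned schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import MEC2, N_AVOGADRO
from .groups import GroupStructure
from .materials import MaterialSpec, get_material
from .stopping import stopping_model
from .xs_bremsstrahlung import build_brems_transfer
from .xs_elastic import build_elastic_moments
from .xs_ionization import build_ionization_transfer
from .xs_relaxation import build_relaxation_transfer

SCHEMA_VERSION = 1
ALL_CHANNELS = ("ionization", "brems", "elastic", "relaxation")


@dataclass
class MultigroupLibrary:
    gs: GroupStructure
    L: int
    name: str
    density: float
    sigma_t: np.ndarray          # (G,) cm^-1
    transfer: np.ndarray         # (L+1, G, G) cm^-1, combined channels
    channels: dict               # per-channel l=0 matrices, (G, G) cm^-1
    elastic_bar: np.ndarray      # (L+1, G) cm^-1, transport-corrected
    beta_c: np.ndarray           # (G,) MeV/cm
    beta_r: np.ndarray           # (G,) MeV/cm
    beta_bnd: np.ndarray         # (G+1,) MeV/cm
    alpha: np.ndarray            # (G,) cm^-1
    edep: np.ndarray             # (G,) MeV/cm
    edep_total: np.ndarray       # (G,) MeV/cm (as-printed variant)
    photon_prod: np.ndarray      # (G,) MeV/cm
    meta: dict = field(default_factory=dict)

    @property
    def delta_e_mev(self) -> np.ndarray:
        return self.gs.widths * MEC2


def mix_macroscopic(micro_per_element: dict, mat: MaterialSpec):
    """Number-density weighting of per-atom arrays: Sigma = sum_i N_i sigma_i.

    ``micro_per_element`` maps element symbols to arrays in cm^2.
    """
    mat = get_material(mat)
    out = None
    seen = set()
    for el, ndens in mat.number_densities():
        if el.symbol not in micro_per_element:
            raise KeyError(f"no microscopic data for element {el.symbol}")
        seen.add(el.symbol)
        arr = np.asarray(micro_per_element[el.symbol], dtype=float)
        out = ndens * arr if out is None else out + ndens * arr
    extra = set(micro_per_element) - seen
    if extra:
        raise KeyError(f"elements {sorted(extra)} not in material")
    return out


def total_xs(channels: dict, elastic_bar0: np.ndarray) -> np.ndarray:
    """Total catastrophic cross section: channel-sum identity.

    Outflow of the surviving-primary ionization and bremsstrahlung
    channels plus the within-group (transport-corrected) elastic P0
    moment; delta-ray and Auger production do not remove the primary.
    """
    return (channels["ee"].sum(axis=1) + channels["brems"].sum(axis=1)
            + elastic_bar0)


def soft_stopping_powers(gs, mat, loss_cat_col, loss_cat_rad, model=None):
    """Restricted soft stopping powers at group midpoints, MeV/cm.

    beta_g = beta_total(midpoint) - catastrophic first-moment loss; a
    negative result beyond tolerance signals an inconsistent DDCS/total
    pair and raises.
    """
    mat = get_material(mat)
    m = model or stopping_model(mat, e_max_mev=max(
        2.0 * gs.bounds_mev[-1], 10.0))
    mids = gs.midpoints_mev
    bt_c = m.collisional(mids) * mat.density
    bt_r = m.radiative(mids) * mat.density
    beta_c = bt_c - loss_cat_col
    beta_r = bt_r - loss_cat_rad
    for name, arr, tot in (("collisional", beta_c, bt_c),
                           ("radiative", beta_r, bt_r)):
        bad = arr < -1e-10 * np.maximum(tot, 1e-300)
        if np.any(bad):
            g = int(np.argmax(bad))
            raise ValueError(
                f"negative soft {name} stopping power in group {g}: "
                f"{arr[g]:.3e} of total {tot[g]:.3e}")
    return np.maximum(beta_c, 0.0), np.maximum(beta_r, 0.0)


def _boundary_interp(gs: GroupStructure, beta_mid: np.ndarray) -> np.ndarray:
    """Log-log interpolation of midpoint values onto group boundaries."""
    lx = np.log(gs.midpoints)
    ly = np.log(np.maximum(beta_mid, 1e-300))
    return np.exp(np.interp(np.log(gs.bounds), lx, ly))


def energy_deposition_xs(channels_e1: dict, beta_c, beta_r,
                         mode="electron"):
    """Energy-deposition cross section per group, MeV/cm per unit flux.

    ``mode='electron'``: local deposit only -- soft collisional loss plus
    the catastrophic residuals (incident minus exported electron/photon
    energy, zero up to quadrature) minus energy exported by Auger
    electrons and fluorescence photons.  Photon energy is tallied, not
    deposited.

    ``mode='total'``: the as-printed four-term variant that treats all
    radiative losses as local deposit and adds the Auger first moment.
    """
    res_i = (channels_e1["ee_total"] - channels_e1["ee_out"]
             - channels_e1["ed_out"])
    res_b_e = (channels_e1["b_total"] - channels_e1["b_out"]
               - channels_e1["b_photon"])
    if mode == "electron":
        out = (beta_c + res_i + res_b_e
               - channels_e1["auger"] - channels_e1["fluor"])
    elif mode == "total":
        out = (beta_c + beta_r + res_i
               + (channels_e1["b_total"] - channels_e1["b_out"])
               + channels_e1["auger"])
    else:
        raise ValueError(f"unknown deposition mode {mode!r}")
    return out


def build_library(mat, gs: GroupStructure, L: int,
                  channels=ALL_CHANNELS, alpha_mode="zero",
                  n_outer=16, nu_e=1.0) -> MultigroupLibrary:
    """Assemble the macroscopic multigroup library for one material.

    ``channels`` selects the catastrophic channels; dropping them all
    yields a pure continuous-slowing-down library (beta equals the total
    stopping power and the deposition reduces to beta_c).
    ``alpha_mode='fokker-planck'`` moves elastic scattering into the
    angular Fokker-Planck operator (alpha_g = 2 G_1) instead of the
    Boltzmann kernel.
    """
    mat = get_material(mat)
    G = gs.G
    zeros_gg = np.zeros((G, G))
    acc = {k: zeros_gg.copy() for k in ("ee", "ed", "brems", "auger")}
    transfer = np.zeros((L + 1, G, G))
    elastic_bar = np.zeros((L + 1, G))
    g1_macro = np.zeros(G)
    e1 = {k: np.zeros(G) for k in ("ee_total", "ee_out", "ed_out",
                                   "b_total", "b_out", "b_photon",
                                   "auger", "fluor")}
    loss_col = np.zeros(G)
    loss_rad = np.zeros(G)

    for el, ndens in mat.number_densities():
        if "ionization" in channels:
            ion = build_ionization_transfer(gs, L, el, n_outer=n_outer)
            acc["ee"] += ndens * ion.sigma_ee[0]
            acc["ed"] += ndens * ion.sigma_ed[0]
            transfer += ndens * (ion.sigma_ee + ion.sigma_ed)
            e1["ee_total"] += ndens * ion.total_e1 * MEC2
            e1["ee_out"] += ndens * ion.sigma_ee1.sum(axis=1) * MEC2
            e1["ed_out"] += ndens * ion.sigma_ed1.sum(axis=1) * MEC2
            loss_col += ndens * ion.loss_cat * MEC2
        if "brems" in channels:
            br = build_brems_transfer(gs, L, el, n_outer=n_outer)
            acc["brems"] += ndens * br.sigma0
            transfer += ndens * br.sigma0[None, :, :]
            e1["b_total"] += ndens * br.total_e1 * MEC2
            e1["b_out"] += ndens * br.sigma1_out.sum(axis=1) * MEC2
            e1["b_photon"] += ndens * br.photon_energy * MEC2
            loss_rad += ndens * br.photon_energy * MEC2
        if "elastic" in channels:
            em = build_elastic_moments(gs, L, el, nu_e=nu_e)
            if alpha_mode == "fokker-planck":
                g1_macro += ndens * em.g_moments[1] if L >= 1 else 0.0
            else:
                elastic_bar += ndens * em.sigma_bar
        if "relaxation" in channels:
            rx = build_relaxation_transfer(gs, el)
            acc["auger"] += ndens * rx.sigma_a
            transfer[0] += ndens * rx.sigma_a
            e1["auger"] += ndens * rx.auger_e1 * MEC2
            e1["fluor"] += ndens * rx.fluor_energy * MEC2

    # within-group elastic goes on the transfer diagonal
    for l in range(L + 1):
        transfer[l] += np.diag(elastic_bar[l])

    sigma_t = total_xs(acc, elastic_bar[0])
    beta_c, beta_r = soft_stopping_powers(gs, mat, loss_col, loss_rad)
    beta_bnd = _boundary_interp(gs, beta_c + beta_r)
    edep = energy_deposition_xs(e1, beta_c, beta_r, mode="electron")
    edep_total = energy_deposition_xs(e1, beta_c, beta_r, mode="total")
    photon_prod = beta_r + e1["b_photon"] + e1["fluor"]
    alpha = 2.0 * g1_macro if alpha_mode == "fokker-planck" else np.zeros(G)

    meta = {
        "elements": [el.symbol for el, _ in mat.constituents],
        "fractions": [w for _, w in mat.constituents],
        "channels": list(channels),
        "alpha_mode": alpha_mode,
        "first_moments": e1,
    }
    return MultigroupLibrary(
        gs=gs, L=L, name=mat.name, density=mat.density,
        sigma_t=sigma_t, transfer=transfer, channels=acc,
        elastic_bar=elastic_bar, beta_c=beta_c, beta_r=beta_r,
        beta_bnd=beta_bnd, alpha=alpha, edep=edep, edep_total=edep_total,
        photon_prod=photon_prod, meta=meta)


# ---------------------------------------------------------------- container

def write_library(lib: MultigroupLibrary, path) -> None:
    """Write the library to a self-describing versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["name"] = lib.name
        f.attrs["density"] = lib.density
        f.attrs["L"] = lib.L
        f.attrs["elements"] = ",".join(lib.meta.get("elements", []))
        f.attrs["fractions"] = lib.meta.get("fractions", [])
        f.attrs["channels_built"] = ",".join(lib.meta.get("channels", []))
        f.attrs["alpha_mode"] = lib.meta.get("alpha_mode", "zero")
        f["group_bounds"] = lib.gs.bounds
        for key in ("sigma_t", "transfer", "elastic_bar", "beta_c",
                    "beta_r", "beta_bnd", "alpha", "edep", "edep_total",
                    "photon_prod"):
            f[key] = getattr(lib, key)
        ch = f.create_group("channels")
        for k, v in lib.channels.items():
            ch[k] = v
        e1g = f.create_group("first_moments")
        for k, v in lib.meta.get("first_moments", {}).items():
            e1g[k] = v


def read_library(path) -> MultigroupLibrary:
    """Read a container written by :func:`write_library` (lossless)."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version > SCHEMA_VERSION:
            raise ValueError(
                f"library schema version {version} is newer than "
                f"supported version {SCHEMA_VERSION}")
        gs = GroupStructure(f["group_bounds"][...])
        meta = {
            "elements": [s for s in str(f.attrs["elements"]).split(",") if s],
            "fractions": list(f.attrs["fractions"]),
            "channels": [s for s in
                         str(f.attrs["channels_built"]).split(",") if s],
            "alpha_mode": str(f.attrs["alpha_mode"]),
            "first_moments": {k: v[...] for k, v
                              in f["first_moments"].items()},
        }
        return MultigroupLibrary(
            gs=gs, L=int(f.attrs["L"]), name=str(f.attrs["name"]),
            density=float(f.attrs["density"]),
            sigma_t=f["sigma_t"][...], transfer=f["transfer"][...],
            channels={k: v[...] for k, v in f["channels"].items()},
            elastic_bar=f["elastic_bar"][...],
            beta_c=f["beta_c"][...], beta_r=f["beta_r"][...],
            beta_bnd=f["beta_bnd"][...], alpha=f["alpha"][...],
            edep=f["edep"][...], edep_total=f["edep_total"][...],
            photon_prod=f["photon_prod"][...], meta=meta)
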