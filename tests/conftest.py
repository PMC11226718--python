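import numpy as np
import pytest

import bfpdose as bd


@pytest.fixture(scope="session")
def gs30():
    """Coarse 30-group structure, 1 keV - 10 MeV."""
    return bd.build_group_structure(30, e_max_mev=10.0)


@pytest.fixture(scope="session")
def gs60():
    """60-group structure up to 100 MeV (VHEE scale)."""
    return bd.build_group_structure(60, e_max_mev=100.0)


@pytest.fixture(scope="session")
def water():
    return bd.get_material("water")


@pytest.fixture(scope="session")
def water_lib30(gs30):
    return bd.build_library("water", gs30, 7)


@pytest.fixture(scope="session")
def oxygen_ion30(gs30):
    return bd.build_ionization_transfer(gs30, 7, "O")


@pytest.fixture(scope="session")
def oxygen_brems30(gs30):
    return bd.build_brems_transfer(gs30, 7, "O")


def absorber_library(gs, sigma_t=1.0, L=1):
    """Synthetic pure-absorber library: no scattering, no slowing down."""
    G = gs.G
    return bd.MultigroupLibrary(
        gs=gs, L=L, name="absorber", density=1.0,
        sigma_t=np.full(G, sigma_t),
        transfer=np.zeros((L + 1, G, G)),
        channels={k: np.zeros((G, G)) for k in
                  ("ee", "ed", "brems", "auger")},
        elastic_bar=np.zeros((L + 1, G)),
        beta_c=np.zeros(G), beta_r=np.zeros(G),
        beta_bnd=np.zeros(G + 1), alpha=np.zeros(G),
        edep=np.zeros(G), edep_total=np.zeros(G),
        photon_prod=np.zeros(G), meta={})
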