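"""Macroscopic library assembly: totals, restricted stopping powers,
energy deposition, mixing and the on-disk container."""

import numpy as np
import pytest

import bfpdose as bd
from bfpdose.constants import MEC2, N_AVOGADRO
from bfpdose.library import SCHEMA_VERSION, total_xs


class TestTotalXS:
    def test_channel_sum_identity(self, water_lib30):
        """Sigma_t equals the four-term channel sum to 1e-12."""
        lib = water_lib30
        recomputed = (lib.channels["ee"].sum(axis=1)
                      + lib.channels["brems"].sum(axis=1)
                      + lib.elastic_bar[0])
        ref = np.max(np.abs(lib.sigma_t))
        assert np.max(np.abs(recomputed - lib.sigma_t)) < 1e-12 * ref

    def test_all_channels_zero(self):
        ch = {k: np.zeros((5, 5)) for k in ("ee", "ed", "brems", "auger")}
        assert np.all(total_xs(ch, np.zeros(5)) == 0.0)

    def test_elastic_only(self, gs30):
        lib = bd.build_library("water", gs30, 3, channels=("elastic",))
        assert np.allclose(lib.sigma_t, lib.elastic_bar[0])
        assert np.all(lib.sigma_t >= 0)

    def test_production_channels_not_in_total(self, water_lib30):
        """Delta-ray and Auger creation do not remove the primary."""
        lib = water_lib30
        with_ed = lib.channels["ee"].sum(1) + lib.channels["brems"].sum(1) \
            + lib.channels["ed"].sum(1) + lib.elastic_bar[0]
        assert np.any(with_ed > lib.sigma_t)


class TestSoftStoppingPowers:
    def test_pure_csd_equals_total(self, gs30, water):
        """With no catastrophic channels the restricted stopping power
        is the full total at each midpoint."""
        lib = bd.build_library(water, gs30, 3, channels=())
        m = bd.stopping_model(water, e_max_mev=max(
            2.0 * gs30.bounds_mev[-1], 10.0))
        mids = gs30.midpoints_mev
        assert np.allclose(lib.beta_c, m.collisional(mids) * water.density,
                           rtol=1e-12)
        assert np.allclose(lib.beta_r, m.radiative(mids) * water.density,
                           rtol=1e-12)

    def test_closure_soft_plus_catastrophic(self, water_lib30, water):
        """Restricted + catastrophic first-moment loss = total, 1e-8."""
        lib = water_lib30
        e1 = lib.meta["first_moments"]
        loss_col = np.zeros(lib.gs.G)
        for el, nd in water.number_densities():
            ion = bd.build_ionization_transfer(lib.gs, 7, el)
            loss_col += nd * ion.loss_cat * MEC2
        m = bd.stopping_model(water, e_max_mev=max(
            2.0 * lib.gs.bounds_mev[-1], 10.0))
        total_c = m.collisional(lib.gs.midpoints_mev) * water.density
        assert np.max(np.abs(lib.beta_c + loss_col - total_c)
                      / total_c) < 1e-8

    def test_catastrophic_fraction_bounded(self, water_lib30, water):
        """Catastrophic fraction strictly between 0 and 1 where open."""
        lib = water_lib30
        m = bd.stopping_model(water, e_max_mev=max(
            2.0 * lib.gs.bounds_mev[-1], 10.0))
        total_c = m.collisional(lib.gs.midpoints_mev) * water.density
        frac = 1.0 - lib.beta_c / total_c
        open_ch = lib.channels["ee"].sum(1) > 0
        assert np.all(frac[open_ch] > 0)
        assert np.all(frac[open_ch] < 1)

    def test_boundary_values_positive_monotone_source(self, water_lib30):
        assert np.all(water_lib30.beta_bnd > 0)
        assert water_lib30.beta_bnd.size == water_lib30.gs.G + 1


class TestEnergyDeposition:
    def test_pure_csd_reduces_to_beta(self, gs30):
        """Electron-mode deposition is the soft collisional loss; the
        as-printed variant adds the radiative loss."""
        lib = bd.build_library("water", gs30, 3, channels=())
        assert np.allclose(lib.edep, lib.beta_c, rtol=1e-12)
        assert np.allclose(lib.edep_total, lib.beta_c + lib.beta_r,
                           rtol=1e-12)

    def test_nonnegative(self, water_lib30):
        assert np.all(water_lib30.edep >= 0)
        assert np.all(water_lib30.edep_total >= 0)

    def test_catastrophic_channels_leave_local_deposit_unchanged(
            self, gs30):
        """Free-electron ionization exports all transferred energy to
        transported electrons: the local deposit stays the soft loss up
        to quadrature residue."""
        lib = bd.build_library("water", gs30, 7,
                               channels=("ionization",))
        assert np.allclose(lib.edep, lib.beta_c,
                           rtol=1e-8, atol=1e-12 * lib.beta_c.max())

    def test_photon_production_books_radiative_losses(self, water_lib30):
        lib = water_lib30
        e1 = lib.meta["first_moments"]
        expect = lib.beta_r + e1["b_photon"] + e1["fluor"]
        assert np.allclose(lib.photon_prod, expect, rtol=1e-12)


class TestMixing:
    def test_single_element_identity(self):
        mat = bd.element_material("Al")
        n = mat.density * N_AVOGADRO / bd.get_element("Al").A
        out = bd.mix_macroscopic({"Al": np.ones(4)}, mat)
        assert np.allclose(out, n)

    def test_split_identical_elements(self, water):
        """Water mixing: hand-computed N_H s_H + N_O s_O."""
        s_h, s_o = 2.0, 3.0
        out = bd.mix_macroscopic({"H": np.array([s_h]),
                                  "O": np.array([s_o])}, water)
        n_h = water.density * 0.111894 * N_AVOGADRO / 1.008
        n_o = water.density * 0.888106 * N_AVOGADRO / 15.999
        assert out[0] == pytest.approx(n_h * s_h + n_o * s_o, rel=1e-10)

    def test_unknown_element_rejected(self, water):
        with pytest.raises(KeyError):
            bd.mix_macroscopic({"H": np.ones(2)}, water)
        with pytest.raises(KeyError):
            bd.mix_macroscopic({"H": np.ones(2), "O": np.ones(2),
                                "Fe": np.ones(2)}, water)


class TestContainer:
    def test_lossless_round_trip(self, water_lib30, tmp_path):
        path = tmp_path / "water.h5"
        bd.write_library(water_lib30, path)
        back = bd.read_library(path)
        for key in ("sigma_t", "transfer", "elastic_bar", "beta_c",
                    "beta_r", "beta_bnd", "alpha", "edep", "edep_total",
                    "photon_prod"):
            a, b = getattr(water_lib30, key), getattr(back, key)
            assert np.array_equal(a, b), key
        assert np.array_equal(back.gs.bounds, water_lib30.gs.bounds)
        for k in water_lib30.channels:
            assert np.array_equal(back.channels[k],
                                  water_lib30.channels[k])
        assert back.name == "water" and back.L == 7

    def test_future_schema_rejected(self, water_lib30, tmp_path):
        import h5py
        path = tmp_path / "future.h5"
        bd.write_library(water_lib30, path)
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION + 1
        with pytest.raises(ValueError, match="schema"):
            bd.read_library(path)

    def test_mismatched_group_structures_rejected(self, gs30, water_lib30):
        gs_other = bd.build_group_structure(25, e_max_mev=10.0)
        lib2 = bd.build_library("water", gs_other, 3, channels=())
        with pytest.raises(ValueError, match="group structures"):
            bd.SlabProblem(
                regions=[(water_lib30, 1.0, 4), (lib2, 1.0, 4)],
                source=bd.BoundarySource(group=29), N=8, M=0,
                galerkin=False)
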