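"""Constants, conversions, stopping powers, ranges, group structures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bfpdose as bd
from bfpdose.constants import MEC2, COL_PREFACTOR


class TestReducedUnits:
    @pytest.mark.parametrize("mev,expected", [
        (0.0, 0.0),
        (0.51099895, 1.0),
        (51.099895, 100.0),
    ])
    def test_known_conversions(self, mev, expected):
        assert bd.reduced_energy(mev) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, e_mev):
        assert bd.energy_mev(bd.reduced_energy(e_mev)) == pytest.approx(
            e_mev, rel=1e-14)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bd.reduced_energy(-1.0)


class TestVelocityBeta:
    def test_rest_and_ultrarelativistic(self):
        assert bd.velocity_beta(0.0) == 0.0
        assert bd.velocity_beta(1e6) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_at_unit_energy(self):
        assert bd.velocity_beta(1.0) == pytest.approx(math.sqrt(3) / 2,
                                                      rel=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e5))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing(self, e):
        b = bd.velocity_beta(e)
        assert 0 < b < 1
        assert bd.velocity_beta(e * 1.01) > b


class TestCollisionalStoppingPower:
    def test_density_linearity(self, water):
        """Macroscopic (per-cm) value doubles with density at fixed
        I and delta."""
        d = bd.density_effect(10.0, water)
        s1 = bd.collisional_stopping_power(10.0, water, delta=d)
        doubled = bd.MaterialSpec("water2x", water.constituents,
                                  2.0 * water.density, water.I_eV)
        s2 = bd.collisional_stopping_power(10.0, doubled, delta=d)
        assert s2 * doubled.density == pytest.approx(
            2.0 * s1 * water.density, rel=1e-12)

    def test_delta_switch_off(self, water):
        """delta = 0 recovers the uncorrected closed form (strictly
        larger than the corrected one above the density-effect onset)."""
        s_on = bd.collisional_stopping_power(100.0, water)
        s_off = bd.collisional_stopping_power(100.0, water, delta=0.0)
        d = bd.density_effect(100.0, water)
        assert d > 0
        assert s_off > s_on
        expected_gap = COL_PREFACTOR * water.z_over_a / \
            bd.velocity_beta(100.0 / MEC2) ** 2 * d
        assert s_off - s_on == pytest.approx(expected_gap, rel=1e-12)

    def test_water_100mev_against_independent_coding(self, water):
        """Second, independently written Berger-Seltzer evaluation."""
        tau = 100.0 / MEC2
        beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
        i_red = 75.0e-6 / MEC2
        f_minus = 1 - beta2 + (tau ** 2 / 8 - (2 * tau + 1) * math.log(2)) \
            / (tau + 1) ** 2
        delta = bd.density_effect(100.0, water)
        oracle = (0.1535340e0 * water.z_over_a / beta2 *
                  (math.log(tau ** 2 * (tau + 2) / (2 * i_red ** 2))
                   + f_minus - delta))
        assert bd.collisional_stopping_power(100.0, water) == pytest.approx(
            oracle, rel=1e-3)


class TestRadiativeStoppingPower:
    def test_z_scaling_dominates(self):
        """Radiative loss grows ~Z(Z+1)/A: gold >> carbon per gram."""
        au = bd.radiative_stopping_power(10.0, bd.element_material("Au"))
        c = bd.radiative_stopping_power(10.0, bd.element_material("C"))
        assert au > 5 * c

    def test_ratio_grows_with_energy(self, water):
        energies = [10.0, 50.0, 200.0, 1000.0]
        ratios = [bd.radiative_stopping_power(e, water)
                  / bd.collisional_stopping_power(e, water)
                  for e in energies]
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))

    def test_quadrature_refinement(self, water):
        a = bd.radiative_stopping_power(100.0, water, n_panels=24)
        b = bd.radiative_stopping_power(100.0, water, n_panels=48,
                                        n_quad=32)
        assert a == pytest.approx(b, rel=1e-6)


class TestTotalStoppingContinuity:
    def test_no_jumps_on_full_grid(self, water):
        """Total stopping power continuous (no fit-boundary jump > 0.5%)
        from 1 keV to 1.5 GeV."""
        model = bd.StoppingPowerModel(water, e_max_mev=1500.0, n=400)
        tot = model._col + model._rad
        assert np.all(tot > 0)
        jumps = np.abs(np.diff(np.log(tot)))
        grid = np.abs(np.diff(np.log(model.e_grid)))
        # local relative change per grid step stays smooth
        assert np.max(jumps - 1.5 * grid) < 5e-3


class TestCsdaRange:
    def test_zero_at_cutoff_and_monotone(self, water):
        assert bd.csda_range(1e-3, water) == 0.0
        r = [bd.csda_range(e, water) for e in (1.0, 10.0, 50.0, 100.0)]
        assert all(b > a for a, b in zip(r, r[1:]))

    def test_refinement_convergence(self, water):
        m = bd.stopping_model(water, e_max_mev=400.0)
        r1 = bd.csda_range(200.0, water, n=1024, model=m)
        r2 = bd.csda_range(200.0, water, n=10240, model=m)
        assert r1 == pytest.approx(r2, rel=1e-3)

    def test_water_100mev_magnitude(self, water):
        # ICRU-scale value ~32.5 g/cm^2; our analytic models should land
        # within a few percent
        assert bd.csda_range(100.0, water) == pytest.approx(32.5, rel=0.05)


class TestGroupStructure:
    def test_production_structure(self):
        gs = bd.build_group_structure(300, e_min_mev=1e-3, e_max_mev=100.0)
        assert gs.G == 300
        assert gs.bounds.size == 301
        assert np.all(np.diff(gs.bounds) > 0)
        assert gs.bounds_mev[0] == pytest.approx(1e-3)
        assert gs.bounds_mev[-1] == pytest.approx(100.0)

    def test_minimum_three_groups(self):
        gs = bd.build_group_structure(3, e_max_mev=1.0)
        assert gs.bounds.size == 4
        assert np.all(gs.widths > 0)
        with pytest.raises(ValueError):
            bd.build_group_structure(2, e_max_mev=1.0)

    def test_log_spacing_equal_ratios(self):
        gs = bd.build_group_structure(50, e_max_mev=10.0)
        ratios = gs.bounds[1:] / gs.bounds[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_boundary_energy_ties_to_lower_group(self, gs30):
        g = 10
        assert gs30.group_of(gs30.bounds[g]) == g - 1
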