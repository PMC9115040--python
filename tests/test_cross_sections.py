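import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elfxs.constants import BOHR_NM, EV_HARTREE, HARTREE_EV
from elfxs.cross_sections import (
    channel_cross_sections,
    ddcs,
    kinematic_limits,
    sdcs,
    stopping_power,
    total_cross_section,
)
from elfxs.surfaces import DrudePeakSet, drude_elf_values, make_drude_elf


class TestKinematicLimits:
    @given(
        T=st.floats(min_value=1.0, max_value=1e6),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_product_identity(self, T, frac):
        # q_min * q_max = 2mE is an algebraic identity of the closed forms
        E = T * frac
        lim = kinematic_limits(T, E)
        expected = 2.0 * E * EV_HARTREE
        assert lim.q_min * lim.q_max == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_elastic_limit(self):
        lim = kinematic_limits(100.0, 0.0)
        assert lim.q_min == 0.0
        assert lim.q_max == pytest.approx(2.0 * np.sqrt(2.0 * 100.0 * EV_HARTREE))

    def test_degenerate_full_transfer(self):
        lim = kinematic_limits(100.0, 100.0)
        assert lim.q_min == pytest.approx(lim.q_max)
        assert lim.q_min == pytest.approx(np.sqrt(2.0 * 100.0 * EV_HARTREE))

    def test_energy_loss_above_t_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kinematic_limits(50.0, 51.0)


@pytest.fixture(scope="module")
def flat_q_surface():
    """Drude surface with no q dispersion: every column identical."""
    e = np.arange(0.5, 200.0, 0.5)
    q = np.linspace(0.1, 2.0, 12)
    return make_drude_elf(
        DrudePeakSet([(21.0, 10.0, 350.0)], dispersion_mode="none"), e, q
    ), DrudePeakSet([(21.0, 10.0, 350.0)], dispersion_mode="none")


class TestDDCS:
    def test_zero_elf_gives_zero(self, flat_q_surface):
        surf, _ = flat_q_surface
        zero = make_drude_elf(
            DrudePeakSet([(21.0, 10.0, 1e-30)], dispersion_mode="none"),
            surf.energy_grid, surf.q_grid,
        )
        assert ddcs(zero, 100.0, 20.0, 0.5) == pytest.approx(0.0, abs=1e-20)

    def test_inverse_scaling_with_t(self, flat_q_surface):
        surf, _ = flat_q_surface
        a = ddcs(surf, 200.0, 20.0, 0.5)
        b = ddcs(surf, 400.0, 20.0, 0.5)
        assert a == pytest.approx(2.0 * b, rel=1e-12)

    def test_matches_hand_evaluation_at_grid_node(self, flat_q_surface):
        surf, peaks = flat_q_surface
        T, E, q = 150.0, 21.0, 0.62727272727272732  # q slightly off-grid
        val = ddcs(surf, T, E, q)
        elf_val = drude_elf_values(peaks, np.array([E]), q)[0]
        expected = elf_val / (np.pi * (T * EV_HARTREE) * q) / (HARTREE_EV * BOHR_NM)
        assert val == pytest.approx(expected, rel=1e-10)


class TestSDCS:
    def test_q_independent_elf_closed_form(self, flat_q_surface):
        # dS/dE = ELF(E) ln(q_max/q_min) / (pi a0 T)
        surf, peaks = flat_q_surface
        T = 100.0
        curve = sdcs(surf, T)
        t_ha = T * EV_HARTREE
        for e, v in zip(curve.energies[::10], curve.values[::10]):
            lim = kinematic_limits(T, e)
            elf_val = drude_elf_values(peaks, np.array([e]), 0.1)[0]
            ref = (
                elf_val * np.log(lim.q_max / lim.q_min) / (np.pi * t_ha)
                / (HARTREE_EV * BOHR_NM)
            )
            assert v == pytest.approx(ref, rel=1e-6)

    def test_zero_elf_gives_zero_everywhere(self, flat_q_surface):
        surf, _ = flat_q_surface
        zero = make_drude_elf(
            DrudePeakSet([(21.0, 10.0, 1e-30)], dispersion_mode="none"),
            surf.energy_grid, surf.q_grid,
        )
        curve = sdcs(zero, 100.0)
        assert np.all(np.abs(curve.values) < 1e-25)

    def test_grid_points_above_t_excluded_with_warning(self, flat_q_surface):
        surf, _ = flat_q_surface
        with pytest.warns(UserWarning, match="excluded"):
            curve = sdcs(surf, 150.0)
        assert curve.n_excluded == np.count_nonzero(surf.energy_grid > 150.0)
        assert curve.energies.max() <= 150.0

    def test_matches_brute_force_fine_grid_quadrature(self, water_drude):
        # independent oracle: dense trapezoid in q (linear grid, ELF/q)
        T = 100.0
        curve = sdcs(water_drude, T, n_q=200)
        interp = water_drude.interpolator()
        for e in [10.0, 21.5, 40.0, 80.0]:
            i = int(np.argmin(np.abs(curve.energies - e)))
            lim = kinematic_limits(T, curve.energies[i])
            q = np.linspace(lim.q_min, lim.q_max, 20000)
            ref = (
                np.trapezoid(interp(curve.energies[i], q) / q, q)
                / (np.pi * T * EV_HARTREE) / (HARTREE_EV * BOHR_NM)
            )
            assert curve.values[i] == pytest.approx(ref, rel=5e-3)


class TestTotalAndStopping:
    def test_empty_integration_range_gives_zero(self, flat_q_surface):
        surf, _ = flat_q_surface
        # E_min = E_gap = E_max at T = E_gap: empty range
        tab = total_cross_section(surf, [30.0], emin_mode="gap", E_gap=30.0, E_F=0.0)
        assert tab.sigma_total[0] == 0.0
        assert np.isinf(tab.imfp[0])
        assert tab.imfp_infinite[0]

    def test_second_peak_strictly_increases_sigma(self):
        e = np.arange(0.5, 300.0, 0.5)
        q = np.geomspace(0.05, 8.0, 40)
        one = make_drude_elf(DrudePeakSet([(21.0, 10.0, 300.0)]), e, q)
        two = make_drude_elf(
            DrudePeakSet([(21.0, 10.0, 300.0), (35.0, 8.0, 80.0)]), e, q
        )
        t_grid = [50.0, 100.0, 500.0, 2000.0]
        s1 = total_cross_section(one, t_grid).sigma_total
        s2 = total_cross_section(two, t_grid).sigma_total
        assert np.all(s2 > s1)

    def test_imfp_u_shape_and_reciprocity(self, water_drude):
        t_grid = np.geomspace(10.0, 1e4, 25)
        tab = total_cross_section(water_drude, t_grid)
        prod = tab.imfp * tab.sigma_total
        np.testing.assert_allclose(prod[~tab.imfp_infinite], 1.0, rtol=1e-12)
        imin = int(np.argmin(tab.imfp))
        assert 0 < imin < t_grid.size - 1  # interior minimum (U shape)
        assert 0.1 < tab.imfp[imin] < 5.0  # nm, physically sensible scale

    def test_stopping_bounded_by_moments(self, water_drude):
        t = 500.0
        sig = total_cross_section(water_drude, [t]).sigma_total[0]
        stop = stopping_power(water_drude, [t]).stopping[0]
        e_max = t / 2.0
        assert 0.0 <= stop <= e_max * sig

    def test_zero_elf_zero_stopping(self, flat_q_surface):
        surf, _ = flat_q_surface
        zero = make_drude_elf(
            DrudePeakSet([(21.0, 10.0, 1e-30)], dispersion_mode="none"),
            surf.energy_grid, surf.q_grid,
        )
        assert stopping_power(zero, [100.0]).stopping[0] == pytest.approx(0.0, abs=1e-25)

    def test_bethe_asymptote_high_energy(self, water_drude):
        # S_e(T) * T affine in ln T for a plasmon-pole surface
        t_grid = np.geomspace(1e4, 1e5, 10)
        stop = stopping_power(water_drude, t_grid).stopping
        y = stop * t_grid
        x = np.log(t_grid)
        A = np.vstack([x, np.ones_like(x)]).T
        _, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        r2 = 1.0 - res[0] / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.999

    def test_refinement_convergence(self, water_drude):
        # halving the q quadrature step moves sigma and S_e by < 0.2%
        t = [200.0]
        s_a = total_cross_section(water_drude, t, n_q=200).sigma_total[0]
        s_b = total_cross_section(water_drude, t, n_q=400).sigma_total[0]
        st_a = stopping_power(water_drude, t, n_q=200).stopping[0]
        st_b = stopping_power(water_drude, t, n_q=400).stopping[0]
        assert abs(s_b - s_a) / s_a < 2e-3
        assert abs(st_b - st_a) / st_a < 2e-3

    def test_linearity_in_the_surface(self):
        e = np.arange(0.5, 300.0, 0.5)
        q = np.geomspace(0.05, 8.0, 40)
        p1 = DrudePeakSet([(21.0, 10.0, 300.0)])
        p2 = DrudePeakSet([(35.0, 8.0, 80.0)])
        both = DrudePeakSet([(21.0, 10.0, 300.0), (35.0, 8.0, 80.0)])
        t_grid = [100.0, 1000.0]
        s1 = total_cross_section(make_drude_elf(p1, e, q), t_grid).sigma_total
        s2 = total_cross_section(make_drude_elf(p2, e, q), t_grid).sigma_total
        s12 = total_cross_section(make_drude_elf(both, e, q), t_grid).sigma_total
        np.testing.assert_allclose(s12, s1 + s2, rtol=1e-10)


class TestChannels:
    def test_channel_curves_sum_to_total(self, toy_water):
        from elfxs.partition import mo_channel_elf

        e_grid = np.arange(0.5, 55.0, 0.5)
        qs = [toy_water.min_q(), 2 * toy_water.min_q()]
        part, surfs = mo_channel_elf(toy_water, None, qs, e_grid, 0.3)
        from elfxs.surfaces import ELFSurface

        total = ELFSurface(e_grid, np.asarray(qs), part.total,
                           allow_negative=True)
        for T in (100.0, 500.0):
            per = channel_cross_sections(surfs, T)
            summed = sum(c.values for c in per.values())
            # total under the same value-linear out-of-grid policy
            ref = sdcs(total, T, high_q="hold").values
            scale = np.max(np.abs(ref))
            np.testing.assert_allclose(summed, ref, atol=1e-8 * scale)

    def test_low_loss_dominated_by_homo_channel(self, toy_water):
        # losses below the 3a1 threshold can only excite the shallowest
        # band: the HOMO (1b1) channel carries >= 90% of the cross section
        # there (axis-averaged, as for an isotropic liquid)
        from elfxs.partition import mo_channel_elf

        e_grid = np.arange(0.5, 55.0, 0.5)
        qs = [toy_water.min_q(), 2 * toy_water.min_q()]
        _, surfs = mo_channel_elf(toy_water, None, qs, e_grid, 0.3,
                                  average_directions=True)
        per = channel_cross_sections(surfs, 100.0)
        total = sum(c.values for c in per.values())
        low = per["1b1"].energies < 10.0
        share = np.sum(per["1b1"].values[low]) / np.sum(total[low])
        assert share >= 0.9

    def test_grid_mismatch_rejected(self, flat_q_surface):
        surf, _ = flat_q_surface
        other = make_drude_elf(
            DrudePeakSet([(21.0, 10.0, 350.0)], dispersion_mode="none"),
            surf.energy_grid[:-1], surf.q_grid,
        )
        with pytest.raises(ValueError, match="grid"):
            channel_cross_sections({"a": surf, "b": other}, 100.0)

    def test_zero_weight_channel_identically_zero(self, toy_water):
        from elfxs.partition import mo_channel_elf
        from elfxs.surfaces import ELFSurface

        e_grid = np.arange(0.5, 40.0, 0.5)
        qs = [toy_water.min_q()]
        _, surfs = mo_channel_elf(toy_water, None, qs, e_grid, 0.3)
        zero = ELFSurface(e_grid, np.asarray(qs), np.zeros((e_grid.size, 1)))
        surfs["empty"] = zero
        per = channel_cross_sections(surfs, 100.0)
        assert np.all(per["empty"].values == 0.0)
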