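import numpy as np
import pytest

from elfxs.constants import HARTREE_EV
from elfxs.models import make_toy_water
from elfxs.partition import (
    default_mo_windows,
    delf_occupied,
    effective_potential,
    mo_channel_elf,
    pair_contributions,
    partition_surfaces,
    project_labels,
)
from elfxs.response import (
    KernelMatrix,
    ResponseMatrix,
    chi0,
    chi0_array,
    coulomb_kernel,
    elf_with_lfe,
    pair_table,
)
from tests.test_response import tiny_lcao

ETA = 0.3


@pytest.fixture(scope="module")
def water_point(toy_water):
    """chi0/kernel/veff/pairs of the toy-water model at one (E, q)."""
    q = toy_water.min_q()
    e = 20.0
    pt = pair_table(toy_water, q)
    rm = ResponseMatrix(q=q, energy=e, matrix=chi0_array(pt, [e], ETA)[0],
                        kind="noninteracting", gvectors=pt.glist)
    kern = coulomb_kernel(toy_water, q, glist=pt.glist)
    veff = effective_potential(rm, kern)
    pairs = pair_contributions(toy_water, veff, q, e, ETA, pairs=pt)
    return toy_water, q, e, rm, kern, veff, pairs


class TestEffectivePotential:
    def test_zero_kernel_returns_external(self, water_point):
        _, q, e, rm, kern, _, _ = water_point
        zero = KernelMatrix(q=q, matrix=np.zeros_like(kern.matrix))
        v = effective_potential(rm, zero)
        expected = np.zeros(rm.matrix.shape[0], dtype=complex)
        expected[0] = 1.0
        np.testing.assert_allclose(v.vector, expected, atol=1e-14)

    def test_scalar_closed_form(self):
        c = 0.03 - 0.07j
        vq = 2.5
        rm = ResponseMatrix(q=0.5, energy=10.0, matrix=np.array([[c]]),
                            kind="noninteracting")
        v = effective_potential(rm, KernelMatrix(q=0.5, matrix=np.array([[vq]])))
        assert v.vector[0] == pytest.approx(1.0 / (1.0 - vq * c))

    def test_residual_is_small(self, water_point):
        *_, veff, _ = water_point[:7]
        assert water_point[5].residual < 1e-10


class TestPairContributions:
    def test_sum_reproduces_direct_elf(self, water_point):
        model, q, e, *_ , pairs = water_point
        direct = elf_with_lfe(model, q, [e], ETA)[0]
        assert pairs.total == pytest.approx(direct, rel=1e-10)
        assert pairs.closure_error() < 1e-12

    def test_fully_occupied_model_all_zero(self):
        m = tiny_lcao(occupations=(2.0, 2.0, 2.0))
        q = m.min_q()
        pt = pair_table(m, q)
        rm = ResponseMatrix(q=q, energy=10.0, matrix=chi0_array(pt, [10.0], ETA)[0],
                            kind="noninteracting", gvectors=pt.glist)
        veff = effective_potential(rm, coulomb_kernel(m, q, glist=pt.glist))
        pr = pair_contributions(m, veff, q, 10.0, ETA, pairs=pt)
        assert pr.total == 0.0
        assert pr.components == {}

    def test_single_pair_toy_lone_component_is_total(self):
        # one occupied and one empty band at a single k-point
        m = tiny_lcao(kmesh=(1, 1, 1), occupations=(2.0, 0.0, 0.0))
        m.band_energies = m.band_energies[:, :2]
        m.occupations = m.occupations[:, :2]
        m.coeffs = m.coeffs[:, :2]
        q = m.min_q()
        # with a single k-point the smallest q equals a reciprocal-lattice
        # vector, so keep the response basis away from the singular G = -q
        glist = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0]])
        pt = pair_table(m, q, glist=glist)
        e = 17.0
        rm = ResponseMatrix(q=q, energy=e, matrix=chi0_array(pt, [e], ETA)[0],
                            kind="noninteracting", gvectors=pt.glist)
        veff = effective_potential(rm, coulomb_kernel(m, q, glist=pt.glist))
        pr = pair_contributions(m, veff, q, e, ETA, pairs=pt)
        # resonant (occ->emp) and antiresonant (emp->occ) terms of one pair
        assert len(pr.components) == 2
        assert sum(pr.components.values()) == pytest.approx(pr.total)


class TestDELF:
    def test_one_bin_closure(self, water_point):
        *_, pairs = water_point
        d = delf_occupied(pairs, [-40.0, 0.0])
        assert d.component_sum() == pytest.approx(pairs.total)

    def test_empty_bin_is_exactly_zero(self, water_point):
        *_, pairs = water_point
        # -8 eV to -6 eV lies inside the gap: no occupied states there
        d = delf_occupied(pairs, [-40.0, -8.0, -6.0])
        assert d.components[(-8.0, -6.0)] == 0.0

    def test_uncovered_states_rejected(self, water_point):
        *_, pairs = water_point
        with pytest.raises(ValueError, match="do not cover"):
            delf_occupied(pairs, [-20.0, 0.0])  # misses the 2a1 band

    def test_toy_water_delf_nonzero_in_exactly_four_windows(self, toy_water):
        # histogram bins aligned with the four occupied bands plus gap bins
        # between them: signal in the band bins, silence in the gaps
        q = toy_water.min_q()
        e = 22.0
        pt = pair_table(toy_water, q)
        rm = ResponseMatrix(q=q, energy=e, matrix=chi0_array(pt, [e], ETA)[0],
                            kind="noninteracting", gvectors=pt.glist)
        veff = effective_potential(rm, coulomb_kernel(toy_water, q, glist=pt.glist))
        pairs = pair_contributions(toy_water, veff, q, e, ETA, pairs=pt)

        occ = toy_water.band_energies[:, :4] * HARTREE_EV
        edges = []
        for b in range(4):
            edges += [occ[:, b].min() - 0.2, occ[:, b].max() + 0.2]
        edges = sorted(edges)
        d = delf_occupied(pairs, edges)
        nonzero = [k for k, v in d.components.items()
                   if abs(v) > 1e-10 * abs(d.total)]
        assert len(nonzero) == 4
        # and they are the band bins, not the gaps
        for (lo, hi) in nonzero:
            assert np.any((occ >= lo) & (occ <= hi))


class TestLabelProjections:
    @pytest.mark.parametrize(
        "grouping", ["species", "angular_momentum", "species_by_l", "species_pairs"]
    )
    def test_closure_under_every_grouping(self, water_point, grouping):
        model, *_, pairs = water_point
        p = project_labels(model, pairs, grouping)
        assert p.closure_error() < 1e-12

    def test_species_pairs_symmetrized_product(self, water_point):
        model, *_, pairs = water_point
        p2 = project_labels(model, pairs, "species_pairs")
        assert set(p2.components) == {"O-O", "O-H", "H-H"}

    def test_all_s_model_is_pure_s(self):
        m = tiny_lcao()
        # restrict occupied band to the s-dominated template? instead use
        # angular_momentum weights directly: occupied band 0 mixes s and p,
        # so build a pure-s occupied model
        from elfxs.models import OrbitalLabel, make_lcao_model

        a = 6.0
        c = 0.5 * a * np.ones(3)
        orbitals = [
            (OrbitalLabel(0, "O", "s"), c, 1.2, 0),
            (OrbitalLabel(1, "H", "s"), c + np.array([1.5, 0, 0]), 1.4, 0),
        ]
        m = make_lcao_model(
            a=a, kmesh=(2, 1, 1), orbitals=orbitals,
            band_templates=np.array([[0.9, 0.3], [-0.3, 0.9]]),
            band_centers_ev=np.array([-15.0, -4.0]),
            band_halfwidths_ev=np.array([0.5, 0.5]),
            band_occupations=np.array([2.0, 0.0]),
            internal_norm2=5.0,
        )
        q = m.min_q()
        pt = pair_table(m, q)
        rm = ResponseMatrix(q=q, energy=11.0, matrix=chi0_array(pt, [11.0], ETA)[0],
                            kind="noninteracting", gvectors=pt.glist)
        veff = effective_potential(rm, coulomb_kernel(m, q, glist=pt.glist))
        pairs = pair_contributions(m, veff, q, 11.0, ETA, pairs=pt)
        p = project_labels(m, pairs, "angular_momentum")
        assert set(p.components) == {"s"}
        assert p.components["s"] == pytest.approx(p.total)

    def test_unlabelled_model_rejected(self, jellium_small):
        m = jellium_small
        q = m.min_q()
        pt = pair_table(m, q, glist=np.array([[0, 0, 0]]))
        rm = ResponseMatrix(q=q, energy=10.0, matrix=chi0_array(pt, [10.0], 1.0)[0],
                            kind="noninteracting", gvectors=pt.glist)
        veff = effective_potential(rm, coulomb_kernel(m, q, glist=pt.glist))
        pairs = pair_contributions(m, veff, q, 10.0, 1.0, pairs=pt)
        with pytest.raises(ValueError, match="no orbital labels"):
            project_labels(m, pairs, "species")


class TestMOChannels:
    E_GRID = np.arange(0.5, 55.0, 0.5)

    def test_default_windows_centred_on_binding_energies(self, toy_water):
        win = default_mo_windows(toy_water)
        assert set(win) == {"2a1", "1b2", "3a1", "1b1"}
        for lab, centre in zip(("2a1", "1b2", "3a1", "1b1"),
                               (30.90, 17.34, 13.50, 11.16)):
            lo, hi = win[lab]
            assert lo < centre < hi

    def test_channels_close_onto_total_surface(self, toy_water):
        qs = [toy_water.min_q(), 2 * toy_water.min_q()]
        part, surfs = mo_channel_elf(toy_water, None, qs, self.E_GRID, ETA)
        assert part.closure_error() < 1e-12
        summed = sum(s.values for s in surfs.values())
        np.testing.assert_allclose(summed, part.total, atol=1e-12)

    def test_route_equivalence_with_direct_dyson_elf(self, toy_water):
        # the veff assembly must reproduce the direct Dyson-solve ELF
        qs = [toy_water.min_q()]
        part = partition_surfaces(toy_water, "species", qs, self.E_GRID, ETA)
        direct = elf_with_lfe(toy_water, qs[0], self.E_GRID, ETA)
        np.testing.assert_allclose(part.total[:, 0], direct, atol=1e-10)

    def test_single_window_covering_everything_equals_total(self, toy_water):
        qs = [toy_water.min_q()]
        part, surfs = mo_channel_elf(
            toy_water, {"all": (5.0, 40.0)}, qs, self.E_GRID, ETA
        )
        np.testing.assert_allclose(
            surfs["all"].values, part.total, atol=1e-12
        )

    def test_window_boundary_shift_in_gap_leaves_channels_invariant(self, toy_water):
        # moving a boundary inside the empty region between 1b2 and 2a1
        # cannot change any channel total
        qs = [toy_water.min_q()]
        base = default_mo_windows(toy_water)
        shifted = dict(base)
        lo2a1 = base["2a1"]
        hi1b2 = base["1b2"]
        shifted["2a1"] = (lo2a1[0] + 2.0, lo2a1[1])
        shifted["1b2"] = (hi1b2[0], lo2a1[0] + 2.0)
        p1, _ = mo_channel_elf(toy_water, base, qs, self.E_GRID, ETA)
        p2, _ = mo_channel_elf(toy_water, shifted, qs, self.E_GRID, ETA)
        for lab in base:
            np.testing.assert_allclose(
                p1.components[lab], p2.components[lab], atol=1e-14
            )

    def test_overlapping_windows_rejected(self, toy_water):
        win = {"a": (9.0, 14.0), "b": (13.0, 32.0)}
        with pytest.raises(ValueError, match="overlap"):
            mo_channel_elf(toy_water, win, [toy_water.min_q()], self.E_GRID, ETA)

    def test_window_without_states_rejected(self, toy_water):
        win = dict(default_mo_windows(toy_water))
        win["ghost"] = (2.0, 5.0)
        with pytest.raises(ValueError, match="no occupied state"):
            mo_channel_elf(toy_water, win, [toy_water.min_q()], self.E_GRID, ETA)

    def test_occupied_energy_surface_scheme_closes(self, toy_water):
        part = partition_surfaces(
            toy_water, "occupied_energy", [toy_water.min_q()], self.E_GRID, ETA,
            bin_edges_ev=np.linspace(-35.0, -5.0, 16),
        )
        assert part.closure_error() < 1e-12
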