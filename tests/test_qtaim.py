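"""Critical-point search, Abramov/virial energy densities and bond classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fullersense import (
    Geometry,
    PromolecularField,
    SyntheticAtom,
    energy_densities,
    find_bcp,
    midpoint_seeds,
    rozas_class,
    total_energy_density,
)
from fullersense.qtaim import ABRAMOV_COEFF, cp_table


class TestEnergyDensities:
    def test_reference_point(self):
        g, v, hb = energy_densities(0.01, 0.04)
        assert g == pytest.approx(8.00e-3, rel=1e-3)
        assert v == pytest.approx(-6.0e-3, rel=1e-3)
        assert hb == pytest.approx(2.0e-3, rel=1e-3)

    def test_vacuum_limit(self):
        assert energy_densities(0.0, 0.0) == (0.0, 0.0, 0.0)

    def test_closed_shell_contact_regime(self):
        # Abramov estimate from rho and the Laplacian alone; the
        # wavefunction-derived reference G for this point is larger
        g, _, _ = energy_densities(0.019, -0.007)
        assert g == pytest.approx(2.72e-3, rel=2e-3)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            energy_densities(-0.01, 0.0)

    @given(rho=st.floats(1e-4, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_zero_laplacian_closed_form(self, rho):
        g, v, hb = energy_densities(rho, 0.0)
        assert g == pytest.approx(ABRAMOV_COEFF * rho ** (5 / 3), rel=1e-12)
        assert v == pytest.approx(-2 * g, rel=1e-12)
        assert hb == pytest.approx(-g, rel=1e-12)

    @given(rho=st.floats(0, 0.5), lap=st.floats(-0.5, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_local_virial_identity(self, rho, lap):
        g, v, hb = energy_densities(rho, lap)
        assert 2 * g + v == pytest.approx(0.25 * lap, abs=1e-12)
        assert hb == g + v


class TestTotalEnergyDensity:
    @pytest.mark.parametrize(
        "g,v,expected",
        [
            (0.005, -0.001, 0.004),  # pristine-cage complex
            (0.008, 0.0007, 0.0087),  # boron-doped complex, prints as 0.009
            (0.0, 0.0, 0.0),
        ],
    )
    def test_sum(self, g, v, expected):
        assert total_energy_density(g, v) == pytest.approx(expected, abs=1e-12)

    def test_fixture_hb_within_printed_digit(self, fixture):
        from fullersense import printed_tolerance

        for row in fixture.table7:
            hb = total_energy_density(row.g, row.v)
            assert hb == pytest.approx(
                float(row.hb_text), abs=printed_tolerance(row.hb_text)
            ), row.label


class TestRozasClass:
    @pytest.mark.parametrize(
        "hb,lap,expected",
        [
            (0.004, -0.006, "moderate"),
            (-0.01, -0.02, "strong"),
            (0.002, 0.003, "weak"),
            (-0.002, 0.003, "unclassified"),
            (0.0, -0.01, "unclassified"),
        ],
    )
    def test_stated_rule(self, hb, lap, expected):
        assert rozas_class(hb, lap) == expected

    def test_literature_variant_moves_moderate(self):
        assert rozas_class(-0.002, 0.003, variant="literature") == "moderate"
        assert rozas_class(0.004, -0.006, variant="literature") == "unclassified"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rozas_class(0.0, 0.0, variant="bogus")


class TestFindBCP:
    def test_dimer_midpoint_is_3_minus_1(self, dimer):
        analytic, _ = dimer
        points = find_bcp(analytic, [[0.05, -0.08, 0.2]])
        assert len(points) == 1
        cp = points[0]
        np.testing.assert_allclose(cp.position, 0.0, atol=1e-6)
        assert (cp.rank, cp.signature) == (3, -1)
        assert cp.is_bcp
        assert cp.rho == pytest.approx(2 * math.exp(-1.0), rel=1e-9)
        # closed form: transverse curvatures -4/e, axial +4/e
        np.testing.assert_allclose(
            cp.eigenvalues,
            [-4 / math.e, -4 / math.e, 4 / math.e],
            rtol=1e-6,
        )
        assert cp.laplacian == pytest.approx(-4 / math.e, rel=1e-6)

    def test_gradient_and_trace_identities_at_cp(self, dimer):
        analytic, _ = dimer
        (cp,) = find_bcp(analytic, [[0.1, 0.0, -0.3]])
        assert np.linalg.norm(analytic.gradient(cp.position)) < 1e-8
        assert abs(np.sum(cp.eigenvalues) - cp.laplacian) < 1e-6

    def test_nuclear_maximum_reported_but_not_bcp(self, single_gaussian):
        points = find_bcp(single_gaussian, [[0.2, 0.1, -0.1]])
        assert len(points) == 1
        assert (points[0].rank, points[0].signature) == (3, -3)
        assert not points[0].is_bcp

    def test_unconverged_seed_warns_and_is_dropped(self, single_gaussian):
        # from the outer tail Newton drifts outward and never reaches a zero
        with pytest.warns(UserWarning, match="did not converge"):
            points = find_bcp(single_gaussian, [[3.0, 0.0, 0.0]], max_steps=3)
        assert points == []

    def test_vacuum_seed_contributes_nothing(self, single_gaussian):
        # the gradient underflows to zero far away: the trivial "zero" is
        # rank-deficient and excluded rather than reported as a BCP
        with pytest.warns(UserWarning, match="rank-deficient"):
            points = find_bcp(single_gaussian, [[80.0, 80.0, 80.0]])
        assert points == []

    def test_duplicate_seeds_deduplicate(self, dimer):
        analytic, _ = dimer
        points = find_bcp(
            analytic, [[0.05, 0.0, 0.1], [-0.05, 0.0, -0.1], [0.0, 0.02, 0.0]]
        )
        assert len(points) == 1

    def test_grid_backed_search_matches_analytic(self, dimer):
        from fullersense import grid_field

        analytic, grid = dimer
        points = find_bcp(grid_field(grid), [[0.05, 0.0, 0.1]], grad_tol=1e-7)
        assert len(points) == 1
        np.testing.assert_allclose(points[0].position, 0.0, atol=0.05)
        assert points[0].rho == pytest.approx(2 / math.e, rel=0.01)

    # below separation √2 the midpoint saddle merges with the two maxima
    # into a single (3,-3) point, so stay clear of the bifurcation
    @given(sep=st.floats(1.7, 3.0), amp=st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_forced_midpoint_cp(self, sep, amp):
        field = PromolecularField([
            SyntheticAtom(center=[0, 0, -sep / 2], amplitude=amp),
            SyntheticAtom(center=[0, 0, sep / 2], amplitude=amp),
        ])
        points = find_bcp(field, [[0.03, -0.02, 0.05]])
        assert len(points) == 1
        np.testing.assert_allclose(points[0].position, 0.0, atol=1e-5)


class TestSeedsAndReport:
    def test_midpoint_seeds_between_fragments_only(self):
        a = Geometry(("C", "C"), np.array([[0.0, 0, 0], [0, 0, 1.0]]))
        b = Geometry(("C",), np.array([[0.0, 0, 3.0]]))
        seeds = midpoint_seeds(a, b)
        assert len(seeds) == 2  # 2 atoms x 1 atom, never intra-fragment pairs
        # midpoints in bohr of the Å coordinates
        np.testing.assert_allclose(seeds[0], [0, 0, 1.5 / 0.529177], rtol=1e-6)

    def test_cp_table_columns(self, dimer):
        analytic, _ = dimer
        table = cp_table(find_bcp(analytic, [[0.0, 0.1, 0.0]]))
        assert list(table.columns[:5]) == [
            "x_bohr", "y_bohr", "z_bohr", "rho_au", "laplacian_au"
        ]
        assert table.loc[0, "bond_class"] in {
            "strong", "moderate", "weak", "unclassified"
        }
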