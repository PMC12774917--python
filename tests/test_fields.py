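"""Promolecular and grid-backed density fields, RDG and NCI binning."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fullersense import (
    CubeGrid,
    PromolecularField,
    SyntheticAtom,
    classify_nci,
    grid_field,
    nci_point,
    nci_scan,
)
from fullersense.fields import RDG_PREFACTOR


def gaussian_cube(spacing, half=3.0, exponent=1.0):
    n = int(round(2 * half / spacing)) + 1
    xs = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
    vals = np.exp(-exponent * (gx**2 + gy**2 + gz**2))
    grid = CubeGrid(
        origin=[xs[0]] * 3,
        axes=np.diag([spacing] * 3),
        counts=(n, n, n),
        atoms=[(1, 1.0, np.zeros(3))],
        values=vals,
    )
    return grid, xs


class TestPromolecularField:
    def test_single_atom_closed_forms_at_center(self, single_gaussian):
        s = single_gaussian.sample(np.zeros(3))
        assert s.rho == pytest.approx(1.0)
        np.testing.assert_allclose(s.grad, 0.0, atol=1e-15)
        np.testing.assert_allclose(s.eigenvalues, [-2.0, -2.0, -2.0], atol=1e-12)

    def test_superposition_linearity(self):
        a = SyntheticAtom(center=[0, 0, -1.0])
        b = SyntheticAtom(center=[0, 0, 1.0])
        pair = PromolecularField([a, b])
        fa, fb = PromolecularField([a]), PromolecularField([b])
        for p in ([0.2, -0.3, 0.5], [0, 0, 0], [1, 1, 1]):
            assert pair.rho(p) == pytest.approx(fa.rho(p) + fb.rho(p), rel=1e-14)
            np.testing.assert_allclose(
                pair.hessian(p), fa.hessian(p) + fb.hessian(p), atol=1e-14
            )

    @given(
        t=st.tuples(*[st.floats(-3, 3) for _ in range(3)]),
        p=st.tuples(*[st.floats(-2, 2) for _ in range(3)]),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_invariance(self, t, p):
        t, p = np.asarray(t), np.asarray(p)
        base = PromolecularField([SyntheticAtom(center=[0.5, -0.25, 1.0])])
        moved = PromolecularField([SyntheticAtom(center=[0.5, -0.25, 1.0] + t)])
        assert moved.rho(p + t) == pytest.approx(base.rho(p), rel=1e-12, abs=1e-300)

    def test_empty_atom_list_rejected(self):
        with pytest.raises(ValueError):
            PromolecularField([])


class TestGridField:
    def test_linear_ramp_exact(self):
        n = 9
        xs = np.arange(n) * 0.5
        gx, _, _ = np.meshgrid(xs, xs, xs, indexing="ij")
        grid = CubeGrid(origin=np.zeros(3), axes=np.diag([0.5] * 3),
                        counts=(n, n, n), atoms=[], values=gx)
        f = grid_field(grid)
        p = np.array([2.0, 2.0, 2.0])
        np.testing.assert_allclose(f.gradient(p), [1.0, 0.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(f.hessian(p), 0.0, atol=1e-10)

    def test_gradient_and_hessian_converge_second_order(self, single_gaussian):
        errors = {}
        for h in (0.2, 0.1):
            grid, xs = gaussian_cube(h)
            f = grid_field(grid)
            ge, he = 0.0, 0.0
            for x in xs[4:-4:3]:
                for y in xs[4:-4:3]:
                    p = np.array([x, y, 0.0])
                    ge = max(ge, np.max(np.abs(
                        f.gradient(p) - single_gaussian.gradient(p))))
                    he = max(he, np.max(np.abs(
                        f.hessian(p) - single_gaussian.hessian(p))))
            errors[h] = (ge, he)
        grad_ratio = errors[0.2][0] / errors[0.1][0]
        hess_ratio = errors[0.2][1] / errors[0.1][1]
        assert 3.0 < grad_ratio < 5.5
        assert 2.5 < hess_ratio < 6.0
        # absolute accuracy at 0.1 bohr, normalized by the peak gradient norm
        assert errors[0.1][0] / (2.0 / math.sqrt(2 * math.e)) < 0.02

    def test_grid_reproduces_analytic_dimer_at_nodes(self, dimer):
        analytic, grid = dimer
        f = grid_field(grid)
        for p in ([0, 0, 0], [0.25, 0.25, 1.0], [-0.5, 0.0, -1.0]):
            assert f.rho(p) == pytest.approx(analytic.rho(p), abs=1e-12)

    def test_outside_probe_clamps_with_warning(self, dimer):
        _, grid = dimer
        f = grid_field(grid)
        with pytest.warns(UserWarning, match="clamped"):
            f.rho([100.0, 0.0, 0.0])

    def test_non_orthogonal_axes_rejected(self):
        axes = np.array([[0.5, 0.1, 0.0], [0.0, 0.5, 0.0], [0.0, 0.0, 0.5]])
        grid = CubeGrid(origin=np.zeros(3), axes=axes, counts=(5, 5, 5),
                        atoms=[], values=np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="non-orthogonal"):
            grid_field(grid)

    def test_rotated_orthogonal_axes_supported(self):
        # 45-degree rotation about z: orthogonal but not axis-aligned
        c = math.sqrt(0.5)
        rot = np.array([[c, c, 0.0], [-c, c, 0.0], [0.0, 0.0, 1.0]]) * 0.25
        n = 25
        origin = -(n - 1) / 2 * rot.sum(axis=0)
        idx = np.arange(n)
        ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
        pts = (ii[..., None] * rot[0] + jj[..., None] * rot[1]
               + kk[..., None] * rot[2] + origin)
        vals = np.exp(-np.sum(pts**2, axis=-1))
        grid = CubeGrid(origin=origin, axes=rot, counts=(n, n, n),
                        atoms=[], values=vals)
        f = grid_field(grid)
        analytic = PromolecularField([SyntheticAtom(center=np.zeros(3))])
        # probe at a lattice node: only the finite-difference error remains,
        # which at 0.25 bohr spacing is a few percent of the peak gradient
        p = origin + np.array([13, 14, 11]) @ rot
        np.testing.assert_allclose(f.gradient(p), analytic.gradient(p), atol=0.05)


class TestNCIPoint:
    def test_rdg_at_unit_radius_of_gaussian_atom(self, single_gaussian):
        s, rdg = nci_point(single_gaussian.sample([1.0, 0.0, 0.0]))
        expected = 1.0 * math.exp(1.0 / 3.0) / (3 * math.pi**2) ** (1 / 3)
        assert rdg == pytest.approx(expected, rel=1e-10)
        assert rdg == pytest.approx(0.4511, abs=1e-4)

    def test_rdg_vanishes_at_stationary_points(self, dimer):
        analytic, _ = dimer
        s, rdg = nci_point(analytic.sample([0.0, 0.0, 0.0]))
        assert rdg == pytest.approx(0.0, abs=1e-12)
        # the midpoint accumulation is bonding: lambda2 < 0
        assert s == pytest.approx(-analytic.rho([0, 0, 0]))

    def test_local_maximum_signs_negative(self, single_gaussian):
        s, _ = nci_point(single_gaussian.sample([0.0, 0.0, 0.0]))
        assert s == pytest.approx(-1.0)

    def test_vacuum_point_rejected(self, single_gaussian):
        sample = single_gaussian.sample([0.0, 0.0, 0.0])
        broke = type(sample)(rho=0.0, grad=sample.grad, hessian=sample.hessian,
                             eigenvalues=sample.eigenvalues)
        with pytest.raises(ValueError):
            nci_point(broke)

    @given(c=st.floats(0.1, 10.0), r=st.floats(0.3, 2.5))
    @settings(max_examples=100, deadline=None)
    def test_rdg_density_scaling_law(self, c, r):
        # rho -> c*rho with grad -> c*grad rescales RDG by c^(-1/3)
        base = PromolecularField([SyntheticAtom(center=np.zeros(3))])
        scaled = PromolecularField(
            [SyntheticAtom(center=np.zeros(3), amplitude=c)]
        )
        p = [r, 0.0, 0.0]
        _, rdg0 = nci_point(base.sample(p))
        _, rdg1 = nci_point(scaled.sample(p))
        assert rdg1 == pytest.approx(c ** (-1.0 / 3.0) * rdg0, rel=1e-9)

    def test_s_bounded_by_rho(self, dimer):
        analytic, _ = dimer
        rng = np.random.default_rng(7)
        for p in rng.uniform(-2, 2, size=(50, 3)):
            sample = analytic.sample(p)
            if sample.rho <= 1e-12:
                continue
            s, _ = nci_point(sample)
            assert abs(s) <= sample.rho + 1e-15


class TestNCIScan:
    def test_dimer_bond_trough(self, dimer):
        analytic, _ = dimer
        rho_mid = analytic.rho([0, 0, 0])
        scatter = nci_scan(analytic, [-1.5, -1.5, -2.5], [1.5, 1.5, 2.5],
                           spacing=0.25, rho_ceiling=1.5)
        # the midpoint critical point is a low-RDG attractive trough
        mask = np.isclose(scatter.points[:, 0], -rho_mid, atol=1e-9)
        assert mask.any()
        assert scatter.points[mask, 1].min() < 1e-9
        assert scatter.attractive >= 1

    def test_bins_exhaustive_and_exclusive(self, dimer):
        analytic, _ = dimer
        scatter = nci_scan(analytic, [-2, -2, -3], [2, 2, 3], spacing=0.5,
                           rho_ceiling=1.5)
        assert scatter.attractive + scatter.vdw + scatter.repulsive == scatter.n_points

    def test_empty_region_after_filtering(self, single_gaussian):
        scatter = nci_scan(single_gaussian, [50, 50, 50], [51, 51, 51],
                           spacing=0.5)
        assert scatter.n_points == 0
        assert (scatter.attractive, scatter.vdw, scatter.repulsive) == (0, 0, 0)

    def test_far_separated_dimer_has_no_midplane_points(self):
        from fullersense import make_dimer

        atoms, _ = make_dimer(12.0, grid_spacing=0.5)
        field = PromolecularField(atoms)
        assert field.rho([0, 0, 0]) < 1e-8
        scatter = nci_scan(field, [-1, -1, -1], [1, 1, 1], spacing=0.5)
        assert scatter.n_points == 0

    def test_zero_spacing_rejected(self, single_gaussian):
        with pytest.raises(ValueError):
            nci_scan(single_gaussian, [0, 0, 0], [1, 1, 1], spacing=0.0)


class TestClassify:
    def test_bracketing_thresholds(self):
        assert classify_nci([-0.02, 0.0, 0.02]) == (1, 1, 1)

    def test_all_zero_is_vdw(self):
        assert classify_nci(np.zeros(5)) == (0, 5, 0)

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_nci([0.0], t_attr=0.01, t_rep=-0.01)
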