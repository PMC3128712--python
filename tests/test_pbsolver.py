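"""Finite-difference linearized PB solver: maps, boundaries, relaxation,
focusing and pocket classification, checked against closed forms."""

import numpy as np
import pytest

from hladr.evaluation import born_screened_potential
from hladr.pb import (
    ConvergenceError,
    GridGeometry,
    SolverParams,
    boundary_potentials,
    build_maps,
    classify_pocket,
    coulomb_constant,
    debye_kappa,
    debye_length,
    focused_solve,
    grid_for_system,
    read_patch,
    solve_lpb,
    solve_system,
    spread_charges,
)
from hladr.pqr import ChargeSystem


def ion(q=1.0, radius=2.0):
    return ChargeSystem(
        coords=np.zeros((1, 3)), charges=np.array([q]), radii=np.array([radius])
    )


SMALL = SolverParams(npts=33)


class TestConstants:
    def test_coulomb_constant_scale(self):
        # e^2/(4 pi eps0 kB T A) ~ 560 at room temperature
        assert coulomb_constant(298.15) == pytest.approx(560.7, rel=1e-3)

    def test_debye_length_physiological(self):
        # ~8 Angstrom at 145 mM monovalent salt in water
        lam = debye_length(SolverParams())
        assert 7.5 < lam < 8.5

    def test_zero_ionic_strength_no_screening(self):
        assert debye_kappa(SolverParams(ionic_strength=0.0)) == 0.0


class TestBuildMaps:
    def test_zero_atoms_all_solvent(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=1.0)
        maps = build_maps(ChargeSystem(np.empty((0, 3)), [], []), SMALL, geom)
        assert not maps.interior.any()
        assert np.unique(maps.kappa2).size == 1
        assert maps.eps.min() == maps.eps.max() == SMALL.eps_out

    def test_probe_and_stern_inflation_radii(self):
        # atom radius 2, probe 1.4 -> interior to 3.4 A; ion-free to 4.0 A
        geom = GridGeometry(center=(0, 0, 0), npts=33, spacing=0.4)
        maps = build_maps(ion(), SMALL, geom)
        xs, ys, zs = geom.axes()
        grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        r = np.linalg.norm(grid, axis=-1)
        tol = 1e-9  # same inclusive tie convention as the map builder
        np.testing.assert_array_equal(maps.interior, r <= 3.4 + tol)
        np.testing.assert_array_equal(maps.ion_excluded, r <= 4.0 + tol)
        assert (maps.kappa2[r <= 4.0 + tol] == 0).all()
        assert (maps.kappa2[r > 4.0 + tol] > 0).all()

    def test_interior_count_matches_brute_force(self, rng):
        coords = rng.normal(size=(3, 3)) * 1.5
        radii = np.array([1.0, 1.5, 0.8])
        system = ChargeSystem(coords=coords, charges=np.zeros(3), radii=radii)
        geom = GridGeometry(center=(0, 0, 0), npts=21, spacing=0.7)
        maps = build_maps(system, SMALL, geom)
        xs, ys, zs = geom.axes()
        grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
        brute = np.zeros(grid.shape[:-1], dtype=bool)
        for i in range(3):
            d = np.linalg.norm(grid - coords[i], axis=-1)
            brute |= d <= radii[i] + SMALL.probe_radius
        assert maps.interior.sum() == brute.sum()

    def test_system_exceeding_grid_rejected(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=0.5)
        with pytest.raises(ValueError, match="larger grid"):
            build_maps(ion(radius=5.0), SMALL, geom)


class TestBoundary:
    def test_zero_charge_zero_boundary(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=1.0)
        phi = boundary_potentials(ion(q=0.0), SMALL, geom)
        assert np.abs(phi).max() == 0.0

    def test_centered_charge_symmetric_faces(self):
        geom = GridGeometry(center=(0, 0, 0), npts=11, spacing=1.0)
        phi = boundary_potentials(ion(), SMALL, geom)
        np.testing.assert_allclose(phi[0], phi[-1], rtol=1e-12)
        np.testing.assert_allclose(phi[:, 0], phi[:, -1], rtol=1e-12)
        np.testing.assert_allclose(phi[0], phi[0].T, rtol=1e-12)

    def test_kappa_zero_limit_is_plain_coulomb(self):
        params = SolverParams(npts=33, ionic_strength=0.0)
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=2.0)
        phi = boundary_potentials(ion(), params, geom)
        C = coulomb_constant(params.temperature)
        corner_r = np.sqrt(3) * 8.0
        assert phi[0, 0, 0] == pytest.approx(
            C / (params.eps_out * corner_r), rel=1e-12
        )


class TestSpreadCharges:
    def test_on_node_charge_no_spreading(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=1.0)
        q = spread_charges(ion(), geom)
        assert q[4, 4, 4] == pytest.approx(1.0)
        assert q.sum() == pytest.approx(1.0)

    def test_off_node_charge_conserved(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=1.0)
        system = ChargeSystem(
            coords=np.array([[0.3, -0.2, 0.7]]), charges=[1.5], radii=[1.0]
        )
        q = spread_charges(system, geom)
        assert q.sum() == pytest.approx(1.5)
        assert (q != 0).sum() == 8


class TestSolve:
    def test_zero_everything_zero_map(self):
        geom = GridGeometry(center=(0, 0, 0), npts=9, spacing=1.0)
        system = ChargeSystem(np.empty((0, 3)), [], [])
        maps = build_maps(system, SMALL, geom)
        pmap = solve_lpb(maps, np.zeros((9, 9, 9)), np.zeros((9, 9, 9)), SMALL, geom)
        assert np.abs(pmap.values).max() == 0.0

    def test_charge_negation_negates_potential(self):
        params = SolverParams(npts=17)
        geom = GridGeometry(center=(0, 0, 0), npts=17, spacing=0.5)
        plus = solve_system(ion(q=1.0), params, geom)
        minus = solve_system(ion(q=-1.0), params, geom)
        np.testing.assert_allclose(plus.values, -minus.values, atol=1e-9)

    def test_nonconvergence_raises_with_history(self):
        params = SolverParams(npts=17, max_iter=3, tol=1e-12)
        geom = GridGeometry(center=(0, 0, 0), npts=17, spacing=0.5)
        with pytest.raises(ConvergenceError) as err:
            solve_system(ion(), params, geom)
        assert len(err.value.history) == 3

    def test_residual_reported_small(self):
        params = SolverParams(npts=17, tol=1e-8)
        geom = GridGeometry(center=(0, 0, 0), npts=17, spacing=0.5)
        pmap = solve_system(ion(), params, geom)
        # discrete-operator residual scales with tol, far below the solution
        assert pmap.provenance["max_residual"] < 1e-2


class TestAnalytic:
    def test_refinement_ladder_monotone(self):
        """Halving the spacing on a fixed box reduces the Born analytic
        error (17 -> 33 -> 65 points).  Salt-free, so the analytic far
        field equals the boundary condition exactly and discretization is
        the only error source."""
        params = SolverParams(
            npts=17, probe_radius=0.4, stern_radius=0.6, tol=1e-7,
            ionic_strength=0.0,
        )
        system = ion(radius=1.0)
        rs = np.linspace(2.2, 2.8, 5)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        analytic = born_screened_potential(rs, 1.0, 1.0, params)
        errors = []
        for npts in (17, 33, 65):
            geom = GridGeometry(center=(0, 0, 0), npts=npts, spacing=6.0 / (npts - 1))
            pmap = solve_system(system, params, geom)
            err = np.abs(pmap.interpolate(pts) - analytic) / np.abs(analytic)
            errors.append(float(err.max()))
        assert errors[0] > errors[1] > errors[2]

    def test_debye_screening_decay_length(self):
        """Fitted far-field decay of r*phi matches the analytic Debye
        length within 15%."""
        params = SolverParams(npts=65, tol=1e-8)
        system = ion(radius=1.0)
        geom = GridGeometry(center=(0, 0, 0), npts=65, spacing=0.5)
        pmap = solve_system(system, params, geom)
        rs = np.linspace(6.0, 13.0, 15)
        pts = np.column_stack([rs, np.zeros_like(rs), np.zeros_like(rs)])
        phi = pmap.interpolate(pts)
        slope = np.polyfit(rs, np.log(rs * phi), 1)[0]
        fitted_length = -1.0 / slope
        analytic = debye_length(params)
        assert abs(fitted_length - analytic) / analytic < 0.15


class TestFocusing:
    def test_zero_system_zero_both_stages(self):
        params = SolverParams(npts=9)
        system = ChargeSystem(np.zeros((1, 3)), [0.0], [1.0])
        pmap = focused_solve(system, params)
        assert np.abs(pmap.values).max() == 0.0

    def test_fine_boundary_is_interpolated_coarse_map(self):
        params = SolverParams(npts=17)
        system = ion()
        coarse_geom = grid_for_system(system, params, params.fill_coarse)
        coarse = solve_system(system, params, coarse_geom)
        fine = focused_solve(system, params)
        fine_geom = grid_for_system(system, params, params.fill_fine)
        xs, ys, zs = fine_geom.axes()
        # spot-check corner and face-center boundary nodes
        spots = [
            (xs[0], ys[0], zs[0]),
            (xs[-1], ys[8], zs[3]),
            (xs[5], ys[0], zs[12]),
            (xs[7], ys[16], zs[7]),
        ]
        expected = coarse.interpolate(np.array(spots))
        ix = {v: i for i, v in enumerate(xs)}
        for (x, y, z), want in zip(spots, expected):
            i = np.argmin(np.abs(xs - x))
            j = np.argmin(np.abs(ys - y))
            k = np.argmin(np.abs(zs - z))
            assert fine.values[i, j, k] == pytest.approx(want, rel=1e-9)

    def test_focusing_metadata_recorded(self):
        params = SolverParams(npts=17)
        pmap = focused_solve(ion(), params)
        assert "focused_from" in pmap.provenance


class TestClassifyPocket:
    def zero_map(self):
        from hladr.pb import PotentialMap

        return PotentialMap(
            values=np.zeros((9, 9, 9)), origin=np.full(3, -4.0), spacing=1.0
        )

    def test_zero_map_neutral(self):
        cls = classify_pocket(self.zero_map(), np.zeros((1, 3)))
        assert cls.label == "neutral"
        assert cls.mean_potential == 0.0

    def test_empty_patch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_pocket(self.zero_map(), np.empty((0, 3)))

    def test_buried_charge_sign_and_antisymmetry(self):
        params = SolverParams(npts=33)
        patch = np.array([[0.0, 0.0, 3.0], [0.5, 0.0, 3.0], [0.0, 0.5, 3.0]])
        plus = focused_solve(ion(q=1.0), params)
        minus = focused_solve(ion(q=-1.0), params)
        cls_plus = classify_pocket(plus, patch)
        cls_minus = classify_pocket(minus, patch)
        assert cls_plus.label == "positive"
        assert cls_minus.label == "negative"
        assert cls_plus.mean_potential == pytest.approx(
            -cls_minus.mean_potential, rel=1e-9
        )

    def test_patch_file_parsing(self):
        patch = read_patch("# pocket\n0 0 3\n0.5, 0, 3\n")
        assert patch.shape == (2, 3)
        with pytest.raises(ValueError, match="3 coordinates"):
            read_patch("1 2\n")
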