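import numpy as np
import pytest

from rhizoflow.phase_io import AIR, SOIL, WATER, PhaseVolume
from rhizoflow.rev_sampling import REVSample, reflect
from rhizoflow.stokes_cell import (
    GRAVITY,
    MU,
    RHO,
    assemble_conductivity,
    darcy_velocity,
    flow_domain,
    solve_cell_problem,
    solve_conductivity,
)
from rhizoflow.synthetic_geometry import SyntheticSpec, generate_sand_like

from conftest import duct_mask, duct_mean_velocity_coefficient, poiseuille_slab_mask


class TestFlowDomain:
    def test_saturated_channel_mask_equals_pore(self, channel_volume):
        dom = flow_domain(channel_volume)
        np.testing.assert_array_equal(dom.mask, channel_volume.pore_mask)
        assert dom.percolates[0]  # spans the vertical axis

    def test_isolated_droplet_flagged(self):
        labels = np.zeros((12, 12, 12), dtype=np.uint8)
        labels[5:7, 5:7, 5:7] = WATER
        dom = flow_domain(PhaseVolume(labels, 10.0))
        assert not any(dom.percolates.values())
        assert dom.n_isolated == 1

    def test_air_core_leaves_annulus(self, channel_volume):
        labels = channel_volume.labels.copy()
        yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        core = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 2.5**2
        labels[:, core] = AIR
        vol = PhaseVolume(labels, 10.0)
        dom = flow_domain(vol)
        np.testing.assert_array_equal(dom.mask, vol.water_mask)
        assert not dom.mask[:, core].any()  # air is a rigid obstacle


class TestCellProblemBasics:
    def test_empty_mask_zero_solution(self):
        sol = solve_cell_problem(np.zeros((8, 8, 8), bool), 0)
        assert sol.n_unknowns == 0
        np.testing.assert_array_equal(sol.mean_velocity, 0.0)

    def test_all_fluid_rejected(self):
        with pytest.raises(ValueError, match="all-fluid"):
            solve_cell_problem(np.ones((8, 8, 8), bool), 0)

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError, match="tolerance"):
            solve_cell_problem(np.ones((8, 8, 8), bool), 0, tolerance=0.0)

    def test_no_slip_on_interface_and_low_divergence(self, sand16):
        sol = solve_cell_problem(sand16.water_mask, 0, method="direct")
        assert sol.max_divergence < 1e-9
        # faces touching solid carry exactly zero velocity
        solid = ~sand16.water_mask
        u = sol.u_faces[0]
        # u_z face grid (17,16,16): face i flanks cells i-1, i
        interior = u[1:-1]
        touching = solid[:-1] | solid[1:]
        assert np.abs(interior[touching]).max() == 0.0

    def test_isolated_pocket_carries_no_flow(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:7, 4:7, 4:7] = True
        sol = solve_cell_problem(mask, 0, method="direct")
        assert np.abs(sol.mean_velocity).max() < 1e-12


class TestAnalyticOracles:
    def test_poiseuille_slab_matches_closed_form(self):
        # discrete MAC solution of a slab is phi*(a^2+2)/12 exactly;
        # continuum limit phi*a^2/12 within 5% from 16 voxels up
        a = 16
        mask = poiseuille_slab_mask(a)
        sol = solve_cell_problem(mask, 2, method="direct")
        phi = mask.mean()
        assert sol.mean_velocity[2] == pytest.approx(phi * (a**2 + 2) / 12, rel=1e-9)
        assert sol.mean_velocity[2] == pytest.approx(phi * a**2 / 12, rel=0.05)

    def test_square_duct_matches_series_solution(self):
        a = 32
        c = duct_mean_velocity_coefficient()
        mask = duct_mask(a)
        sol = solve_cell_problem(mask, 0, method="direct")
        phi = mask.mean()
        assert sol.mean_velocity[0] == pytest.approx(phi * c * a**2, rel=0.05)

    def test_poiseuille_physical_units(self):
        # slab occupying fraction phi of the cell: K_kk -> phi a^2/(12 mu)
        a, dx_um = 16, 25.0
        mask = poiseuille_slab_mask(a)
        sol = solve_cell_problem(mask, 2, method="direct")
        res = assemble_conductivity([sol], voxel_size_um=dx_um)
        phi = mask.mean()
        a_m = a * dx_um * 1e-6
        assert res.K[2, 2] == pytest.approx(phi * a_m**2 / (12 * MU), rel=0.01)


class TestReflectionEquivalence:
    def test_symmetric_equals_periodic_on_reflection(self, sand16):
        sample = REVSample(sand16, (0, 0, 0))
        refl = reflect(sample)
        for k in range(3):
            sym = solve_cell_problem(
                sand16.water_mask, k, mode="symmetric", method="direct",
                keep_fields=False,
            )
            per = solve_cell_problem(
                refl.water_mask, k, mode="periodic", method="minres",
                tolerance=1e-10, keep_fields=False,
            )
            assert sym.mean_velocity[k] == pytest.approx(
                per.mean_velocity[k], rel=1e-6
            )


class TestTensorProperties:
    def test_diagonal_nonnegative_random_geometries(self):
        for seed in range(4):
            spec = SyntheticSpec(
                texture="sand_like",
                grid_shape=(16, 16, 16),
                target_porosity=0.4,
                rng_seed=seed + 20,
            )
            mask = generate_sand_like(spec).water_mask
            for k in range(3):
                sol = solve_cell_problem(mask, k, method="direct", keep_fields=False)
                assert sol.mean_velocity[k] >= -1e-12

    def test_periodic_full_tensor_symmetric(self, sand16):
        res = solve_conductivity(
            sand16.water_mask, voxel_size_um=1.0, mode="periodic", method="direct"
        )
        K = res.K
        tr = np.trace(K) / 3
        for j in range(3):
            for k in range(j + 1, 3):
                assert abs(K[j, k] - K[k, j]) <= 1e-8 * max(tr, 1e-30)

    def test_nested_domain_monotonicity(self, sand16):
        big = sand16.water_mask
        small = big.copy()
        small[6:10, 6:10, 6:10] = False  # carve solid out of the water domain
        for k in range(3):
            kb = solve_cell_problem(big, k, method="direct", keep_fields=False)
            ks = solve_cell_problem(small, k, method="direct", keep_fields=False)
            assert ks.mean_velocity[k] <= kb.mean_velocity[k] * (1 + 1e-9) + 1e-15


class TestAssembleConductivity:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no solutions"):
            assemble_conductivity([], 10.0)

    def test_length_scaling_quadratic(self):
        mask = poiseuille_slab_mask(8)
        sol = solve_cell_problem(mask, 2, method="direct")
        k1 = assemble_conductivity([sol], voxel_size_um=10.0).K[2, 2]
        k2 = assemble_conductivity([sol], voxel_size_um=20.0).K[2, 2]
        assert k2 == pytest.approx(4 * k1, rel=1e-12)

    def test_inconsistent_shapes_rejected(self):
        s1 = solve_cell_problem(poiseuille_slab_mask(8), 2, method="direct")
        s2 = solve_cell_problem(poiseuille_slab_mask(10), 1, method="direct")
        with pytest.raises(ValueError, match="inconsistent"):
            assemble_conductivity([s1, s2], 10.0)

    def test_hydraulic_conductivity_units(self):
        mask = poiseuille_slab_mask(8)
        sol = solve_cell_problem(mask, 2, method="direct")
        res = assemble_conductivity([sol], voxel_size_um=10.0)
        assert res.K_h_cm_s[2] == pytest.approx(RHO * GRAVITY * res.K[2, 2] * 100)


class TestDarcyVelocity:
    @pytest.fixture()
    def result(self):
        sol = solve_cell_problem(poiseuille_slab_mask(8), 2, method="direct")
        return assemble_conductivity([sol], voxel_size_um=10.0)

    def test_hydrostatic_gradient_balances_gravity(self, result):
        grad = np.array([RHO * GRAVITY, 0.0, 0.0])
        np.testing.assert_allclose(darcy_velocity(result, grad), 0.0, atol=1e-20)

    def test_zero_gradient_gives_gravity_driven_flow(self, result):
        u = darcy_velocity(result, np.zeros(3))
        np.testing.assert_allclose(u, result.K @ np.array([RHO * GRAVITY, 0, 0]))

    def test_zero_conductivity_gives_zero_velocity(self, result):
        result.K = np.zeros((3, 3))
        np.testing.assert_allclose(darcy_velocity(result, np.array([5.0, 1.0, 2.0])), 0.0)
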