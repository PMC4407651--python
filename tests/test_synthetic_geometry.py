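import numpy as np
import pytest
from scipy import ndimage

from rhizoflow.phase_io import AIR, SOIL, WATER, PhaseVolume
from rhizoflow.synthetic_geometry import (
    DrainageSchedule,
    SyntheticSpec,
    apply_drainage,
    drainage_series,
    generate_clay_like,
    generate_sand_like,
    histogram_modes,
    local_pore_radius,
    pore_radius_histogram,
)


class TestSpecValidation:
    def test_porosity_bounds(self):
        with pytest.raises(ValueError, match="target_porosity"):
            SyntheticSpec(target_porosity=1.0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_shape"):
            SyntheticSpec(grid_shape=(8, 32, 32))

    def test_unresolvable_crack_rejected(self):
        with pytest.raises(ValueError, match="crack"):
            SyntheticSpec(crack_aperture_range=(1.0, 4.0), voxel_size_um=1.0)


class TestDrainageSchedule:
    def test_must_start_saturated(self):
        with pytest.raises(ValueError, match="0 kPa"):
            DrainageSchedule(potentials_kpa=(-5.0, -10.0))

    def test_strictly_decreasing(self):
        with pytest.raises(ValueError, match="decreasing"):
            DrainageSchedule(potentials_kpa=(0.0, -10.0, -5.0))

    def test_critical_radius_young_laplace(self):
        sched = DrainageSchedule()
        # r_c = 2*0.072/ (5 kPa) = 28.8 um
        assert sched.critical_radius_um(-5.0) == pytest.approx(28.8)
        assert np.isinf(sched.critical_radius_um(0.0))
        with pytest.raises(ValueError):
            sched.critical_radius_um(1.0)


class TestSandLike:
    def test_porosity_and_saturation(self):
        spec = SyntheticSpec(
            texture="sand_like", grid_shape=(64, 64, 64), target_porosity=0.45, rng_seed=1
        )
        vol = generate_sand_like(spec)
        assert 0.42 <= vol.porosity <= 0.48
        # pore space fully water-filled at generation
        assert not vol.air_mask.any()
        assert ((vol.labels == SOIL) | (vol.labels == WATER)).all()

    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticSpec(
            texture="sand_like", grid_shape=(32, 32, 32), target_porosity=0.45, rng_seed=9
        )
        a = generate_sand_like(spec)
        b = generate_sand_like(spec)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_oversized_grains_rejected(self):
        spec = SyntheticSpec(
            texture="sand_like",
            grid_shape=(16, 16, 16),
            grain_radius_range=(20.0, 30.0),
            rng_seed=0,
        )
        with pytest.raises(ValueError, match="grain"):
            generate_sand_like(spec)

    def test_wrong_texture_rejected(self):
        spec = SyntheticSpec(texture="clay_like")
        with pytest.raises(ValueError, match="sand_like"):
            generate_sand_like(spec)


@pytest.fixture(scope="module")
def clay():
    spec = SyntheticSpec(
        texture="clay_like", grid_shape=(64, 64, 64), target_porosity=0.45, rng_seed=2
    )
    return generate_clay_like(spec)


class TestClayLike:
    def test_porosity(self, clay):
        assert abs(clay.porosity - 0.45) <= 0.03

    def test_exactly_three_planar_cracks(self, clay):
        # crack-scale pore space labels into exactly crack_count objects
        lt = local_pore_radius(clay.pore_mask)
        cracks = lt >= 3.5
        _, n = ndimage.label(cracks, structure=np.ones((3, 3, 3), bool))
        assert n == 3

    def test_bimodal_pore_radius_histogram(self, clay):
        counts, _ = pore_radius_histogram(clay)
        assert histogram_modes(counts) == 2

    def test_no_cracks_gives_unimodal_histogram(self):
        spec = SyntheticSpec(
            texture="clay_like",
            grid_shape=(48, 48, 48),
            target_porosity=0.35,
            crack_count=0,
            rng_seed=4,
        )
        vol = generate_clay_like(spec)
        counts, _ = pore_radius_histogram(vol)
        assert histogram_modes(counts) == 1

    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticSpec(
            texture="clay_like", grid_shape=(48, 48, 48), target_porosity=0.42, rng_seed=5
        )
        a = generate_clay_like(spec)
        b = generate_clay_like(spec)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestLocalPoreRadius:
    def test_cylinder_radius(self, channel_volume):
        lt = local_pore_radius(channel_volume.pore_mask)
        inside = lt[channel_volume.pore_mask]
        # digitized radius-5 channel: inscribed radius between 3 and 7
        assert inside.min() > 3.0
        assert inside.max() < 7.0
        # uniform along the channel (local thickness, not wall distance)
        assert inside.max() - inside.min() < 1.0

    def test_empty_mask(self):
        lt = local_pore_radius(np.zeros((8, 8, 8), bool))
        assert (lt == 0).all()


class TestDrainage:
    def test_saturation_potential_leaves_volume_unchanged(self, channel_volume):
        out = apply_drainage(channel_volume, 0.0)
        np.testing.assert_array_equal(out.labels, channel_volume.labels)

    def test_channel_drains_when_rc_below_radius(self, channel_volume):
        # voxel 10 um; channel radius ~5 voxels = 50 um
        # r_c = 30 um (3 voxels): |P| = 2*0.072/30e-6 Pa = 4.8 kPa
        out = apply_drainage(channel_volume, -4.8)
        assert not out.water_mask.any()
        assert out.air_mask.sum() == channel_volume.water_mask.sum()

    def test_channel_stays_wet_when_rc_above_radius(self, channel_volume):
        # r_c = 70 um (7 voxels): |P| ~ 2.057 kPa
        out = apply_drainage(channel_volume, -2.057)
        assert not out.air_mask.any()

    def test_positive_potential_rejected(self, channel_volume):
        with pytest.raises(ValueError, match="non-positive"):
            apply_drainage(channel_volume, 1.0)

    def test_subvoxel_rc_warns_and_fully_drains_connected(self, channel_volume):
        with pytest.warns(UserWarning, match="below one voxel"):
            out = apply_drainage(channel_volume, -75.0)
        assert not out.water_mask.any()

    def test_disconnected_pore_does_not_drain(self):
        labels = np.zeros((16, 16, 16), dtype=np.uint8)
        labels[6:10, 6:10, 6:10] = WATER  # enclosed pocket, no path to top
        vol = PhaseVolume(labels, 10.0)
        out = apply_drainage(vol, -4.8)
        assert not out.air_mask.any()

    def test_series_invariants(self):
        spec = SyntheticSpec(
            texture="sand_like", grid_shape=(48, 48, 48), target_porosity=0.45, rng_seed=6
        )
        vol = generate_sand_like(spec)
        series = drainage_series(vol)
        water = [v.water_mask.sum() for v in series]
        # monotone non-increasing water volume
        assert all(b <= a for a, b in zip(water, water[1:]))
        for v in series:
            counts = v.phase_counts()
            # exact phase partition
            assert sum(counts.values()) == v.labels.size
            # solid phase invariant under drainage
            np.testing.assert_array_equal(v.soil_mask, series[0].soil_mask)
        # air never reverts to water down the schedule
        for a, b in zip(series, series[1:]):
            assert not (a.air_mask & b.water_mask).any()

    def test_clay_retains_more_than_sand_at_minus75(self):
        kw = dict(grid_shape=(48, 48, 48), target_porosity=0.42)
        sand = generate_sand_like(
            SyntheticSpec(texture="sand_like", rng_seed=1, **kw)
        )
        clay = generate_clay_like(
            SyntheticSpec(texture="clay_like", rng_seed=1, **kw)
        )
        assert abs(sand.porosity - clay.porosity) < 0.02  # matched porosity
        sand75 = drainage_series(sand)[-1]
        clay75 = drainage_series(clay)[-1]
        assert clay75.water_fraction > sand75.water_fraction
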