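import numpy as np
import pytest

from rhizoflow.phase_io import (
    AIR,
    SOIL,
    WATER,
    GreyscaleVolume,
    PhaseVolume,
    export_stl,
    filter_noise,
    read_volume,
    segment_threshold,
    write_volume,
)


@pytest.fixture()
def small_phase(rng=np.random.default_rng(0)):
    labels = rng.integers(0, 3, (16, 16, 16)).astype(np.uint8)
    return PhaseVolume(labels, 10.17, potential_kpa=-5.0, meta={"seed": 0})


class TestRoundTrip:
    def test_phase_volume_round_trip(self, small_phase, tmp_path):
        path = tmp_path / "vol.tif"
        write_volume(small_phase, path)
        back = read_volume(path)
        assert isinstance(back, PhaseVolume)
        np.testing.assert_array_equal(back.labels, small_phase.labels)
        assert back.voxel_size_um == small_phase.voxel_size_um
        assert back.potential_kpa == small_phase.potential_kpa
        assert back.meta["seed"] == 0

    def test_greyscale_round_trip_preserves_range(self, tmp_path):
        rng = np.random.default_rng(1)
        data = rng.uniform(-3.5, 7.25, (8, 8, 8)).astype(np.float32)
        grey = GreyscaleVolume(data, 10.17, water_ref_grey=0.0, soil_ref_grey=5.0)
        path = tmp_path / "grey.tif"
        write_volume(grey, path)
        back = read_volume(path)
        assert isinstance(back, GreyscaleVolume)
        np.testing.assert_array_equal(back.intensities, data)
        assert back.intensities.min() == data.min()
        assert back.intensities.max() == data.max()

    def test_missing_sidecar_errors(self, small_phase, tmp_path):
        path = tmp_path / "vol.tif"
        write_volume(small_phase, path)
        (tmp_path / "vol.tif.json").unlink()
        with pytest.raises(FileNotFoundError, match="sidecar"):
            read_volume(path)

    def test_raw_round_trip(self, tmp_path):
        import json

        data = np.arange(64, dtype=np.uint8).reshape(4, 4, 4) % 3
        raw = tmp_path / "vol.raw"
        data.tofile(raw)
        with open(tmp_path / "vol.raw.json", "w") as fh:
            json.dump(
                {
                    "kind": "phase",
                    "voxel_size_um": 5.0,
                    "dtype": "uint8",
                    "shape": [4, 4, 4],
                },
                fh,
            )
        back = read_volume(raw)
        np.testing.assert_array_equal(back.labels, data)


class TestValidation:
    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            PhaseVolume(np.full((4, 4, 4), 7, dtype=np.uint8), 10.0)

    def test_nonpositive_voxel_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            PhaseVolume(np.zeros((4, 4, 4), dtype=np.uint8), 0.0)

    def test_inverted_reference_greys_rejected(self):
        with pytest.raises(ValueError, match="[Rr]eference"):
            GreyscaleVolume(np.zeros((4, 4, 4)), 10.0, water_ref_grey=5.0, soil_ref_grey=1.0)


class TestSegmentation:
    @staticmethod
    def _three_level(shape=(24, 24, 24), seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 3, shape).astype(np.uint8)
        greys = {AIR: 0.0, WATER: 100.0, SOIL: 200.0}
        img = np.vectorize(greys.get)(labels).astype(float)
        if noise:
            img += rng.normal(0, noise, shape)
        return labels, GreyscaleVolume(img, 10.17, water_ref_grey=100.0, soil_ref_grey=200.0)

    def test_noiseless_exact_recovery(self):
        labels, grey = self._three_level()
        seg = segment_threshold(grey, air_ref_grey=0.0)
        np.testing.assert_array_equal(seg.labels, labels)

    def test_noisy_recovery_above_99_percent(self):
        # sigma = 10% of the 100-grey class separation
        labels, grey = self._three_level(seed=2, noise=10.0)
        seg = segment_threshold(grey, air_ref_grey=0.0)
        agreement = (seg.labels == labels).mean()
        assert agreement >= 0.99

    def test_default_air_reference_from_histogram(self):
        labels, grey = self._three_level(seed=3, noise=5.0)
        seg = segment_threshold(grey)
        assert (seg.labels == labels).mean() >= 0.99

    def test_air_reference_above_water_errors(self):
        _, grey = self._three_level()
        with pytest.raises(ValueError, match="air reference"):
            segment_threshold(grey, air_ref_grey=150.0)


class TestNoiseFilter:
    def test_isolated_voxel_relabelled_to_majority(self):
        labels = np.zeros((9, 9, 9), dtype=np.uint8)  # all soil
        labels[4, 4, 4] = WATER
        out = filter_noise(PhaseVolume(labels, 10.17), mode="3D")
        assert out.labels[4, 4, 4] == SOIL

    def test_three_voxel_cube_retained(self):
        # (3 * 0.01017 mm)^3 ~ 2.8e-5 mm^3 exceeds the 8e-6 mm^3 cutoff
        labels = np.zeros((9, 9, 9), dtype=np.uint8)
        labels[3:6, 3:6, 3:6] = WATER
        out = filter_noise(PhaseVolume(labels, 10.17), mode="3D")
        assert (out.labels == WATER).sum() == 27

    def test_clean_slab_unchanged(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[:, :4] = WATER
        vol = PhaseVolume(labels, 10.17)
        out = filter_noise(vol, mode="3D")
        np.testing.assert_array_equal(out.labels, labels)

    def test_2d_mode_removes_thin_slice_objects(self):
        labels = np.zeros((4, 16, 16), dtype=np.uint8)
        labels[2, 8, 8] = AIR  # single pixel in its slice
        out = filter_noise(PhaseVolume(labels, 10.17), mode="2D")
        assert out.labels[2, 8, 8] == SOIL

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        labels = (rng.random((16, 16, 16)) < 0.1).astype(np.uint8)  # water specks
        once = filter_noise(PhaseVolume(labels, 10.17), mode="3D")
        twice = filter_noise(once, mode="3D")
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_volume_conserved_and_soil_only_grows_by_specks(self):
        rng = np.random.default_rng(8)
        labels = np.where(rng.random((16, 16, 16)) < 0.05, WATER, SOIL).astype(np.uint8)
        vol = PhaseVolume(labels, 10.17)
        out = filter_noise(vol, mode="3D")
        assert out.labels.size == vol.labels.size
        # soil voxels never turn into pore
        assert not ((vol.labels == SOIL) & (out.labels != SOIL)).any()

    def test_tie_breaks_toward_water(self):
        # air speck with equal water and soil neighbour counts -> water
        labels = np.zeros((3, 3, 5), dtype=np.uint8)
        labels[1, 1, 1] = WATER
        labels[1, 1, 3] = WATER
        labels[1, 1, 2] = AIR
        out = filter_noise(PhaseVolume(labels, 10.17), mode="3D")
        assert out.labels[1, 1, 2] in (WATER, SOIL)
        # the speck has 2 water + 4 soil face neighbours: majority soil
        labels2 = np.zeros((3, 3, 3), dtype=np.uint8)
        labels2[1, 1, 1] = AIR  # 6 soil neighbours
        out2 = filter_noise(PhaseVolume(labels2, 10.17), mode="3D")
        assert out2.labels[1, 1, 1] == SOIL


def test_export_stl_writes_mesh(tmp_path, sand16):
    path = tmp_path / "water.stl"
    export_stl(sand16, WATER, path)
    assert path.exists() and path.stat().st_size > 100
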