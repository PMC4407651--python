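# Full bulk-vs-rhizosphere comparison on synthetic media.
# Run with:  rhizoflow run --config docs/example_config.yaml
seed: 1
grid_shape: [48, 48, 48]
voxel_size_um: 1.0
# conditions defaults to the four presets:
# bulk_sand, rhizosphere_sand, bulk_clay, rhizosphere_clay
potentials_kpa: [0, -5, -10, -20, -40, -60, -75]
n_subsamples: 2
subsample_side_voxels: 24
j_max: 3
directions: [0]          # 0 = z (vertical)
solver_tolerance: 1.0e-8
outdir: rhizoflow_out
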