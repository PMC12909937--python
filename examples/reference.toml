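# Reference actuation conditions: 25 nm cubes (69 emu/g) in a 359.2 nm
# lysosome filled with 471.1 cP fluid, driven at 260 mT.
# Every key is optional; unknown keys are rejected.
seed = 1
output_dir = "lysoflow_output"

[nanoparticle]
edge_length_nm = 25.0
saturation_magnetization_emu_g = 69.0
mass_density_kg_m3 = 5180.0

[field]
amplitude_mt = 260.0
frequencies_hz = [0.2, 0.8, 1.0, 2.0, 5.0]

[lysosome]
radius_nm = 359.2
viscosity_cp = 471.1

[assembly]
bond_strength_scale = 1.0
geometric_fill_fraction = 0.7

[solver]
resolution = 1.0

[synthetic]
radius_mean_nm = 379.0
radius_cv = 0.25
frequencies_hz = [180.0, 240.0, 300.0, 360.0]
n_obs_per_frequency = 50
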