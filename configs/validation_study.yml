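# Validation-study analogue: a small scaffold column (0.64 mm cube at
# 10 um voxels standing in for a 1.5 mm-diameter x 1.0 mm scaffold
# sub-section) with one central RVE of half the footprint. The RVE/pore
# ratio (~4) matches the physical study the defaults emulate.
fluid:
  mu_mPa_s: 1.0
  rho_kg_m3: 1000.0
geometry:
  source: generate
  generator:
    porosity: 0.8
    mean_pore_diameter_um: 80.0
    shape: [64, 64, 64]
    voxel_size_um: 10.0
    seed: 1
rve:
  grid: [1, 1]
  xy_size_um: 320.0
micro:
  inlet_velocity_um_s: 500.0
  permeability_probe_dp_Pa: 0.5
  tol: 1.0e-4
macro:
  entrance_heights: 1.0
  exit_heights: 1.0
  cells_across_height: 24
  wall_condition: no_slip
wss:
  surface_model: smoothed-normal
  bin_width_mPa: 5.0
  max_mPa: 100.0
  weighting: area
  bands_mPa: [[0.11, 10.0], [0.55, 24.0], [10.0, 30.0]]
  subregion_count: 5
  subregion_width_um: 32.0
output_dir: out_validation
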