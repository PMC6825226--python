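# Large-scaffold analogue: a 0.96 x 0.96 x 0.48 mm synthetic scaffold
# (standing in for a 5 mm-diameter x 2 mm specimen) sampled by a 3x3 grid
# of isometric RVEs spanning the full height. The flow rate preserves the
# superficial velocity of 3 mL/min through a 5 mm-diameter bioreactor
# channel (~2.55 mm/s) at the scaled-down cross-section.
fluid:
  mu_mPa_s: 1.0
  rho_kg_m3: 1000.0
geometry:
  source: generate
  generator:
    porosity: 0.8
    mean_pore_diameter_um: 80.0
    shape: [96, 96, 48]
    voxel_size_um: 10.0
    seed: 1
rve:
  grid: [3, 3]
  xy_size_um: 240.0
micro:
  inlet_velocity_um_s: 500.0
  permeability_probe_dp_Pa: 0.5
  tol: 1.0e-4
macro:
  flow_rate_mL_min: 0.141
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
  subregion_width_um: 40.0
output_dir: out_large
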