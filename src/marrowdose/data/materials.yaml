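# Material and calibration defaults for marrowdose.
# Every value here is a configurable default; densities are the standard
# spongiosa constituent densities, the HU calibration is a generic
# water-anchored bilinear curve (instrument calibrations are site-specific),
# and the cellularity tables are approximate adult reference values.

densities:        # g/mL
  rho_rm: 1.03
  rho_ym: 0.98
  rho_bone: 1.92
  rho_tumor: 1.00

calibration:      # bilinear HU -> g/mL
  breakpoint_hu: 100.0
  soft_slope: 0.001       # g/mL per HU, soft-tissue segment through (0, 1.0)
  soft_intercept: 1.0
  bone_slope: 0.0005      # shallower bone segment, continuous at breakpoint

site_cellularity:          # adult reference marrow cellularity per site
  cervical_spine: 0.70
  thoracic_spine: 0.70
  lumbar_spine: 0.70
  sacrum: 0.70
  ribs: 0.70
  sternum: 0.70
  hips: 0.48
  clavicles: 0.33
  scapulae: 0.38
  skull: 0.38
  humeri: 0.25
  femurs: 0.25

age_cellularity:           # age (years) -> reference L2 cellularity
  - [0, 0.95]
  - [10, 0.80]
  - [20, 0.70]
  - [40, 0.60]
  - [60, 0.50]
  - [80, 0.40]

refine:                    # spongiosa mask refinement defaults
  hu_threshold: 800.0
  erosion_mm: 0.0
  min_island_voxels: 0
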