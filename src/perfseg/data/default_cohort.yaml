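# Default synthetic cohort configuration.
#
# One editable block: every group-level generator parameter lives here so
# cohort experiments are configuration, not code.  Stress/rest ratios are
# the prescribed ground-truth perfusion-reserve values per sector class;
# noise_sd_fraction is additive Gaussian pixel noise as a fraction of the
# AIF peak (no published acquisition-noise estimate exists for this
# protocol; 0.05 is a stated choice).

seed: 42

n_per_group:
  control: 9
  hcm_risk: 15
  hcm: 12

image:
  shape: [64, 64]
  pixel_spacing_mm: 2.0
  slice_thickness_mm: 10.0
  lge_slice_thickness_mm: 8.0
  n_contour_points: 96
  rv_insertion_deg: 150.0      # anterior RV insertion: 12 o'clock minus 60 deg

timing:
  frame_interval_s: 1.0
  n_frames: 60
  bolus_arrival_s: 10.0

aif:
  amplitude: 1.0
  alpha: 3.0
  beta: 2.0
  baseline: 0.1

tissue:
  k_rest: 0.5                  # rest transfer factor, all sectors
  delay_s: 0.0
  smoothing_width: 1
  baseline: 0.05

noise_sd_fraction: 0.05

lge:
  remote_mean: 100.0
  remote_sd: 5.0
  scar_contrast_sd: 10.0       # scar mean = remote + this many SD
  blood_mean: 180.0

levels:
  basal:  {endo_radius_px: 12.0, slice_position_mm: 10.0}
  mid:    {endo_radius_px: 11.0, slice_position_mm: 20.0}
  apical: {endo_radius_px: 9.0,  slice_position_mm: 30.0}

groups:
  control:
    age_range: [16, 30]
    septal_thickness_mm: 9.0
    free_wall_thickness_mm: 8.0
    septal_segments: [2, 3, 8, 9, 14]
    lvh_segments: []
    stress_rest_ratio: 2.1
    subject_jitter_sd: 0.08
    sector_jitter_sd: 0.03
    ejection_fraction: 57.0
    n_scar_segments: 0
  hcm_risk:
    age_range: [14, 26]
    septal_thickness_mm: 8.5
    free_wall_thickness_mm: 7.5
    septal_segments: [2, 3, 8, 9, 14]
    lvh_segments: []
    stress_rest_ratio: 2.2
    subject_jitter_sd: 0.10
    sector_jitter_sd: 0.03
    ejection_fraction: 57.0
    n_scar_segments: 0
  hcm:
    age_range: [12, 30]
    septal_thickness_mm: 17.0
    free_wall_thickness_mm: 8.0
    septal_segments: [2, 3, 8, 9, 14]
    lvh_segments: [2, 3, 8, 9, 14]
    stress_rest_ratio: 2.0       # LVH- LGE- sectors
    lvh_stress_rest_ratio: 1.5   # LVH+ LGE- sectors
    scar_stress_rest_ratio: 0.9  # LVH+ LGE+ sectors
    subject_jitter_sd: 0.08
    sector_jitter_sd: 0.03
    ejection_fraction: 62.0
    n_scar_segments: 2
    scar_angular_fraction: 0.6
    scar_transmural: [0.3, 0.7]
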