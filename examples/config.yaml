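# Example run configuration: every pipeline and generator knob.
# Use with e.g.  uvcoverage run-all --config examples/config.yaml --out out/
seed: 42
n_participants: 84
image_dims: [128, 128]

# region geometry (fractions are of eye width / canthus side)
region_params:
  forehead_margin: 1.0
  lateral_margin_frac: 0.10
  canthus_inner_frac: 0.60
  canthus_eye_cap_frac: 0.25
  nasal_offset_frac: 0.25

# per-participant threshold T = max(mu - k*sigma, floor)
calibration_k: 3.0
calibration_floor: 0.0

# segmentation cleanup (0 disables either step)
min_blob: 5
close_radius: 1

# medial canthus scored covered iff covered fraction >= tau
tau: 0.95

# statistics: nonparametric fallback (mannwhitney | wilcoxon), ANCOVA SS type
nonparametric: mannwhitney
ss_type: 2

# mg-equivalents driving image darkening per formulation
applied_mass:
  sunscreen: 100.0
  moisturiser: 75.0

# study population (omit to use the built-in defaults shown here)
population:
  n_participants: 84
  rho: 0.5
  sex_effect: -5.0
  skin_type_effect: -6.0
  canthus_missed_rate: 0.78
  seed: 42
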