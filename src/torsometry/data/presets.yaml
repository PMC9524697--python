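# Named synthetic-torso scenario templates.  These are generator settings for
# a healthy torso, a single thoracic-apex curve and a double curve — scenario
# shapes for exercising the pipeline, not reproductions of any patient.
healthy:
  base_a: 150.0
  base_b: 100.0
  superellipse_exponent: 2.5
  dip_depth: 8.0
  dip_width: 8.0
  hump_amplitude: 0.0
  noise_sd: 0.5
  seed: 0
  n_points: 720

thoracic_t8:
  base_a: 150.0
  base_b: 100.0
  superellipse_exponent: 2.5
  dip_depth: 8.0
  dip_width: 8.0
  hump_amplitude: 12.0
  hump_angle: 40.0
  hump_width: 15.0
  apex_level: T8
  apex_spread: 2.0
  noise_sd: 0.5
  seed: 0
  n_points: 720

double_t9_l2:
  base_a: 150.0
  base_b: 100.0
  superellipse_exponent: 2.5
  dip_depth: 8.0
  dip_width: 8.0
  hump_amplitude: 10.0
  hump_angle: 40.0
  hump_width: 15.0
  apex_level: T9
  apex_spread: 1.5
  extra_humps:
    - amplitude: 8.0
      angle: -40.0
      width: 15.0
      apex_level: L2
      apex_spread: 1.5
  noise_sd: 0.5
  seed: 0
  n_points: 720
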