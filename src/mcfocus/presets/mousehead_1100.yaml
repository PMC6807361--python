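wavelength_tag: emission_1100
units: mm
ambient_above_n: 1.0
z_top: -0.1
layers:
- name: air
  n: 1.0
  mu_a: 0.001
  mu_s: 0.0
  g: 1.0
  thickness: 0.1
- name: skin
  n: 1.37
  mu_a: 0.35
  mu_s: 171.5
  g: 0.9
  thickness: 0.2
- name: skull
  n: 1.45
  mu_a: 0.4
  mu_s: 135.6
  g: 0.9
  thickness: 0.1
- name: csf
  n: 1.33
  mu_a: 1.0
  mu_s: 0.0
  g: 1.0
  thickness: 0.1
- name: cortex
  n: 1.368
  mu_a: 0.5
  mu_s: 71.4
  g: 0.9
  thickness: 10.0
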