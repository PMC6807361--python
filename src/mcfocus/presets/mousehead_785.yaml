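wavelength_tag: excitation_785
units: mm
ambient_above_n: 1.0
z_top: 0.0
layers:
- name: skin
  n: 1.37
  mu_a: 1.62
  mu_s: 238.9
  g: 0.9
  thickness: 0.2
- name: skull
  n: 1.454
  mu_a: 0.087
  mu_s: 162.7
  g: 0.9
  thickness: 0.1
- name: csf
  n: 1.33
  mu_a: 0.1
  mu_s: 0.0
  g: 1.0
  thickness: 0.1
- name: cortex
  n: 1.368
  mu_a: 0.087
  mu_s: 76.2
  g: 0.9
  thickness: 10.0
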