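# Polarity sorting between two concentric shells; filaments start along
# meridians (+/- e_theta).  Desk-scale smoke preset (published runs used
# 100,000 filaments between 5 and 5.102 µm shells at h = 1e-5 s).
scenario:
  name: spherical_shell
  n_filaments: 150
  n_motors: 300
  r_in: 2.0
  r_out: 2.102
  length: 0.25
  diameter: 0.025
  motor: dynein
step:
  h: 1.0e-5
  brownian: true
run:
  duration: 0.5
  seed: 1
output:
  cadence: 0.05
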