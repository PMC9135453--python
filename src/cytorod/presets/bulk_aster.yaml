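# Bulk isotropic suspension condensing into asters: end-pausing minus-end
# motors (rest length 53 nm), Brownian filaments.  Desk-scale preset:
# 120 filaments / 240 motors in a 1.86 µm periodic box at the published
# number density (published runs used 40,000 / 80,000 in 10 µm).
scenario:
  name: bulk_isotropic
  n_filaments: 120
  n_motors: 240
  box_lengths: [1.86, 1.86, 1.86]
  length: 0.5
  diameter: 0.025
  motor: aster_motor
step:
  h: 1.0e-4
  brownian: true
run:
  duration: 12.0
  seed: 1
output:
  cadence: 0.1
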