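# Antiparallel crosslinked nematic in an x-periodic tube at 30% volume
# fraction, XCTK2-like motors (walking speed 46 nm/s).  Desk-scale preset:
# 32 filaments x 10 motors/filament (published runs used 3000 filaments).
scenario:
  name: nematic_tube
  n_filaments: 32
  motors_per_filament: 10
  tube_diameter: 0.1694
  period: 1.2
  length: 0.5
  diameter: 0.025
  motor: xctk2
step:
  h: 1.0e-4
  brownian: false
run:
  duration: 12.0
  seed: 1
output:
  cadence: 0.1
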