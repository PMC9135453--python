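# Motor-filament assembly confined in an impermeable cylinder (periodic
# along x).  Dcyl/L = 1 favors polarity-sorted bilayers; Dcyl/L = 3
# (diameter 0.75) favors bottle-brush aggregates.  Desk-scale smoke preset.
scenario:
  name: confined_cylinder
  n_filaments: 60
  n_motors: 120
  cylinder_diameter: 0.25
  period: 1.5
  length: 0.25
  diameter: 0.025
  motor: aster_motor
step:
  h: 1.0e-5
  brownian: true
run:
  duration: 0.5
  seed: 1
output:
  cadence: 0.05
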