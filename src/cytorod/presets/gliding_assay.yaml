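# Surface gliding assay: one 1 µm microtubule over a carpet of 100
# surface-anchored kinesin-1 motors (all active).  Athermal filament motion;
# motor kinetics are thermal.  Velocity ≈ the free motor speed (1 µm/s).
scenario:
  name: gliding_assay
  n_motors: 100
  n_active: 100
  length: 1.0
  diameter: 0.025
  track_period: 1.0
  motor: kinesin1
step:
  h: 1.0e-4
  brownian: false
run:
  duration: 10.0
  seed: 1
output:
  cadence: 0.1
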