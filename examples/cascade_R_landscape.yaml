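family: cascade_R
window: [50.0, 100.0]
plane:
  x: [lacI, K]
  y: [tetR, K]
  bounds_x: [1.0, 4.0]
  bounds_y: [-1.5, 1.5]
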