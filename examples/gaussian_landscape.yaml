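family: gaussian
angle: 0.2617993877991494  # pi/12
bounds: [-3.0, 3.0]
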