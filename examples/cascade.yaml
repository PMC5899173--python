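input_name: arabinose (uM)
stages:
- name: araC
  role: repressor
  M: 100.0
  m: 0.2
  K: 22.0
  n: 1.0
- name: tetR
  role: repressor
  M: 100.0
  m: 4.0
  K: 25.0
  n: 5.0
- name: lacI
  role: repressor
  M: 100.0
  m: 1.0
  K: 20.0
  n: 1.7
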