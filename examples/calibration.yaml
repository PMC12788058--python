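roi: ch1
baseline_window_s: [0.0, 12.0]
x_unit: RIU
blank_roi: ch2
levels:
  - {window_s: [2.0, 12.0], x: 0.0}
  - {window_s: [15.0, 25.0], x: 0.001}
  - {window_s: [28.0, 38.0], x: 0.002}
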