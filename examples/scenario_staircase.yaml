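# Two-channel staircase scenario: ch1 steps through three RI levels,
# ch2 is a flat blank. Noise-free for a quick deterministic demo.
seed: 5
base_ri: 1.3295
frame_period_s: 1.0
duration_s: 38.0
noise_sd: 0.0
shape: [12, 24]
rois:
  ch1:
    rect: [2, 2, 8, 10]
    course: {kind: staircase, levels: [0.0, 0.001, 0.002], dwell_s: 13.0}
  ch2:
    rect: [12, 2, 18, 10]
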