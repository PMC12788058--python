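# Synthetic chromium adhesion-layer optical constants: smoothed representative
# magnitudes for evaporated Cr in the visible/NIR. The 2 nm layer this table
# feeds perturbs the resonance position by well under a nanometre, so only the
# order of magnitude of n and k matters here.
# wavelength_nm	n	k
400	1.99	2.88
500	2.75	3.24
600	3.08	3.33
700	3.16	3.30
800	3.20	3.30
900	3.23	3.32
1000	3.26	3.37
1200	3.30	3.42
1600	3.35	3.50
2000	3.40	3.60
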