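# Gold complex refractive index, evaporated films (Johnson-Christy-style
# visible/NIR values), linear interpolation between rows.
# wavelength_nm	n	k
413.3	1.46	1.958
430.5	1.45	1.948
450.9	1.38	1.914
471.4	1.31	1.849
494.0	1.04	1.833
521.0	0.62	2.081
548.6	0.43	2.455
582.1	0.29	2.863
616.8	0.21	3.272
659.5	0.14	3.697
704.5	0.13	4.103
756.0	0.14	4.542
821.1	0.16	5.083
891.9	0.17	5.663
984.0	0.22	6.350
1087.6	0.27	7.150
1215.5	0.35	8.145
1393.1	0.43	9.519
1610.2	0.56	11.21
1937.3	0.92	13.78
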