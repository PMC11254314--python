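id	kind	dose_uM	time_h	direction
RRM2	protein	100	12	↑
ACOT2	protein	100	12	↓
MAT2A	protein	100	24	↓
RRM2	protein	200	12	↑
GNPNAT1	protein	200	12	↓
CP	protein	200	12	↓
MAT2A	protein	200	48	↓
GPD1	protein	200	48	↓
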