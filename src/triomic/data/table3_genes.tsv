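id	kind	dose_uM	time_h	direction
Rrm2	gene	100	12	↑
Acot2	gene	100	12	↓
Mat2a	gene	100	24	↓
Rrm2	gene	200	12	↑
Gnpnat1	gene	200	12	↓
Cp	gene	200	12	↓
Mat2a	gene	200	48	↓
Gpd1	gene	200	48	↓
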