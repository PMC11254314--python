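dose_uM	time_h	value
100	12	96.9
100	24	92.7
100	48	90.1
200	12	96.1
200	24	89.3
200	48	81.8
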