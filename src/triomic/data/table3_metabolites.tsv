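id	kind	dose_uM	time_h	direction
Uric acid	metabolite	100	12	↑
Palmitic acid	metabolite	100	12	↑
Oleic acid	metabolite	100	12	↑
Linoleic acid	metabolite	100	12	↓
3-Sulfinylpyruvate	metabolite	100	24	↓
dGMP	metabolite	200	12	↓
Uridine	metabolite	200	12	↓
dUMP	metabolite	200	12	↑
D-Glucose 1-phosphate	metabolite	200	12	↑
Bilirubin	metabolite	200	12	↓
5'-Methylthioadenosine	metabolite	200	48	↑
L-Cystathionine	metabolite	200	48	↑
sn-Glycero-3-phosphocholine	metabolite	200	48	↑
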