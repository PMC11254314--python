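# Published per-group indicator counts (differential-metabolite totals and
# joint/relation pathway counts) used as correlation inputs.
dose_uM	time_h	n_differential_metabolites	n_joint_pathways	n_relation_pathways
100	12	51	4	2
100	24	48	2	1
100	48	27	0	0
200	12	48	4	4
200	24	66	2	0
200	48	60	2	2
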