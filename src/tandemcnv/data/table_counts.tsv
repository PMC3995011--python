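# Deletion-carrier by case/control counts per stratum.
# a = case carriers, b = case non-carriers, c = control carriers, d = control non-carriers.
# Case non-carriers derive from the stated stratum totals (total - a).
stratum	a	b	c	d
Sweden	28	2375	33	1236
UK	9	1837	67	7288
US	11	1956	9	987
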