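# Synthetic pPRT step profiles over the panel B5,B6,B8,P1,B9,B10:
# three European deletion and three European duplication carriers with
# an AB1 (B9-B10) crossover, two Yoruba-style duplication carriers with
# a B5-B6 crossover, and one normal sample; Gaussian noise sd 0.05.
sample	locus	log2_value
eur_del_1	B5	-1.0161
eur_del_1	B6	-1.0243
eur_del_1	B8	-0.916
eur_del_1	P1	-0.9015
eur_del_1	B9	-0.9922
eur_del_1	B10	0.9371
eur_del_2	B5	-0.9534
eur_del_2	B6	-1.0067
eur_del_2	B8	-1.0549
eur_del_2	P1	-0.9395
eur_del_2	B9	-1.076
eur_del_2	B10	0.9817
eur_del_3	B5	-0.9946
eur_del_3	B6	-1.0816
eur_del_3	B8	-0.9339
eur_del_3	P1	-0.9959
eur_del_3	B9	-1.0588
eur_del_3	B10	1.0578
eur_dup_1	B5	0.5339
eur_dup_1	B6	0.5789
eur_dup_1	B8	0.5137
eur_dup_1	P1	0.5651
eur_dup_1	B9	0.5824
eur_dup_1	B10	-0.5106
eur_dup_2	B5	0.5856
eur_dup_2	B6	0.5818
eur_dup_2	B8	0.5974
eur_dup_2	P1	0.5874
eur_dup_2	B9	0.6441
eur_dup_2	B10	-0.5147
eur_dup_3	B5	0.5494
eur_dup_3	B6	0.5759
eur_dup_3	B8	0.5561
eur_dup_3	P1	0.5771
eur_dup_3	B9	0.6361
eur_dup_3	B10	-0.6164
yri_dup_1	B5	0.6434
yri_dup_1	B6	-0.6849
yri_dup_1	B8	-0.5412
yri_dup_1	P1	-0.495
yri_dup_1	B9	-0.5528
yri_dup_1	B10	-0.512
yri_dup_2	B5	0.5312
yri_dup_2	B6	-0.6486
yri_dup_2	B8	-0.5786
yri_dup_2	P1	-0.5445
yri_dup_2	B9	-0.5584
yri_dup_2	B10	-0.5723
normal_1	B5	-0.0208
normal_1	B6	-0.0491
normal_1	B8	0.114
normal_1	P1	0.0821
normal_1	B9	-0.1183
normal_1	B10	0.0483
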