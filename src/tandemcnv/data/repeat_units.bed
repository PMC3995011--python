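#assembly=GRCh37
# Repeat units (boundaries approximate) and the AB1 crossover stretch
# (published coordinates) of the chr12p13.31 tandem duplication.
chr12	7896499	7996999	unit_A
chr12	7996999	8141999	unit_B
chr12	7995629	7996700	AB1_A
chr12	8124314	8125390	AB1_B
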