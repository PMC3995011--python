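#assembly=GRCh37
# Synthetic approximate gene intervals for the chr12p13.31 tandem-repeat
# region: placements preserve the qualitative layout (NANOG and most of
# SLC2A14 in unit A, NANOGP1 and SLC2A3 in unit B) but are not exact
# RefSeq coordinates.
chr12	7941991	7948657	NANOG
chr12	7981999	8000500	SLC2A14
chr12	8047999	8054500	NANOGP1
chr12	8070999	8088000	SLC2A3
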