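name	direction	sequence	origin
ITS1	forward	TCCGTAGGTGAACCTGCGG	literature
ITS1-F	forward	CTTGGTCATTTAGAGGAAGTAA	literature
ITS5	forward	GGAAGTAAAAGTCGTAACAAGG	literature
ITS2	reverse	GCTGCGTTCTTCATCGATGC	literature
ITS1-27F	forward	TACGTCCCTGCCCTTTGTAC	custom
ITS1-30F	forward	GTCCCTGCCCTTTGTACACA	custom
ITS1-34F	forward	CTGCCCTTTGTACACACCGC	custom
ITS1-48F	forward	ACACACCGCCCGTCGCTACT	custom
ITS1-217R	reverse	TTTCGCTGCGTTCTTCATCG	custom
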