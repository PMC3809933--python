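set_name	target_species	forward	reverse	amplicon_length	cycles
benA_Chrysogenum	chrysogenum	CATGTGAGTACAATGACTGGGAATCTT	TCGACCAGAACGGCACG	111	35
crt1_Rubens	rubens	CCTCGAGGACTTCAATCCTCCCGTG	GTCAGCGGGCTGAGTGGCC	180	28
crt1_Chainii	chainii	CTTTCTACAATTGCTCGCGTTTTTATTTG	CCTTGTTAGTGGCACCGCACTTA	185	35
parA_Floreyii	floreyi	ACGGCCCCTCCTTACGAAA	TGTGAGACCAAAGGCAGTGG	111	32
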