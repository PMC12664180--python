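element	patterns	category
TATA-box	TATA	development
CAAT-box	CCAAT,CAAT	development
G-Box	CACGTG	light
Box 4	ATTAAT	light
LTR	CCGAAA	stress
ARE	AAACCA	stress
MBS	CAACTG	stress
MRE	AACCTAA	stress
ABRE	ACGTG	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
GARE-motif	TCTGTTG	hormone
W-box	TGACCA,TGACCT	stress
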