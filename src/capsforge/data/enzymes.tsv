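name	recognition	cut_offset
BamHI	GGATCC	1
BglII	AGATCT	1
ClaI	ATCGAT	2
EcoRV	GATATC	3
HindIII	AAGCTT	1
PstI	CTGCAG	5
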