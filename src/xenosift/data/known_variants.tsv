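gene	protein_change
RS1	R209H
PIK3CA	E542K
MLL3	R199*
LRIG3	E576K
KLHL3	S410L
FANCD2	L1134V
DNAH7	R1957*
PIK3CA	E545K
NCSTN	S389C
MYD88	S219C
CREBBP	W1472C
CFTR	R1066C
CDKN2A	E69*
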