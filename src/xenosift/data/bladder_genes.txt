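# Frozen list of genes recurrently mutated in bladder cancer (fixture).
ARID1A
ELF3
ERBB2
FGFR3
KDM6A
KMT2D
RB1
RXRA
STAG2
TSC1
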