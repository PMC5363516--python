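# Frozen Cancer Gene Census subset used for tiering (fixture, not a live
# database export).
ARID2
ATP7A
BMPR1A
BRCA2
CASP8
CDKN2A
CREBBP
ELF3
ETV4
FANCD2
KDM6A
KRAS
MLH1
MLL
MLL2
MLL3
MYD88
MYST4
PIK3CA
TP53
ZFP36L1
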