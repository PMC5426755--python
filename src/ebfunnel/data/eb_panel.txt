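# Known epidermolysis bullosa genes (recessive or dominant), one symbol per line.
COL7A1
COL17A1
DSP
DST
EXPH5
FERMT1
ITGA3
ITGA6
ITGB4
JUP
KLHL24
KRT5
KRT14
LAMA3
LAMB3
LAMC2
PLEC
PKP1
TGM5
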