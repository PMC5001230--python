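# Known type 2 diabetes proteins (OMIM-derived seed list, HGNC symbols)
GPD2
NEUROD1
IRS1
CAPN10
PPARG
SLC2A2
IGF2BP2
WFS1
CDKAL1
HMGA1
ENPP1
GCK
TCF7L2
KCNJ11
ABCC8
MAPK8IP1
UCP3
MTNR1B
HNF1A
TBC1D4
IRS2
LIPC
HNF1B
GCGR
RETN
AKT2
HNF4A
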