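HUB	Nucleus
HUB	Cytosol
LEAF1	Cytosol
LEAF2	Nucleus
AUX1	Nucleus
AUX2	Nucleus
AUX3	Peroxisome
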