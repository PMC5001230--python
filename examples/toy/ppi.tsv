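# toy network: a seeded star (HUB with three leaves) plus a scaffold
# triangle-free chain that fixes the compartment sizes
HUB	LEAF1
HUB	LEAF2
HUB	LEAF3
AUX1	AUX2
AUX2	AUX3
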