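# Transformation efficiency (titer) of each screen, colonies screened
bait	titer_cfu
EMPTY	12300000
NINJA	3850000
TPL-N	20500000
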