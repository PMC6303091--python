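# Sanger-sequenced prey colonies per screen, collapsed to per-gene colony counts
screen	colonies	gene_id	description
NINJA	8	AT1G19180	jasmonate-ZIM-domain protein 1 (JAZ1)
NINJA	1	AT4G14720	protein PEAPOD2 (PPD2)
TPL-N	4	AT3G23030	indole-3-acetic acid inducible 2 (IAA2)
TPL-N	3	AT5G25890	indole-3-acetic acid inducible 28 (IAA28)
TPL-N	2	AT3G57390	AGAMOUS-like 18 (AGL18)
TPL-N	1	AT5G43700	indole-3-acetic acid inducible 4 (IAA4)
TPL-N	1	AT3G62100	indole-3-acetic acid inducible 30 (IAA30)
TPL-N	1	AT5G65670	indole-3-acetic acid inducible 9 (IAA9)
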