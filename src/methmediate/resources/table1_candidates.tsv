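probe_id	delta_beta_percent	p	chromosome	position	gene	genomic_feature	meqtl_flag	cit_flag	category	il1b_direction
cg26201826	1.15	7.27e-06	5	114598579	PGGT1B	TSS200	Y	not_applicable	il1b_production	down
cg20419410	0.39	1.48e-07	7	155089803	INSIG1	5UTR	Y	not_applicable	il1b_production	down
cg17618153	-1.38	1.36e-05	9	129874991	ANGPTL2	5UTR	Y	not_applicable	il1b_production	up
cg15686135	-1.24	1.32e-09	10	49542423	JNK1	5UTR	Y	not_applicable	il1b_production	up
cg14167017	0.38	2.78e-07	9	34178925	UBAP1	TSS200	N	Y	expressed_macrophage_il1b	down
cg03081134	0.49	8.77e-06	9	36036806	RECK	TSS200	N	N	expressed_macrophage_il1b	down
cg01680773	0.67	1.13e-05	14	74960124	NPC2	TSS200	N	N	expressed_macrophage_il1b	down
cg11988568	1.04	7.84e-07	17	78518917	RAPTOR	5UTR	N	Y	expressed_macrophage_il1b	down
cg16745952	0.96	1.22e-05	11	98891665	CNTN5	TSS200	Y	not_applicable	gouty_inflammation	unknown
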