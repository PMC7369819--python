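# Curated gene list: genes whose promoter methylation candidates are retained
# because the gene regulates IL-1beta production, is expressed in macrophages
# and implicated in IL-1beta production, or was previously implicated in gouty
# inflammation.  il1b_direction gives the literature-reported effect of the
# gene product on IL-1beta output (up = stimulates, down = suppresses).
genes:
  PGGT1B: {category: il1b_production, il1b_direction: down}
  INSIG1: {category: il1b_production, il1b_direction: down}
  ANGPTL2: {category: il1b_production, il1b_direction: up}
  JNK1: {category: il1b_production, il1b_direction: up}
  UBAP1: {category: expressed_macrophage_il1b, il1b_direction: down}
  RECK: {category: expressed_macrophage_il1b, il1b_direction: down}
  NPC2: {category: expressed_macrophage_il1b, il1b_direction: down}
  RAPTOR: {category: expressed_macrophage_il1b, il1b_direction: down}
  CNTN5: {category: gouty_inflammation, il1b_direction: unknown}

# Shared-variant replay map for fixture-mode runs: for each candidate CpG that
# had variants concurrently associated with its methylation and with gout, the
# variant ids and whether the causal inference test was significant for all of
# them (true -> methylation-mediated; false -> genetically confounded).
shared_variants:
  cg14167017: {variants: [rs1189081296, rs962251804], cit_significant: true}
  cg11988568: {variants: [rs754012543], cit_significant: true}
  cg03081134: {variants: [rs186201319], cit_significant: false}
  cg01680773: {variants: [rs539604468], cit_significant: false}
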