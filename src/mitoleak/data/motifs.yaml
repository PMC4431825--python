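# Discriminating haplotype motifs of the bundled four-trio dataset.
# Positions are 1-based rCRS (NC_012920); maternal/paternal give the
# allele carried by each lineage of the trio the motif discriminates.
motifs:
- motif_id: A
  amplicon_id: amp1
  flank: 20
  sites:
  - {position: 11299, maternal: T, paternal: C}
  - {position: 11467, maternal: A, paternal: G}
- motif_id: B
  amplicon_id: amp1
  flank: 20
  sites:
  - {position: 12308, maternal: A, paternal: G}
  - {position: 12346, maternal: C, paternal: T}
  - {position: 12372, maternal: G, paternal: A}
- motif_id: C
  amplicon_id: amp2
  flank: 20
  sites:
  - {position: 15452, maternal: G, paternal: A}
  - {position: 15454, maternal: T, paternal: C}
  - {position: 15607, maternal: G, paternal: A}
- motif_id: D
  amplicon_id: amp2
  flank: 20
  sites:
  - {position: 16233, maternal: T, paternal: C}
  - {position: 16278, maternal: C, paternal: T}
  - {position: 16391, maternal: A, paternal: G}
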