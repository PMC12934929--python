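# Mouse (GRCm39-style) chromosome inventory: 19 autosomes + X + Y.
# Published assembly chromosome lengths; bundled as a convenience.
system: XY
chromosomes:
  - {id: chr1, length: 195154279, role: autosome}
  - {id: chr2, length: 181755017, role: autosome}
  - {id: chr3, length: 159745316, role: autosome}
  - {id: chr4, length: 156860686, role: autosome}
  - {id: chr5, length: 151758149, role: autosome}
  - {id: chr6, length: 149588044, role: autosome}
  - {id: chr7, length: 144995196, role: autosome}
  - {id: chr8, length: 130127694, role: autosome}
  - {id: chr9, length: 124359700, role: autosome}
  - {id: chr10, length: 130530862, role: autosome}
  - {id: chr11, length: 121973369, role: autosome}
  - {id: chr12, length: 120092757, role: autosome}
  - {id: chr13, length: 120883175, role: autosome}
  - {id: chr14, length: 125139656, role: autosome}
  - {id: chr15, length: 104073951, role: autosome}
  - {id: chr16, length: 98008968, role: autosome}
  - {id: chr17, length: 95294699, role: autosome}
  - {id: chr18, length: 90720763, role: autosome}
  - {id: chr19, length: 61420004, role: autosome}
  - {id: chrX, length: 169476592, role: sex_homogametic}
  - {id: chrY, length: 91455967, role: sex_heterogametic}
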