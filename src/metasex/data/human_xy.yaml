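# Human (GRCh38.p14-style) chromosome inventory: 22 autosomes + X + Y.
# Lengths are the published assembly chromosome lengths; bundled as a
# convenience for examples, simulations and tests.
system: XY
chromosomes:
  - {id: chr1, length: 248956422, role: autosome}
  - {id: chr2, length: 242193529, role: autosome}
  - {id: chr3, length: 198295559, role: autosome}
  - {id: chr4, length: 190214555, role: autosome}
  - {id: chr5, length: 181538259, role: autosome}
  - {id: chr6, length: 170805979, role: autosome}
  - {id: chr7, length: 159345973, role: autosome}
  - {id: chr8, length: 145138636, role: autosome}
  - {id: chr9, length: 138394717, role: autosome}
  - {id: chr10, length: 133797422, role: autosome}
  - {id: chr11, length: 135086622, role: autosome}
  - {id: chr12, length: 133275309, role: autosome}
  - {id: chr13, length: 114364328, role: autosome}
  - {id: chr14, length: 107043718, role: autosome}
  - {id: chr15, length: 101991189, role: autosome}
  - {id: chr16, length: 90338345, role: autosome}
  - {id: chr17, length: 83257441, role: autosome}
  - {id: chr18, length: 80373285, role: autosome}
  - {id: chr19, length: 58617616, role: autosome}
  - {id: chr20, length: 64444167, role: autosome}
  - {id: chr21, length: 46709983, role: autosome}
  - {id: chr22, length: 50818468, role: autosome}
  - {id: chrX, length: 156040895, role: sex_homogametic}
  - {id: chrY, length: 57227415, role: sex_heterogametic}
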