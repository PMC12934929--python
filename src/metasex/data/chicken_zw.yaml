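# Chicken (broiler GRCg7b-style) chromosome inventory: 33 autosomes + Z + W.
# In this ZW system males are the homogametic sex (ZZ) and females are
# heterogametic (ZW).  Approximate published assembly lengths; convenience only.
system: ZW
chromosomes:
  - {id: chr1, length: 196449156, role: autosome}
  - {id: chr2, length: 149539284, role: autosome}
  - {id: chr3, length: 110642502, role: autosome}
  - {id: chr4, length: 90861225, role: autosome}
  - {id: chr5, length: 59506338, role: autosome}
  - {id: chr6, length: 36220557, role: autosome}
  - {id: chr7, length: 36382834, role: autosome}
  - {id: chr8, length: 29578256, role: autosome}
  - {id: chr9, length: 23733309, role: autosome}
  - {id: chr10, length: 20453248, role: autosome}
  - {id: chr11, length: 19638187, role: autosome}
  - {id: chr12, length: 20119077, role: autosome}
  - {id: chr13, length: 17905061, role: autosome}
  - {id: chr14, length: 15331188, role: autosome}
  - {id: chr15, length: 12703657, role: autosome}
  - {id: chr16, length: 2706039, role: autosome}
  - {id: chr17, length: 11092391, role: autosome}
  - {id: chr18, length: 11623896, role: autosome}
  - {id: chr19, length: 10455293, role: autosome}
  - {id: chr20, length: 14265659, role: autosome}
  - {id: chr21, length: 6970754, role: autosome}
  - {id: chr22, length: 4686657, role: autosome}
  - {id: chr23, length: 6253421, role: autosome}
  - {id: chr24, length: 6478339, role: autosome}
  - {id: chr25, length: 3067737, role: autosome}
  - {id: chr26, length: 5349051, role: autosome}
  - {id: chr27, length: 5228753, role: autosome}
  - {id: chr28, length: 5437364, role: autosome}
  - {id: chr29, length: 726478, role: autosome}
  - {id: chr30, length: 755666, role: autosome}
  - {id: chr31, length: 2457334, role: autosome}
  - {id: chr32, length: 125424, role: autosome}
  - {id: chr33, length: 3839931, role: autosome}
  - {id: chrZ, length: 86044486, role: sex_homogametic}
  - {id: chrW, length: 9109940, role: sex_heterogametic}
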