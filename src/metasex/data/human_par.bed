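chrX	10000	2781479	PAR1
chrX	155701382	156030895	PAR2
chrY	10000	2781479	PAR1
chrY	56887902	57217415	PAR2
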